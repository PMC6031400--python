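"""Calibrate a species-level identity threshold for a functional gene.

The 16S rRNA gene carries a conventional species boundary (99% identity),
but functional genes such as ureC evolve faster, so the species-level
clustering threshold for a ureC amplicon must be derived rather than
assumed.  The procedure: for reference genomes carrying both markers,
compute, per lineage, the pairwise identity of each genome's 16S and ureC
to a query genome; regress ureC identity on 16S identity; read off the
ureC identity at the 99% 16S boundary; average those per-lineage readouts
and floor the unrounded mean to an integer percent as a conservative
clustering threshold.  Feeding the per-lineage readouts 93.3, 93.6 and
89.0 reproduces the mean 92.0 and the threshold 91.

Identity here is global-alignment identity over non-terminal columns —
deterministic and parameter-light, and equivalent to local-alignment
identity for the near-full-length marker windows this module compares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "MarkerPairRecord",
    "IdentityPoint",
    "CalibrationResult",
    "pairwise_identity",
    "build_identity_points",
    "calibrate_lineage",
    "combine_calibrations",
]


@dataclass
class MarkerPairRecord:
    """One genome's 16S and ureC sequences with a lineage label.

    ``region_16s`` / ``region_urec`` are 1-based inclusive windows
    selecting the marker region compared (e.g. the primer-delimited
    amplicon); ``None`` means the full sequence.
    """

    genome_id: str
    lineage: str
    seq_16s: str
    seq_urec: str
    region_16s: tuple[int, int] | None = None
    region_urec: tuple[int, int] | None = None
    true_div_16s: float | None = None  # simulator provenance
    true_div_urec: float | None = None

    def __post_init__(self) -> None:
        if not self.seq_16s or not self.seq_urec:
            raise ValueError(f"{self.genome_id}: empty marker sequence")
        for region, seq, name in ((self.region_16s, self.seq_16s, "16S"),
                                  (self.region_urec, self.seq_urec, "ureC")):
            if region is not None:
                lo, hi = region
                if not (1 <= lo <= hi <= len(seq)):
                    raise ValueError(
                        f"{self.genome_id}: {name} window {region} outside "
                        f"sequence of length {len(seq)}"
                    )

    def window_16s(self) -> str:
        if self.region_16s is None:
            return self.seq_16s
        lo, hi = self.region_16s
        return self.seq_16s[lo - 1:hi]

    def window_urec(self) -> str:
        if self.region_urec is None:
            return self.seq_urec
        lo, hi = self.region_urec
        return self.seq_urec[lo - 1:hi]


@dataclass(frozen=True)
class IdentityPoint:
    """Identities of one subject genome's 16S and ureC to the query."""

    subject_genome: str
    id_16s: float
    id_urec: float


@dataclass
class CalibrationResult:
    """Per-lineage ureC identities at the 16S boundary and their summary."""

    per_lineage: dict[str, float]
    reference_identity: float
    mean_identity: float  # one decimal
    conservative_threshold: int  # floor of the unrounded mean
    unrounded_mean: float = field(repr=False, default=float("nan"))


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -2.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity from a global alignment of two sequences.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1.
    Identity = matched columns / aligned columns, with terminal-gap
    columns excluded from both counts, x 100.  Symmetric.

    Terminal gaps are penalized during alignment (but excluded from the
    identity): leaving them free lets the optimal alignment between two
    dissimilar sequences collapse onto any short conserved block (e.g. a
    shared primer site) with both tails dangling, which reports a
    spuriously perfect identity.  For the near-full-length, high-identity
    comparisons the species-threshold work relies on, the penalized and
    free-end definitions agree.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 100.0
    al = aligner or _DEFAULT_ALIGNER
    aln = al.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    lo, hi = 0, len(s1)
    while lo < hi and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        raise ValueError("alignment has no non-terminal columns")
    matches = sum(x == y for x, y in zip(s1[lo:hi], s2[lo:hi]))
    return 100.0 * matches / (hi - lo)


def build_identity_points(query: MarkerPairRecord,
                          subjects: list[MarkerPairRecord]) -> tuple[list[IdentityPoint], list[str]]:
    """Identity of each subject's 16S and ureC windows to the query's.

    Returns the points and the ids of subjects skipped for missing
    markers.  Subjects from other lineages are compared anyway but
    trigger a warning.
    """
    q16, qure = query.window_16s(), query.window_urec()
    points: list[IdentityPoint] = []
    skipped: list[str] = []
    for s in subjects:
        if s.lineage != query.lineage:
            warnings.warn(
                f"subject {s.genome_id} lineage {s.lineage!r} differs from "
                f"query lineage {query.lineage!r}"
            )
        try:
            s16, sure = s.window_16s(), s.window_urec()
        except Exception:
            skipped.append(s.genome_id)
            continue
        if not s16.strip("N") or not sure.strip("N"):
            skipped.append(s.genome_id)
            continue
        points.append(IdentityPoint(
            s.genome_id,
            pairwise_identity(q16, s16),
            pairwise_identity(qure, sure),
        ))
    if not points:
        raise ValueError("no usable subjects: all skipped or list empty")
    return points, skipped


def calibrate_lineage(points: list[IdentityPoint], reference_identity: float = 99.0,
                      mode: str = "regression") -> tuple[float, dict]:
    """Functional-gene identity at the 16S reference boundary.

    ``mode='regression'`` (default): OLS fit of id_urec on id_16s
    evaluated at ``reference_identity``; ``mode='nearest'``: id_urec of
    the point whose id_16s is closest to the reference.  Returns the
    identity and a diagnostics dict (slope, intercept, r_squared, n).
    """
    if len(points) < 3:
        raise ValueError(f"need >=3 points, got {len(points)}")
    x = np.array([p.id_16s for p in points], dtype=float)
    y = np.array([p.id_urec for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all id_16s values equal: degenerate fit")
    if not (x.min() - 2 <= reference_identity <= x.max() + 2):
        warnings.warn(
            f"reference identity {reference_identity} outside the observed "
            f"16S identity span [{x.min():.2f}, {x.max():.2f}]: extrapolating"
        )
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    diag = {"slope": float(slope), "intercept": float(intercept),
            "r_squared": r2, "n": len(points), "mode": mode}
    if mode == "regression":
        value = float(slope * reference_identity + intercept)
    elif mode == "nearest":
        value = float(y[np.argmin(np.abs(x - reference_identity))])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return value, diag


def combine_calibrations(values: list[float] | dict[str, float],
                         reference_identity: float = 99.0) -> CalibrationResult:
    """Average per-lineage identities and take the conservative threshold.

    The mean is reported to one decimal; the clustering threshold is the
    floor of the *unrounded* mean (92.0 from 93.3/93.6/89.0 -> 91).
    """
    if isinstance(values, dict):
        per_lineage = dict(values)
    else:
        per_lineage = {f"lineage{i + 1}": v for i, v in enumerate(values)}
    if not per_lineage:
        raise ValueError("no calibration values supplied")
    vals = list(per_lineage.values())
    unrounded = sum(vals) / len(vals)
    return CalibrationResult(
        per_lineage=per_lineage,
        reference_identity=reference_identity,
        mean_identity=round(unrounded, 1),
        conservative_threshold=math.floor(unrounded),
        unrounded_mean=unrounded,
    )
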