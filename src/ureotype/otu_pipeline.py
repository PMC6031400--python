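"""OTU clustering and diversity statistics for amplicon read sets.

Reads pass a simple length/N-content filter, are dereplicated, and then
clustered by a greedy abundance-ordered centroid method (USEARCH-style):
uniques are processed from most to least abundant; each joins the
existing centroid of highest identity provided that identity meets the
threshold (ties to the earliest centroid), otherwise it founds a new
OTU.  Identity is the same semi-global alignment identity used for
threshold calibration, so the calibrated cutoff (91% for ureC, 97-99%
for 16S) and the clustering metric are commensurable.

Downstream statistics: Good's coverage C = 1 - n1/N per sample,
analytic rarefaction via the hypergeometric expectation, core
(all-sample) vs site-specific OTU partitioning, abundance ranking for
heatmap input, and novelty classification of representatives against a
reference set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .threshold_calibration import pairwise_identity

__all__ = [
    "ReadSet",
    "Unique",
    "OTU",
    "OTUTable",
    "DiversityStats",
    "quality_filter",
    "dereplicate",
    "greedy_cluster",
    "build_otu_table",
    "goods_coverage",
    "rarefaction",
    "shared_otus",
    "rank_otus",
    "novelty_classification",
]


@dataclass
class ReadSet:
    """Amplicon reads of one sample."""

    sample_id: str
    reads: list[tuple[str, str]]  # (read_id, sequence)
    provenance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [r for r, _ in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.sample_id}: duplicate read ids")


@dataclass
class Unique:
    """One dereplicated sequence with its supporting reads."""

    sequence: str
    size: int
    sources: list[tuple[str, str]]  # (sample_id, read_id)


@dataclass
class OTU:
    otu_id: str
    representative: str
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def per_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sample, _ in self.members:
            counts[sample] = counts.get(sample, 0) + 1
        return counts

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class OTUTable:
    """Samples x OTUs count matrix plus representative sequences."""

    counts: pd.DataFrame          # index: samples, columns: otu ids
    representatives: dict[str, str]
    threshold: float

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DiversityStats:
    sample_id: str
    n_reads: int
    richness: int
    singletons: int
    goods_coverage: float
    rarefaction_curve: list[tuple[int, float]] = field(default_factory=list)


def quality_filter(reads: ReadSet, min_len: int = 200,
                   max_n_fraction: float = 0.0) -> tuple[ReadSet, dict[str, int]]:
    """Retain reads of length >= min_len whose N fraction <= max_n_fraction.

    Returns the filtered set and a removal log keyed by rule.
    """
    kept: list[tuple[str, str]] = []
    log = {"input": len(reads.reads), "too_short": 0, "too_many_n": 0}
    for rid, seq in reads.reads:
        if len(seq) < min_len:
            log["too_short"] += 1
        elif seq.upper().count("N") > max_n_fraction * len(seq):
            log["too_many_n"] += 1
        else:
            kept.append((rid, seq))
    log["retained"] = len(kept)
    if not kept:
        warnings.warn(f"{reads.sample_id}: no reads passed the quality filter")
    return ReadSet(reads.sample_id, kept, reads.provenance), log


def dereplicate(readsets: list[ReadSet] | ReadSet) -> list[Unique]:
    """Exact-sequence dereplication across one or more samples.

    Output is ordered by (size desc, sequence lexicographic) — the
    abundance order the greedy clusterer consumes.
    """
    if isinstance(readsets, ReadSet):
        readsets = [readsets]
    groups: dict[str, list[tuple[str, str]]] = {}
    for rs in readsets:
        for rid, seq in rs.reads:
            groups.setdefault(seq.upper(), []).append((rs.sample_id, rid))
    uniques = [Unique(seq, len(src), src) for seq, src in groups.items()]
    uniques.sort(key=lambda u: (-u.size, u.sequence))
    return uniques


def greedy_cluster(uniques: list[Unique], threshold: float,
                   identity_fn=pairwise_identity) -> list[OTU]:
    """Greedy centroid clustering at a percent-identity threshold.

    Deterministic: uniques are taken in dereplication (abundance) order;
    assignment is best-hit with earliest-centroid tie-break; every
    member's identity to its centroid is >= threshold.
    """
    if not (50 < threshold <= 100):
        raise ValueError(f"threshold must lie in (50, 100], got {threshold}")
    otus: list[OTU] = []
    for u in uniques:
        best_i, best_id = -1, -1.0
        for i, otu in enumerate(otus):
            ident = identity_fn(u.sequence, otu.representative)
            if ident >= threshold and ident > best_id:
                best_i, best_id = i, ident
        if best_i >= 0:
            otus[best_i].members.extend(u.sources)
        else:
            otus.append(OTU(f"OTU{len(otus) + 1:04d}", u.sequence,
                            list(u.sources)))
    return otus


def build_otu_table(otus: list[OTU], samples: list[str],
                    threshold: float = float("nan")) -> OTUTable:
    """Assemble the samples x OTUs count matrix.

    Columns ordered by total count descending, then otu_id.
    """
    known = set(samples)
    for otu in otus:
        for sample, _ in otu.members:
            if sample not in known:
                raise ValueError(f"{otu.otu_id}: unknown sample label {sample!r}")
    data = {otu.otu_id: [otu.per_sample_counts.get(s, 0) for s in samples]
            for otu in otus}
    df = pd.DataFrame(data, index=list(samples), dtype=int)
    if len(df.columns):
        totals = df.sum(axis=0)
        order = sorted(df.columns, key=lambda c: (-totals[c], c))
        df = df[order]
    reps = {otu.otu_id: otu.representative for otu in otus}
    return OTUTable(df, reps, threshold)


def goods_coverage(sample_counts) -> float:
    """Good's coverage C = 1 - n1/N for one sample's OTU count vector."""
    c = np.asarray(sample_counts, dtype=int)
    n = int(c.sum())
    if n == 0:
        raise ValueError("sample has no reads")
    n1 = int((c == 1).sum())
    return 1.0 - n1 / n


def rarefaction(sample_counts, depths: list[int]) -> list[tuple[int, float]]:
    """Expected OTU richness at each subsampling depth (analytic).

    E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)), evaluated in log space
    with the gamma function.
    """
    c = np.asarray([x for x in np.asarray(sample_counts, dtype=int) if x > 0])
    n = int(c.sum())
    if n == 0:
        raise ValueError("sample has no reads")
    curve: list[tuple[int, float]] = []
    for d in depths:
        if not (0 < d <= n):
            raise ValueError(f"depth {d} outside (0, {n}]")
        # log C(N - n_i, d) - log C(N, d); term is 0 when N - n_i < d
        rem = n - c
        with np.errstate(invalid="ignore"):
            logp = (gammaln(rem + 1) - gammaln(d + 1) - gammaln(rem - d + 1)
                    - (gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1)))
        p_absent = np.where(rem < d, 0.0, np.exp(logp))
        curve.append((d, float(np.sum(1.0 - p_absent))))
    return curve


def diversity_stats(table: OTUTable, depths: int = 10) -> list[DiversityStats]:
    """Per-sample richness, singleton count, Good's coverage, rarefaction."""
    out = []
    for sample in table.samples:
        row = table.counts.loc[sample].to_numpy()
        n = int(row.sum())
        if n == 0:
            warnings.warn(f"{sample}: empty sample, skipped")
            continue
        grid = sorted({max(1, round(n * k / depths)) for k in range(1, depths + 1)})
        out.append(DiversityStats(
            sample_id=sample,
            n_reads=n,
            richness=int((row > 0).sum()),
            singletons=int((row == 1).sum()),
            goods_coverage=goods_coverage(row),
            rarefaction_curve=rarefaction(row, grid),
        ))
    return out


def shared_otus(table: OTUTable) -> tuple[set[str], dict[str, int], dict[str, set[str]]]:
    """Core OTUs (present in every sample) and site-specific OTU counts.

    Returns (core set, per-sample site-specific counts, per-sample
    site-specific OTU sets).  With a single sample every OTU is both
    core and site-specific by definition.
    """
    if not table.samples:
        raise ValueError("table has no samples")
    present = table.counts > 0
    core = set(present.columns[present.all(axis=0)])
    nsamples_per_otu = present.sum(axis=0)
    specific_sets: dict[str, set[str]] = {}
    specific_counts: dict[str, int] = {}
    for sample in table.samples:
        own = set(present.columns[(present.loc[sample]) & (nsamples_per_otu == 1)])
        specific_sets[sample] = own
        specific_counts[sample] = len(own)
    return core, specific_counts, specific_sets


def rank_otus(table: OTUTable, n: int) -> pd.DataFrame:
    """Top-n OTUs by total reads, with per-sample relative abundances.

    Ordering: total count descending, then otu_id ascending.  Relative
    abundance is each OTU's share of its sample's reads, in percent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = table.counts.sum(axis=0)
    if n > len(totals):
        warnings.warn(f"requested top {n} of {len(totals)} OTUs; returning all")
        n = len(totals)
    order = sorted(table.counts.columns, key=lambda c: (-totals[c], c))[:n]
    sample_totals = table.counts.sum(axis=1)
    rel = 100.0 * table.counts[order].div(sample_totals, axis=0)
    out = rel.T
    out.insert(0, "total_reads", [int(totals[c]) for c in order])
    return out


def novelty_classification(otus: list[OTU], reference: dict[str, str],
                           threshold: float = 91.0,
                           identity_fn=pairwise_identity) -> pd.DataFrame:
    """Best reference identity per OTU representative and a novelty flag.

    An OTU whose best identity to any known reference sequence falls
    below the species-level threshold is flagged as novel (no described
    relative at species rank).
    """
    if not reference:
        raise ValueError("empty reference set")
    rows = []
    for otu in otus:
        best_ref, best_id = None, -1.0
        for ref_id, ref_seq in reference.items():
            ident = identity_fn(otu.representative, ref_seq)
            if ident > best_id:
                best_ref, best_id = ref_id, ident
        rows.append({"otu_id": otu.otu_id, "best_reference": best_ref,
                     "best_identity": best_id,
                     "below_threshold": best_id < threshold})
    return pd.DataFrame(rows).set_index("otu_id")
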