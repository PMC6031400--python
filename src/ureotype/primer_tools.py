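"""Degenerate-primer arithmetic for functional-gene amplicon work.

IUPAC-coded primers are treated as sets of concrete oligonucleotides.
Matching is asymmetric: the primer position admits a *set* of bases, the
template must supply a concrete base — a template ``N`` never satisfies a
primer position.  This mirrors wet-lab annealing semantics, where an
ambiguous template call gives no guarantee of a Watson–Crick pair.

The module covers expansion and degeneracy counting, mismatch-tolerant
site scanning on both strands, in-silico PCR (amplicon prediction),
database coverage reports, and majority-vote degeneracy reduction against
a target alignment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "IUPAC_CODES",
    "DegeneratePrimer",
    "PrimerMatch",
    "Amplicon",
    "CoverageReport",
    "L2F_V1",
    "URE_733R",
    "degeneracy",
    "expand",
    "match_primer",
    "in_silico_pcr",
    "primer_coverage",
    "reduce_degeneracy",
    "reverse_complement",
]

# IUPAC nucleotide ambiguity codes -> admitted concrete bases.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-coded oligonucleotide, written 5'->3'."""

    name: str
    sequence: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for pos, ch in enumerate(seq, start=1):
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"primer {self.name!r}: invalid IUPAC character "
                    f"{ch!r} at position {pos}"
                )
        if len(seq) < 10:
            raise ValueError(
                f"primer {self.name!r}: length {len(seq)} < 10"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)


# ureC primer pair used for amplification of the urease alpha-subunit gene
# (amplicon ca. 386 bp).  L2F_V1 is fully concrete; 733R carries six
# degenerate positions.
L2F_V1 = DegeneratePrimer("L2F_V1", "CGGCAAGGCCGGCAACCC", "forward")
URE_733R = DegeneratePrimer("733R", "GTBGHDCCCCARTCYTCRT", "reverse")


@dataclass(frozen=True)
class PrimerMatch:
    """One mismatch-tolerant primer binding site on a template.

    ``start`` is the 1-based template position of the primer's 5'-most
    aligned base: the leftmost occupied position on strand ``+``, the
    rightmost on strand ``-``.
    """

    template_id: str
    start: int
    strand: str
    mismatches: int
    three_prime_mismatch: bool


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, 0-based half-open on the template."""

    start: int
    end: int
    sequence: str
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class CoverageReport:
    """Fraction of a template database a primer pair can amplify."""

    primer_pair: tuple[str, str]
    n_templates: int
    n_amplifiable: int
    detail: list[dict] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        return self.n_amplifiable / self.n_templates


def degeneracy(primer: DegeneratePrimer) -> int:
    """Number of concrete oligonucleotides the primer encodes.

    Product over positions of the cardinality of each IUPAC code.
    """
    n = 1
    for ch in primer.sequence:
        n *= len(IUPAC_CODES[ch])
    return n


def expand(primer: DegeneratePrimer, cap: int = 65_536) -> set[str]:
    """Enumerate every concrete expansion of the primer.

    Refuses to expand beyond ``cap`` sequences.
    """
    d = degeneracy(primer)
    if d > cap:
        raise ValueError(
            f"primer {primer.name!r} degeneracy {d} exceeds expansion cap {cap}"
        )
    pools = [sorted(IUPAC_CODES[ch]) for ch in primer.sequence]
    return {"".join(p) for p in itertools.product(*pools)}


def _validate_template(template: str) -> str:
    template = template.upper()
    bad = set(template) - set("ACGTN")
    if bad:
        raise ValueError(f"template contains non-ACGTN characters: {sorted(bad)}")
    return template


def _scan(pattern: str, template: str, max_mismatch: int,
          three_prime_window: int, from_right: bool) -> list[tuple[int, int, bool]]:
    """Scan a concrete-orientation IUPAC pattern along a template.

    Returns (0-based leftmost index, mismatches, 3'-window flag) triples.
    ``from_right``: the pattern's 3' end sits at its left (minus-strand
    scan of a reverse-complemented primer).
    """
    sets = [IUPAC_CODES[ch] for ch in pattern]
    L = len(pattern)
    if three_prime_window:
        tp = range(L - three_prime_window, L) if not from_right else range(three_prime_window)
    else:
        tp = range(0)
    tp = set(tp)
    hits = []
    for i in range(len(template) - L + 1):
        mm = 0
        tp_mm = False
        window = template[i:i + L]
        for j, base in enumerate(window):
            if base not in sets[j]:
                mm += 1
                if j in tp:
                    tp_mm = True
                if mm > max_mismatch:
                    break
        else:
            hits.append((i, mm, tp_mm))
    return hits


def match_primer(primer: DegeneratePrimer, template: str, max_mismatch: int = 0,
                 template_id: str = "template",
                 three_prime_window: int = 3) -> list[PrimerMatch]:
    """Find all binding sites of ``primer`` on both strands of ``template``.

    A position mismatches when the template base is not in the primer
    code's admitted set; template ``N`` always counts as a mismatch.
    Results are sorted by (mismatches, start).
    """
    template = _validate_template(template)
    if len(template) < len(primer):
        raise ValueError("template shorter than primer")
    matches: list[PrimerMatch] = []
    for i, mm, tp in _scan(primer.sequence, template, max_mismatch,
                           three_prime_window, from_right=False):
        matches.append(PrimerMatch(template_id, i + 1, "+", mm, tp))
    rc = reverse_complement(primer.sequence)
    for i, mm, tp in _scan(rc, template, max_mismatch,
                           three_prime_window, from_right=True):
        # primer 5' end aligns to the rightmost template base of the site
        matches.append(PrimerMatch(template_id, i + len(primer), "-", mm, tp))
    matches.sort(key=lambda m: (m.mismatches, m.start))
    return matches


def in_silico_pcr(fwd: DegeneratePrimer, rev: DegeneratePrimer, template: str,
                  max_mismatch: int = 0, min_size: int = 50,
                  max_size: int = 5000) -> list[Amplicon]:
    """Predict amplicons from a forward/reverse primer pair on a template.

    Pairs each plus-strand forward site with every downstream minus-strand
    reverse site.  The amplicon span is half-open [fwd_start, rev_end), so
    its size equals the coordinate difference; the 294/680 ureC primer
    sites yield the canonical 386-bp product.
    """
    template = _validate_template(template)
    f_hits = [m for m in match_primer(fwd, template, max_mismatch, "t") if m.strand == "+"]
    r_hits = [m for m in match_primer(rev, template, max_mismatch, "t") if m.strand == "-"]
    out: list[Amplicon] = []
    for f in f_hits:
        start = f.start - 1  # 0-based
        for r in r_hits:
            end = r.start  # 1-based 5'-most == 0-based half-open end
            size = end - start
            if min_size <= size <= max_size and end - len(rev) >= start + len(fwd):
                out.append(Amplicon(start, end, template[start:end],
                                    f.mismatches, r.mismatches))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def primer_coverage(fwd: DegeneratePrimer, rev: DegeneratePrimer,
                    templates: dict[str, str] | Sequence[tuple[str, str]],
                    max_mismatch: int = 0, **pcr_kwargs) -> CoverageReport:
    """Fraction of templates the pair amplifies at <= max_mismatch per primer."""
    if isinstance(templates, dict):
        items: Iterable[tuple[str, str]] = templates.items()
    else:
        items = templates
    items = list(items)
    if not items:
        raise ValueError("empty template set")
    report = CoverageReport((fwd.name, rev.name), len(items), 0)
    for tid, seq in items:
        amps = in_silico_pcr(fwd, rev, seq, max_mismatch, **pcr_kwargs)
        # best per-primer mismatch counts irrespective of pairing, for the
        # per-template detail rows
        fbest = min((m.mismatches for m in match_primer(fwd, seq, len(fwd), tid)),
                    default=None)
        rbest = min((m.mismatches for m in match_primer(rev, seq, len(rev), tid)),
                    default=None)
        amplifiable = bool(amps)
        report.n_amplifiable += amplifiable
        report.detail.append({
            "template_id": tid,
            "amplifiable": amplifiable,
            "n_amplicons": len(amps),
            "amplicon_size": amps[0].size if amps else None,
            "fwd_best_mismatches": fbest,
            "rev_best_mismatches": rbest,
        })
    return report


def reduce_degeneracy(primer: DegeneratePrimer,
                      target_alignment: Sequence[str]) -> tuple[DegeneratePrimer, list[dict]]:
    """Collapse each degenerate position to the majority base among targets.

    ``target_alignment`` holds target sequences aligned to the primer
    (plus-strand orientation), all exactly primer-length.  Ties break
    alphabetically (A<C<G<T) with a warning.  Returns the reduced primer
    and a substitution report (position, old code, new base).
    """
    for t in target_alignment:
        if len(t) != len(primer):
            raise ValueError(
                f"alignment row length {len(t)} != primer length {len(primer)}"
            )
    new_seq = list(primer.sequence)
    report: list[dict] = []
    for j, code in enumerate(primer.sequence):
        if len(IUPAC_CODES[code]) == 1:
            continue
        counts: dict[str, int] = {}
        for t in target_alignment:
            b = t[j].upper()
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            continue
        best = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == best)
        if len(winners) > 1:
            warnings.warn(
                f"tie at position {j + 1} among {winners}; choosing {winners[0]}"
            )
        new_seq[j] = winners[0]
        report.append({"position": j + 1, "old": code, "new": winners[0]})
    reduced = DegeneratePrimer(primer.name + "_reduced", "".join(new_seq),
                               primer.orientation)
    return reduced, report
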