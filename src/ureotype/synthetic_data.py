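"""Synthetic paired-marker communities with known ground truth.

Emulates a multi-site soil survey of ureolytic prokaryotes: genomes carry
a 16S rRNA gene and a ureC gene whose divergence is a fixed multiple
(``rate_ratio_rho``) of the 16S divergence; sites share a known core of
OTUs plus site-specific ones under a long-tailed (lognormal) abundance
distribution; amplicon reads are copied from the primer-delimited ureC
window with independent per-base substitution errors; per-site 16S/ureC
copy numbers feed a qPCR standard curve, and each site's urea-depletion
time series declines at a rate proportional to its ureC copy number.

Every random draw flows from a single seed through named substreams
(genomes / communities / qpcr / kinetics), so each stage is independently
reproducible.

The mutation model is substitution-only (Jukes-Cantor-like: each site
mutates independently to a uniformly chosen different base); divergence
is the expected mismatch fraction, adequate at the <=10% divergences
simulated.  No chimeras, PCR bias or quality-profile errors are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .primer_tools import L2F_V1, URE_733R, expand, reverse_complement
from .threshold_calibration import MarkerPairRecord
from .abundance_rates import KineticsSeries, StandardCurve

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_marker_pairs",
    "simulate_communities",
    "simulate_qpcr_and_kinetics",
    "simulate_study",
    "substream",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_SUBSTREAMS = {"genomes": 0, "communities": 1, "qpcr": 2, "kinetics": 3}

_LINEAGE_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta",
                  "eta", "theta")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named simulation stage."""
    try:
        key = _SUBSTREAMS[name]
    except KeyError:
        raise ValueError(f"unknown substream {name!r}; choose from {sorted(_SUBSTREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated multi-site study.

    Defaults describe seven soil sites sampled for ureC amplicons, with
    16S copy numbers spanning 5.5e7-2.1e9 copies per g dry soil, ureC at
    1.4-17% of 16S, and batch incubations starting at 794 uM N urea.
    """

    seed: int = 0
    n_lineages: int = 3
    genomes_per_lineage: int = 23
    len_16s: int = 1500
    len_urec: int = 1700
    # 1-based start, half-open end on ureC; span = 386 bp
    amplicon_window: tuple[int, int] = (294, 680)
    rate_ratio_rho: float = 8.0
    divergence_grid: tuple[float, ...] = tuple(np.linspace(0.002, 0.04, 20).round(6))
    embed_primer_sites: bool = True
    indel_rate: float = 0.0
    n_sites: int = 7
    core_otus: int = 6
    site_specific_otus: int = 8
    abundance_sigma: float = 1.5
    reads_per_site: int = 200
    per_base_error: float = 0.002
    copies_16s_range: tuple[float, float] = (5.5e7, 2.1e9)
    urec_fraction_range: tuple[float, float] = (0.014, 0.17)
    rate_per_copy: float = 3.3e-9   # umol h^-1 per ureC copy g^-1
    rate_noise_sd: float = 0.002    # umol g^-1 h^-1
    urea_initial_uM: float = 794.0
    kinetics_times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 54, 6))
    kinetics_noise_sd: float = 10.0  # uM
    suspension_volume_L: float = 0.010
    dry_mass_g: float = 1.6
    curve_slope: float = -3.32      # Cq per log10 copies
    curve_intercept: float = 38.0
    cq_noise_sd: float = 0.1
    extraction_dry_mass_g: float = 0.25
    elution_volume_uL: float = 100.0
    template_volume_uL: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.per_base_error < 0.1):
            raise ValueError("per_base_error must be in [0, 0.1)")
        if self.rate_ratio_rho < 1:
            raise ValueError("rate_ratio_rho must be >= 1")
        for name in ("n_lineages", "genomes_per_lineage", "len_16s", "len_urec",
                     "n_sites", "reads_per_site"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.core_otus < 0 or self.site_specific_otus < 0:
            raise ValueError("OTU counts must be non-negative")
        if self.rate_ratio_rho * max(self.divergence_grid) >= 0.5:
            raise ValueError(
                "rate_ratio_rho x max divergence must stay below 0.5 "
                "(substitution model otherwise approaches saturation)"
            )
        lo, hi = self.amplicon_window
        if not (1 <= lo < hi <= self.len_urec):
            raise ValueError("amplicon_window outside ureC bounds")


@dataclass
class SimulatedStudy:
    """Ground truth plus observations for one simulated study."""

    config: SimConfig
    genomes: list[MarkerPairRecord] = field(default_factory=list)
    # per-site genome_id -> true read count
    truth_tables: dict[str, dict[str, int]] = field(default_factory=dict)
    # per-site abundance vectors over the site's OTU pool
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    # per-site list of (read_id, sequence)
    reads: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # read_id -> genome_id
    true_core_otus: set[str] = field(default_factory=set)
    qpcr_truth: dict[str, dict[str, float]] = field(default_factory=dict)
    qpcr_cq: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)
    standard_curve: StandardCurve | None = None
    kinetics: dict[str, KineticsSeries] = field(default_factory=dict)
    true_rates: dict[str, float] = field(default_factory=dict)
    clipped_concentrations: list[str] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, p: float) -> tuple[np.ndarray, float]:
    """Substitute each site with prob p to a uniformly chosen other base.

    Returns the mutated copy and the realised mismatch fraction.
    """
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if len(hits):
        # shift by 1..3 in base index -> always a different base
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + rng.integers(1, 4, size=len(hits))) % 4]
    return out, len(hits) / len(seq)


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def simulate_marker_pairs(config: SimConfig) -> list[MarkerPairRecord]:
    """Generate lineages of genomes with paired 16S and ureC markers.

    Each lineage has a random ancestor; genome g diverges from it by its
    grid value d at 16S and by rho x d at ureC (expected mismatch
    fractions under independent per-site substitution).  When
    ``embed_primer_sites`` is set, the ancestral ureC carries an L2F_V1
    site at the amplicon-window start and a 733R site at its end, so the
    window is a genuine primer-delimited amplicon.
    """
    cfg = config
    if cfg.rate_ratio_rho * max(cfg.divergence_grid) > 0.75:
        raise ValueError("requested ureC divergence is saturated (> 0.75)")
    rng = substream(cfg.seed, "genomes")
    grid = list(cfg.divergence_grid)
    # tile the grid across genomes
    divs = [grid[i % len(grid)] for i in range(cfg.genomes_per_lineage)]
    lo, hi = cfg.amplicon_window  # 1-based, half-open
    records: list[MarkerPairRecord] = []
    for li in range(cfg.n_lineages):
        lineage = (_LINEAGE_NAMES[li] if li < len(_LINEAGE_NAMES)
                   else f"lineage{li + 1}")
        anc16 = _random_seq(rng, cfg.len_16s)
        ancure = _random_seq(rng, cfg.len_urec)
        if cfg.embed_primer_sites:
            fwd = L2F_V1.sequence
            rev_pool = sorted(expand(URE_733R))
            rev_site = reverse_complement(rev_pool[rng.integers(0, len(rev_pool))])
            ancure[lo - 1:lo - 1 + len(fwd)] = np.frombuffer(
                fwd.encode(), dtype="S1")
            ancure[hi - 1 - len(rev_site):hi - 1] = np.frombuffer(
                rev_site.encode(), dtype="S1")
        for gi, d in enumerate(divs):
            s16, real16 = _mutate(rng, anc16, d)
            sure, realure = _mutate(rng, ancure, cfg.rate_ratio_rho * d)
            records.append(MarkerPairRecord(
                genome_id=f"{lineage}_g{gi + 1:02d}",
                lineage=lineage,
                seq_16s=_to_str(s16),
                seq_urec=_to_str(sure),
                region_16s=(1, cfg.len_16s),
                region_urec=(lo, hi - 1),  # 1-based inclusive
                true_div_16s=real16,
                true_div_urec=realure,
            ))
    return records


def _amplicon(rec: MarkerPairRecord, cfg: SimConfig) -> str:
    lo, hi = cfg.amplicon_window
    return rec.seq_urec[lo - 1:hi - 1]


def simulate_communities(genomes: list[MarkerPairRecord],
                         config: SimConfig) -> SimulatedStudy:
    """Assemble per-site communities and draw error-bearing amplicon reads.

    Each site's OTU pool = the shared core plus its own site-specific
    genomes.  Reads are drawn multinomially from a lognormal abundance
    vector over the pool, then copied from the ureC amplicon window with
    independent per-base substitution errors.  Every pool member is
    guaranteed at least one read (a site's pool is its community), so
    the truth table's core count always equals ``core_otus``.
    """
    cfg = config
    needed = cfg.core_otus + cfg.n_sites * cfg.site_specific_otus
    if needed > len(genomes):
        raise ValueError(
            f"community design needs {needed} genomes "
            f"({cfg.core_otus} core + {cfg.n_sites} x {cfg.site_specific_otus} "
            f"site-specific) but only {len(genomes)} are available"
        )
    if cfg.reads_per_site < cfg.core_otus + cfg.site_specific_otus:
        raise ValueError("reads_per_site smaller than the per-site OTU pool")
    rng = substream(cfg.seed, "communities")
    order = rng.permutation(len(genomes))
    core = [genomes[i] for i in order[:cfg.core_otus]]
    rest = [genomes[i] for i in order[cfg.core_otus:needed]]
    study = SimulatedStudy(config=cfg, genomes=list(genomes))
    study.true_core_otus = {g.genome_id for g in core}
    by_id = {g.genome_id: g for g in genomes}
    for s in range(cfg.n_sites):
        site = f"site{s + 1}"
        own = rest[s * cfg.site_specific_otus:(s + 1) * cfg.site_specific_otus]
        pool = core + own
        weights = rng.lognormal(0.0, cfg.abundance_sigma, size=len(pool))
        weights /= weights.sum()
        study.abundances[site] = {g.genome_id: float(w)
                                  for g, w in zip(pool, weights)}
        counts = rng.multinomial(cfg.reads_per_site, weights)
        # pool membership is ground truth: top up zero draws from the
        # most abundant OTU so every pool member is observed
        while (counts == 0).any():
            counts[counts.argmin()] += 1
            counts[counts.argmax()] -= 1
        truth = {g.genome_id: int(c) for g, c in zip(pool, counts)}
        study.truth_tables[site] = truth
        reads: list[tuple[str, str]] = []
        k = 0
        for gid, c in truth.items():
            template = np.frombuffer(_amplicon(by_id[gid], cfg).encode(), dtype="S1")
            for _ in range(c):
                k += 1
                rid = f"{site}_r{k:05d}"
                if cfg.per_base_error > 0:
                    seq, _ = _mutate(rng, template, cfg.per_base_error)
                else:
                    seq = template
                reads.append((rid, _to_str(seq)))
                study.provenance[rid] = gid
        # shuffle so read order carries no OTU signal
        reads = [reads[i] for i in rng.permutation(len(reads))]
        study.reads[site] = reads
    return study


def simulate_qpcr_and_kinetics(study: SimulatedStudy,
                               config: SimConfig | None = None) -> SimulatedStudy:
    """Attach qPCR copy numbers, Cq triplicates, and urea-decay series.

    16S copies per g dry soil are log-uniform over ``copies_16s_range``;
    ureC copies are a uniform fraction of them; the true ureolytic rate
    is ``rate_per_copy`` x ureC copies plus Gaussian noise; urea declines
    linearly from ``urea_initial_uM`` at the equivalent volumetric rate
    with observation noise, clipped at zero (clipped sites flagged).
    """
    cfg = config or study.config
    if not study.reads:
        raise ValueError("communities must be simulated before qPCR/kinetics")
    rngq = substream(cfg.seed, "qpcr")
    rngk = substream(cfg.seed, "kinetics")
    study.standard_curve = StandardCurve(
        slope=cfg.curve_slope,
        intercept=cfg.curve_intercept,
        r_squared=1.0,
        efficiency=10 ** (-1.0 / cfg.curve_slope) - 1.0,
    )
    lo16, hi16 = cfg.copies_16s_range
    flo, fhi = cfg.urec_fraction_range
    per_rxn_factor = cfg.extraction_dry_mass_g * (
        cfg.template_volume_uL / cfg.elution_volume_uL)
    times = np.asarray(cfg.kinetics_times_h, dtype=float)
    for site in study.reads:
        c16 = float(np.exp(rngq.uniform(np.log(lo16), np.log(hi16))))
        frac = float(rngq.uniform(flo, fhi))
        cure = frac * c16
        study.qpcr_truth[site] = {"copies_16s": c16, "copies_urec": cure,
                                  "urec_fraction": frac}
        cq_site: dict[str, tuple[float, ...]] = {}
        for gene, copies in (("16S", c16), ("ureC", cure)):
            per_rxn = copies * per_rxn_factor
            base_cq = cfg.curve_intercept + cfg.curve_slope * np.log10(per_rxn)
            cq_site[gene] = tuple(
                float(base_cq + rngq.normal(0, cfg.cq_noise_sd))
                if cfg.cq_noise_sd > 0 else float(base_cq)
                for _ in range(3))
        study.qpcr_cq[site] = cq_site
        rate = cfg.rate_per_copy * cure
        if cfg.rate_noise_sd > 0:
            rate += rngk.normal(0, cfg.rate_noise_sd)
        rate = max(rate, 0.0)
        study.true_rates[site] = rate
        slope_uM_h = rate * cfg.dry_mass_g / cfg.suspension_volume_L
        urea = cfg.urea_initial_uM - slope_uM_h * times
        if cfg.kinetics_noise_sd > 0:
            urea = urea + rngk.normal(0, cfg.kinetics_noise_sd, size=len(times))
        if (urea < 0).any():
            urea = np.clip(urea, 0.0, None)
            study.clipped_concentrations.append(site)
        ammonia = np.clip(cfg.urea_initial_uM - urea, 0.0, None)
        study.kinetics[site] = KineticsSeries(
            sample_id=site,
            times=tuple(times),
            urea=tuple(float(u) for u in urea),
            ammonia=tuple(float(a) for a in ammonia),
            suspension_volume=cfg.suspension_volume_L,
            dry_mass=cfg.dry_mass_g,
        )
    return study


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run all three simulation stages for one config."""
    genomes = simulate_marker_pairs(config)
    study = simulate_communities(genomes, config)
    return simulate_qpcr_and_kinetics(study, config)
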