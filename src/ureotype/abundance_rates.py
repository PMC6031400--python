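"""Gene abundance from qPCR and ureolytic rates from batch incubations.

Absolute quantification follows the standard-curve model
Cq = intercept + slope * log10(copies per reaction); copies per reaction
are scaled to copies per g dry soil through the extraction parameters
(elution volume, template volume per reaction, soil dry mass extracted).
Ureolytic rates come from the linear phase of urea depletion in a soil
suspension: rate = -slope(urea vs time) * suspension volume / dry mass,
in umol g dry soil^-1 h^-1.  Rates measured at sub-Km urea
concentrations (hundreds of uM against millimolar-range urease Km) are
flagged as potential underestimates of the soil's ureolytic potential.

Abundance-rate association uses Pearson correlation with the t-based
two-sided p-value; no multiple-testing correction is applied across the
two marker genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "GeneAbundance",
    "KineticsSeries",
    "RateEstimate",
    "fit_standard_curve",
    "quantify",
    "relative_abundance",
    "ureolysis_rate",
    "correlate",
]

SUB_KM_CAVEAT = ("incubation urea concentration is below typical urease Km; "
                 "rates may underestimate the potential ureolytic rate")


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration line: Cq vs log10 template copies."""

    slope: float        # Cq per log10 copies; negative for a valid curve
    intercept: float    # Cq at 1 copy
    r_squared: float
    efficiency: float   # 10^(-1/slope) - 1

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass
class GeneAbundance:
    """Copies of one marker gene per g dry soil for one sample."""

    sample_id: str
    gene: str                      # "16S" | "ureC"
    copies_per_g_dry: float        # triplicate mean
    copies_sd: float
    relative_abundance: float | None = None  # percent, ureC only


@dataclass(frozen=True)
class KineticsSeries:
    """Urea (and optionally ammonia) concentration vs time, one sample."""

    sample_id: str
    times: tuple[float, ...]       # h
    urea: tuple[float, ...]        # uM N
    ammonia: tuple[float, ...] | None = None
    suspension_volume: float = 0.010  # L
    dry_mass: float = 1.0          # g
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.urea):
            raise ValueError("times and urea lengths differ")
        t = np.asarray(self.times)
        if len(t) and not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if any(u < 0 for u in self.urea):
            raise ValueError("negative urea concentration")


@dataclass
class RateEstimate:
    """Ureolytic rate of one sample, umol g dry soil^-1 h^-1."""

    sample_id: str
    rate: float
    se: float
    fit_r_squared: float
    points_used: int
    caveat: str = SUB_KM_CAVEAT


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, r^2, slope SE."""
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue ** 2, res.stderr


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """OLS fit of Cq on log10 copies across dilution points.

    Warns when the implied amplification efficiency leaves [0.8, 1.1].
    """
    if len(points) < 3:
        raise ValueError(f"need >=3 standard points, got {len(points)}")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 copies: cannot fit curve")
    slope, intercept, r2, _ = _ols(x, y)
    if slope >= 0:
        warnings.warn(f"standard-curve slope {slope:.3f} is non-negative")
        efficiency = float("nan")
    else:
        efficiency = 10 ** (-1.0 / slope) - 1.0
        if not (0.8 <= efficiency <= 1.1):
            warnings.warn(f"amplification efficiency {efficiency:.2f} outside [0.8, 1.1]")
    return StandardCurve(slope, intercept, r2, efficiency)


def quantify(cq_triplicate: tuple[float, ...], curve: StandardCurve,
             elution_volume_uL: float = 100.0, template_volume_uL: float = 1.0,
             dry_mass_g: float = 0.25, sample_id: str = "sample",
             gene: str = "ureC", cq_range: tuple[float, float] | None = None) -> GeneAbundance:
    """Copies per g dry soil from a Cq triplicate and a standard curve.

    copies/reaction = 10^((Cq - intercept)/slope), scaled by
    elution/template volumes and divided by the extracted dry mass.
    """
    if curve.slope >= 0:
        raise ValueError("invalid standard curve (non-negative slope)")
    cqs = np.asarray(cq_triplicate, dtype=float)
    if cq_range is not None:
        lo, hi = cq_range
        if ((cqs < lo) | (cqs > hi)).any():
            warnings.warn("Cq outside standard-curve range: extrapolating")
    factor = (elution_volume_uL / template_volume_uL) / dry_mass_g
    per_g = np.array([curve.copies_from_cq(c) for c in cqs]) * factor
    return GeneAbundance(sample_id, gene, float(per_g.mean()),
                         float(per_g.std(ddof=1)) if len(per_g) > 1 else 0.0)


def relative_abundance(urec: GeneAbundance, sixteens: GeneAbundance) -> float:
    """Percent ureC copies relative to 16S copies for the same sample."""
    if urec.sample_id != sixteens.sample_id:
        raise ValueError(
            f"sample mismatch: {urec.sample_id!r} vs {sixteens.sample_id!r}")
    if sixteens.copies_per_g_dry <= 0:
        raise ValueError("16S copy number must be positive")
    pct = 100.0 * urec.copies_per_g_dry / sixteens.copies_per_g_dry
    urec.relative_abundance = pct
    return pct


def ureolysis_rate(series: KineticsSeries, depletion_cutoff: float = 0.05) -> RateEstimate:
    """Ureolytic rate from the linear phase of a urea-depletion series.

    Uses the points where urea remains >= ``depletion_cutoff`` of the
    initial concentration (default 5%), fits urea (uM) vs time (h) by
    OLS, and converts the slope to umol per g dry soil per h via the
    suspension volume.  A non-negative slope yields rate 0 with a
    warning.
    """
    t = np.asarray(series.times, dtype=float)
    u = np.asarray(series.urea, dtype=float)
    keep = u >= depletion_cutoff * u[0] if len(u) else np.array([], bool)
    t, u = t[keep], u[keep]
    if len(t) < 3:
        raise ValueError(
            f"only {len(t)} usable points above the depletion cutoff; need >=3")
    slope, _, r2, se = _ols(t, u)
    vol_over_mass = series.suspension_volume / series.dry_mass
    if slope >= 0:
        warnings.warn(f"{series.sample_id}: non-decreasing urea series; rate set to 0")
        return RateEstimate(series.sample_id, 0.0, abs(se) * vol_over_mass,
                            r2, len(t))
    return RateEstimate(series.sample_id, -slope * vol_over_mass,
                        se * vol_over_mass, r2, len(t))


def pool_replicates(estimates: list[RateEstimate]) -> tuple[float, float]:
    """Mean and sd of replicate rate estimates for one sample."""
    if not estimates:
        raise ValueError("no replicate estimates")
    rates = np.array([e.rate for e in estimates])
    return float(rates.mean()), float(rates.std(ddof=1)) if len(rates) > 1 else 0.0


def correlate(x, y) -> tuple[float, float, float]:
    """Pearson r, r^2 and two-sided p between two per-sample vectors.

    p derives from t = r * sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError(f"need n >= 3, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if math.isclose(abs(r), 1.0):
        p = 0.0
    return r, r * r, float(p)
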