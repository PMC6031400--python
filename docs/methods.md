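# Methods

`ureotype` analyses soil ureolytic prokaryote communities through their
functional marker gene *ureC*, which encodes the urease alpha (catalytic)
subunit, alongside the 16S rRNA gene. This note records the models,
parameter choices and numerical conventions behind each stage, and what
the synthetic-data tests do and do not demonstrate.

## Species-threshold calibration

Species boundaries are conventionally drawn at 99% 16S rRNA identity, but
a protein-coding gene such as *ureC* accumulates substitutions faster, so
its species-level clustering threshold has to be derived. For each
proteobacterial lineage (alpha, beta, gamma) represented by reference
genomes carrying both markers, the package:

1. computes the pairwise identity of every subject genome's 16S and
   *ureC* regions to a designated query genome (`build_identity_points`);
2. regresses *ureC* identity on 16S identity and evaluates the fit at the
   99% 16S reference (`calibrate_lineage`; a nearest-neighbour readout
   mode is available as an alternative, since a regression is only one
   defensible reading of "the identity that corresponds to 99%");
3. averages the per-lineage readouts and floors the *unrounded* mean to
   an integer percent as a conservative clustering threshold
   (`combine_calibrations`). With per-lineage readouts 93.3, 93.6 and
   89.0 the mean is 92.0 and the threshold 91 — the worked example the
   test suite pins down.

The regression model is only meaningful in the shallow-divergence regime:
at per-branch *ureC* divergences above roughly 20% the linear
rate-ratio relationship visibly saturates (multiple substitutions per
site), which is why calibration inputs are near-99% 16S neighbours.

### Pairwise identity

Identity is computed from a global affine-gap alignment (match +1,
mismatch −1, gap open −2, gap extend −1; Biopython `PairwiseAligner`) as
matched columns over aligned columns, with terminal-gap columns excluded
from both counts. Terminal gaps are *penalized during alignment* even
though they are excluded from the identity. Leaving them free (a classic
overlap alignment) lets the optimal alignment between two genuinely
dissimilar amplicons collapse onto any short conserved block — a shared
primer site is enough — and report near-100% identity over a handful of
columns, which silently merges unrelated OTUs. For the near-full-length,
high-identity comparisons that matter here (≥89%), the penalized and
free-end definitions give identical values; the penalized form simply
fails safe on dissimilar pairs. The exact scoring scheme is otherwise
immaterial at these identities and is fixed for reproducibility. The
same routine drives calibration, clustering and novelty classification,
so the calibrated threshold and the clustering metric are commensurable.

## OTU clustering and diversity statistics

Reads pass a minimal length/N-fraction filter (the package deliberately
does not re-implement adapter or quality trimming), are dereplicated
exactly, and are clustered greedily in abundance order (USEARCH-style):
each unique joins the best-matching existing centroid at identity ≥
threshold (ties to the earliest centroid) or founds a new OTU. The
method is deterministic; no chimera removal or denoising is attempted.
Lowering the threshold can only merge clusters, never split them, which
the suite checks as a monotonicity property.

Good's coverage is 1 − n1/N computed per sample on the sample's own
counts. Rarefaction uses the exact hypergeometric expectation
E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d)) evaluated with log-gamma
functions; a 10,000-draw subsampling oracle verifies it in tests. Core
OTUs are those with ≥1 read in every sample; site-specific OTUs occur in
exactly one sample; with a single sample both definitions degenerate to
"all OTUs", which is reported as-is. OTU ranking sorts by total reads
(ties by OTU id) and emits per-sample relative abundances as heatmap
input. Novelty classification flags OTUs whose best identity to any
reference sequence falls below the species threshold.

## qPCR quantification and ureolysis kinetics

The standard curve is an OLS fit of Cq against log10 copies; efficiency
is 10^(−1/slope) − 1 and a warning fires outside [0.8, 1.1]. Copies per
reaction invert the curve and are scaled to copies per g dry soil by
elution volume / template volume / extracted dry mass (defaults 100 µL,
1 µL, 0.25 g → factor 400). Relative abundance is 100 × *ureC* / 16S
copies. No 16S copy-number-per-genome correction is applied, matching
common practice for this ratio.

Ureolytic rates come from urea depletion, not ammonia accumulation: urea
is the substrate followed from t = 0, and the ammonia series, when
present, serves only as a nitrogen-balance consistency check. The linear
phase is defined as points with urea ≥ 5% of the initial concentration
(the windowing rule is the package's own choice); the OLS slope in
µM h⁻¹ is converted by × suspension volume / dry mass to
µmol g dry soil⁻¹ h⁻¹. A non-decreasing series yields rate 0 with a
warning rather than a negative rate. Because batch incubations start at
794 µM N urea — an order of magnitude below typical bacterial urease
Km — every rate estimate carries a caveat field noting it may
underestimate the soil's ureolytic potential; no Michaelis–Menten
correction is attempted. Abundance–rate association uses Pearson r with
the t-based two-sided p on n − 2 df, without multiple-testing correction
across the two marker genes.

## Synthetic-data generator

The generator provides ground truth for every stage. Design choices:

- **Mutation model.** Independent per-site substitution to a uniformly
  chosen different base; no indels by default (`indel_rate` exists as a
  knob and defaults to 0). "Divergence" means expected mismatch
  fraction, not corrected evolutionary distance — adequate at the ≤10%
  16S divergences used, and it keeps identity arithmetic transparent.
  Validity is bounded by requiring rho × max divergence < 0.5.
- **Paired markers.** Each lineage has a random ancestor; genome *g*
  diverges by its grid value *d* at 16S and by rho × *d* at *ureC*
  (default rho = 8, consistent with a functional gene whose 91%
  species threshold mirrors 99% at 16S). The ancestral *ureC* embeds a
  concrete forward-primer site at the amplicon-window start and a
  reverse-primer expansion at its end (window 294–680 half-open, 386 bp),
  so in-silico PCR operates on genuine primer-delimited amplicons and
  mutations create realistic primer–template mismatches.
- **Communities.** Seven sites by default, each with a 6-OTU shared core
  plus 8 site-specific OTUs; abundances are lognormal (sigma 1.5),
  renormalized — producing the singleton-heavy tail that makes Good's
  coverage informative; 200 reads per site drawn multinomially, then
  topped up so every pool member has ≥1 read (a site's pool *is* its
  community, so the truth table's core count equals the design value by
  construction). Reads copy the amplicon window with per-base error
  0.002. No chimeras, PCR bias or quality-profile error structure.
- **qPCR and kinetics.** 16S copies are log-uniform over
  5.5×10⁷–2.1×10⁹ copies g⁻¹; *ureC* is a uniform 1.4–17% fraction of
  16S. True rate = 3.3×10⁻⁹ µmol h⁻¹ per *ureC* copy g⁻¹ plus Gaussian
  noise (sd 0.002), which puts mid-range communities near
  0.1 µmol g⁻¹ h⁻¹; urea declines linearly from 794 µM N, sampled every
  6 h over 48 h with 10 µM observation noise in a 10 mL suspension of
  1.6 g dry soil; negatives are clipped at zero and flagged. Cq values
  follow a slope −3.32 / intercept 38 curve with 0.1-cycle replicate
  noise.
- **Reproducibility.** All randomness flows from one seed through named
  substreams (genomes / communities / qpcr / kinetics), so stages can be
  re-drawn independently and the same seed reproduces a study
  byte-for-byte.

Because genuinely co-occurring field phenomena (chimeras, variable read
quality, taxon-specific primer bias, non-linear urease kinetics) are not
simulated, passing the recovery tests demonstrates the *estimators* are
correct under the stated generative model — not that field data of this
kind would be recovered with the same fidelity.

## Problem sizes

Unit tests run on reduced studies (2 lineages × ~6–10 genomes, 3–7
sites, 30–80 reads per site); recovery analyses that require
well-separated OTU pools use a divergence grid of 0.015–0.045 so that
every between-genome amplicon identity sits below threshold − 2 points.
The acceptance script runs the full default study (69 genomes, 7 sites,
200 reads per site) once, plus the calibration and clustering oracle
analyses at their stated replicate counts (20 and 50 seeds).

## Known limitations

- Greedy clustering performs a full alignment against every centroid
  (best-hit assignment); no k-mer prescreen is applied, so very large
  read sets scale quadratically in unique sequences.
- The degeneracy-reduction tie-break (alphabetical) is arbitrary but
  deterministic; reported substitution positions are 1-based on the
  primer as printed.
- Identity from a score-optimal alignment is not unique when co-optimal
  alignments disagree in match count; near a clustering threshold this
  could, in principle, flip an assignment. The oracle-equivalence tests
  construct families whose within/between identities sit far from the
  threshold, where the definition is unambiguous.
- The calibration's regression reading of "identity corresponding to the
  99% 16S boundary" is one of several defensible choices; the
  nearest-point mode brackets the alternatives.
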