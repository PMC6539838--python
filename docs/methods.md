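# Methods

## The selection model

The pipeline treats reference-gene discovery as a two-step screen on a
genes × samples matrix of normalized log2 intensities with three patient
groups (in the motivating design: presurgical, SIRS, sepsis; sizes on the
order of 19/16/10 or 11/16/15).

**Step 1 — remove discriminatory genes.** For each gene, two-sample
t-tests for the three group pairings (pooled-variance by default, Welch
selectable), each pairing BH-adjusted *across genes*. A gene is
discriminatory if any adjusted p ≤ α = 0.05. This is deliberately
conservative in the direction that matters: FDR correction makes it easy
for a gene to count as nondiscriminatory, which is the *inclusive* first
gate; the demanding filter comes later.

An alternative `fdr_scope="omnibus"` adjusts per-gene one-way ANOVA F-test
p-values across genes instead (the screen's ancestry is ANOVA-based array
software); both scopes are exposed because discovery counts depend on the
choice, and the default is per-pairing.

**Step 2 — among the quiet genes, demand positive evidence of flatness.**
The surviving genes are ranked by the global sample standard deviation
(n−1 denominator, all samples pooled; ties broken lexicographically by
gene id for reproducibility), cut to the `n_lowvar` least variable, then
filtered to those whose *every group mean* lies in the closed intensity
window [4, 11] — below 4, array signals sit on the detection floor with
artificially compressed variance; above 11 they approach saturation.
Walking the shortlist in ascending-sd order, a gene becomes a candidate
when all three *unadjusted* pairwise p-values exceed 0.5 — i.e. the data
look at least as group-flat as the null median — until k = 5 candidates
are found.

p > 0.5 on all three pairings is an intentionally crude "progressive"
stability score, not a calibrated test. Because the three pairings share
group data they are positively correlated: a truly invariant gene passes
all three with probability ≈ 0.22 (Monte Carlo; the naive independence
guess 0.5³ = 0.125 is wrong). Two consequences worth knowing:

* the screen cannot distinguish a "planted" invariant from any other
  truly null gene — candidate identity among equally flat genes is
  essentially arbitrary, which is why borderline flagging and manual
  adjudication exist;
* roughly a fifth of a long null shortlist passes, so the *walk order*
  (ascending variability) is what concentrates the candidate set on the
  most stable genes.

**Borderline genes.** A gene with every p at or above the band floor
(default 0.45) and at least one p inside [0.45, 0.5) is flagged
`borderline` and surfaced in the report, never auto-selected. (A stricter
"exactly one in band" reading exists; the at-least-one reading is used so
that a gene with two near-misses is also surfaced rather than silently
dropped.) Preferring candidates with described gene function is likewise
left to the analyst via an explicit exclusion list — the report records
the exclusion, the pipeline does not encode the judgement.

## Validation semantics

Targeted assays carry technical replicates (triplicate Ct, duplicate
MFI). Replicates are averaged per sample first; every statistic runs on
biological units only.

* **Ct scale** (RT-PCR): Ct is inversely proportional to log2 transcript
  quantity. Fold of group A relative to group B = 2^(mean Ct_B − mean
  Ct_A), amplification efficiency fixed at 2 (equal RNA input per
  reaction; no efficiency correction is modeled).
* **MFI scale** (branched-DNA): proportional to transcript quantity per
  fixed number of lysed cells. Fold = ratio of arithmetic group means
  (matching how such assays are conventionally summarized); a
  geometric-mean option exists, and is the exact counterpart of the
  Ct-scale fold — converting a Ct table to relative quantities 2^−Ct and
  using geometric means reproduces the Ct fold to 1e-9. With arithmetic
  means the two pathways differ by the within-group spread (Jensen gap);
  this is a semantic choice, not an error.
* **Detectability**: a sample is *below* when its replicate-mean signal is
  at or under the limit of detection (LOD). A gene is dropped when the
  below-fraction reaches `max_below_frac` (default 0.5, inclusive — a
  gene detectable in only half the samples is excluded; scope `overall`
  by default, `per_group` selectable). The LOD is an *input*: the package
  does not estimate it from data.
* **Verdicts**: `stable` iff detectable, rank-sum p ≥ 0.05 and fold inside
  the stability band [2/3, 1.5]. The band is an artifact convention
  quantifying "highly similar"; it is configurable.
* **Paired stimulation** (before/after across donors): per-gene fold =
  2^(mean over donors of ΔCt), exact signed-rank test on the paired
  per-donor means, same stable rule. Note the resolution floor: with six
  donors the smallest attainable two-sided exact p is 2/64 ≈ 0.031, so a
  consistent same-sign response is always "significant" no matter how
  small the shift.

## Statistical primitives

All tests are implemented in-package (scipy supplies only distribution
tails and midranks) so exact small-sample behavior is fully specified:

* two-sided p-values everywhere; zero-variance t-test degenerate cases:
  equal means → p = 1 (flag `degenerate`), unequal → smallest positive
  double (flag `zero_variance`);
* exact Wilcoxon rank-sum: dynamic program over the permutation null of
  the rank sum with midranks, two-sided p = min(1, 2·min(tails)); chosen
  automatically for group sizes ≤ 12; normal mode uses tie-adjusted
  variance and a 0.5 continuity correction;
* exact signed-rank: subset-sum dynamic program over 2^n sign
  assignments, zero differences dropped (Wilcoxon's convention),
  automatic for n ≤ 15;
* Kruskal–Wallis with tie correction, chi-square reference (df = g−1);
  Dunn z-tests on midranks with the pooled tie-corrected variance,
  unadjusted by default, BH across pairings optional;
* Benjamini–Hochberg step-up, order-preserving, capped at 1. (BH is not
  idempotent — re-adjusting adjusted values inflates them again; tests
  assert monotonicity and rank preservation instead.)

Each primitive is cross-checked in the test suite against an independent
route: brute-force enumeration oracles for the exact tests, and
scipy/statsmodels for the approximations and BH.

## Synthetic worlds

`generate_microarray` draws gene baselines uniformly over [2, 14] log2
units, gives DE genes independent per-group offsets ~ Normal(0, 0.8)
resampled to |offset| ≥ 0.3 (only genes expressed above the window floor
can be DE), per-gene noise sd log-normal with median 0.25 and log-sd 0.35,
Gaussian noise on the log2 scale, and plants invariant genes (equal group
means, sd 0.10) inside the window with a 0.5-unit margin.

Two presets encode the study-like worlds at desk scale (5000 genes;
`n_lowvar` = 1000 keeps the full-scale 20% retention ratio):

* **NK-like** — 0.5% DE, groups 19/16/10, 20 planted invariants,
  homogeneous variance. Post-filter shortlists run ≈ 600 genes.
* **Granulocyte-like** — 28% DE, groups 11/16/15, 4 planted invariants,
  plus two mechanisms absent from the NK world: 40% of genes sit at the
  unexpressed floor with technical sd compressed ×0.5, and expressed
  genes carry ×3 biological variance (the inter-patient heterogeneity of
  activated granulocytes). The least-variable pool is then dominated by
  sub-window floor genes, which the intensity window removes — collapsing
  the shortlist to a handful, reproducing in kind the published
  thousands-versus-18 contrast (measured shrinkage ≈ 125×). These preset
  constants are artifact conventions fixed once for that purpose.

`generate_targeted_assay` mirrors the validation designs (22/18 samples,
duplicate MFI with a multiplicative group effect, log-normal per-sample
levels, background floor at 15 MFI so LOD censoring occurs; triplicate Ct
with 0.25-cycle biological and 0.15-cycle technical noise).
`generate_paired_stimulation` shares donor baselines between arms and
shifts the stimulated arm by −log2(fold) plus donor response noise of
0.25 cycles — the spread implied by a published six-donor fold range of
0.7–1.1 (range ≈ 2.53 σ for n = 6 normal draws).

**What a green test does not establish.** The generators are exchangeable
Gaussian worlds: no batch effects, no probe-level artifacts, no
intensity-dependent bias beyond the floor mechanisms, no donor outliers.
Recovery results quantify the pipeline's behavior under its own model
assumptions, not array physics. And because planted invariants are
statistically indistinguishable from unplanted null genes, identity-level
recovery ("the candidates are exactly the planted genes") is not a
meaningful target — set-level properties (shortlist size, class purity,
verdict calibration) are.

## Numerical choices and degenerate inputs

* Closed intensity window (boundary values 4.0 and 11.0 are kept).
* sd ties in the variability rank break lexicographically by gene id.
* Genes with any missing value are excluded before filter 1.
* Detectability threshold is inclusive at `max_below_frac`.
* Exact-test p-values use integer-scaled midranks (×2), so tie handling
  is exact, not floating-point-fuzzy.
* All generators are pure functions of (parameters, seed); discovery is
  fully deterministic, so identical inputs give byte-identical reports.

## Known limitations

* No multi-gene normalization-factor computation (geometric-mean-of-panel
  approaches); the package selects and validates single reference genes.
* No qPCR efficiency estimation; Ct folds assume efficiency exactly 2.
* The GEO-Profiles reader handles the two tabular dialects described in
  `refstab.io`; it does not query GEO or parse SOFT archives.
* Upstream array processing (background correction, quantile
  normalization, probe annotation) is out of scope: the pipeline consumes
  an already-normalized matrix.
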