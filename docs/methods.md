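# Methods

This note documents the models behind each stage, the defaults that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Experimental design model

A sample is (treatment, phase, time, replicate) with treatments
{ctrl25, heat35, heat40} and phases {pre_heat, heat, recovery}. The
built-in grid has one pre-heat point, eight heat points (0, 0.5, 1, 2, 4,
8, 16, 24 h; 0 h = the moment the culture reaches temperature) and six
recovery points (0, 2, 4, 8, 24, 48 h), three biological replicates. The
control arm carries the same grid so every time point has a
contemporaneous 25 °C reference. Group adjacency (used by imputation) is
the order pre_heat → heat grid → recovery grid within a treatment, with
pre-heat adjacent to heat 0 h.

## Differential expression

Counts for gene *i* in sample *j* are modelled as negative binomial with
Var = μ + φμ². Each (treatment, time point) is contrasted against the
same treatment's pre-heat group with a two-parameter GLM
(log μ = log library size + β₀ + β₁·treated). The fit is iteratively
reweighted least squares vectorised across genes; coefficients and
standard errors agree with statsmodels' scalar GLM to ~1e-10 (checked in
the test suite). The Wald statistic β₁/se uses the standard normal
reference. Dispersion is method-of-moments per gene, moderated toward
the across-gene median with a prior weight of 10 pseudo-observations —
at n = 3 per group raw moment estimates are unstable and the moderation
keeps the null calibration conservative (null simulations flag ≲ 1.5 %
of genes against the 7 % acceptance bound).

The significance rule combines three criteria: |log₂FC| > 1 (model
coefficient / ln 2), BH-FDR < 0.05, and |ΔTPM| ≥ 1 between raw group
mean TPMs. BH runs within each contrast by default (`pool_fdr=True`
pools all contrasts). The mean-TPM difference criterion suppresses
large-fold calls on genes whose absolute abundance change is negligible.

A random-effect replicate structure was considered and rejected: with
three exchangeable replicates per group and a per-contrast model there
is no within-group structure left for a random effect to absorb.

## Surprisal-style decomposition

Replicate-averaged ln(TPM + 1) (genes × time points) is decomposed by
SVD. Component 0 (largest singular value) is the steady-state baseline;
components 1–3 are the retained constraints, reported as potentials
λ_α(t) = s_α·v_α(t) with gene weights G_iα and variance fractions
s_α²/Σs². The +1 offset admits zero TPM; at typical magnitudes
(TPM ≫ 1) it is negligible. Requires ≥ 4 time points.

## Proteome processing

Processing runs independently per treatment arm (the two heat time
courses are separate LC-MS campaigns and share no size factors).

*Normalization* is median-of-ratios: reference = per-protein geometric
mean over samples (complete rows only); a sample's size factor is the
median ratio to the reference. Note the output is defined only up to a
global constant under rescaling of raw columns — only relative factors
are identifiable.

*Replicate support*: proteins with no replicate group containing ≥ 2
observed values are dropped before quantitative analysis.

*Imputation* (log2 scale) distinguishes three cases per protein × group:
(1) partially observed groups draw missing replicates from Normal(group
mean, global sd), where the global sd is the pooled within-group sd over
all proteins; (2) wholly missing groups with ≥ 1 observed value in an
adjacent time point borrow their mean by k-nearest-neighbour matching
(k = 3) on group-mean profiles, restricted to donors observed at the
query group; distances and the borrowed value are offset-adjusted (each
profile centred on the shared groups) so a neighbour's abundance level
cannot leak into the imputed mean; (3) wholly missing groups whose
adjacent groups are also empty stay missing. Imputed cells are flagged
and never silently mixed with observations; masked-group simulations
show an average signed bias ≈ 0.05 log2 units. The per-group scatter of
an imputed mean is bounded below by the protein-specific decoupling
noise (~0.3 log2 at low transcript–protein coupling), which no
profile-neighbour estimator can remove; bias, not scatter, is therefore
the calibration target.

*Dunnett testing* compares each time point to pre-heat on log2
intensities, excluding non-proteotypic groups and proteins with any
originally missing replicate (imputed cells count as missing for this
purpose). For balanced designs the adjusted p is computed from the exact
equicorrelated multivariate-t distribution of the max-|T| statistic,
evaluated by Gauss–Hermite/Gauss–Legendre quadrature on a monotone grid
and interpolated per protein (agrees with scipy's implementation to
~1e-3; familywise error 0.047 on 5000 null proteins at α = 0.05).
Unbalanced designs use a seeded Monte-Carlo tabulation of the same law.

## Correlation networks and RMT thresholding

Protein groups from non-proteotypic peptides are duplicated to
singletons; profiles with no time structure are removed by one-way ANOVA
(p < 0.05) across time-point groups. Pearson correlations of
log-transformed intensities feed the threshold scan (|r| from 0.50 to
0.99 in steps of 0.01). At each candidate the sub-threshold entries are
zeroed, the eigenvalue spectrum is computed, near-duplicate eigenvalues
are collapsed (the zero/diagonal degeneracy of sparse matrices), and the
cumulative spectral function is unfolded with a cubic smoothing spline
(smoothing parameter 0.5·n). The nearest-neighbour spacing distribution
is binned at width 0.25 on [0, 3] and compared by chi-square distance to
the Poisson law e^(−s) and the Wigner surmise (πs/2)e^(−πs²/4); the
threshold is the first scan value where Poisson is closer. If no
transition occurs the scan maximum is returned with a flag. Thresholds
published for real datasets of this kind (ρ ≈ 0.82–0.87) are recorded
defaults for reruns, not reproduction targets — the exact unfolding
recipe and transition statistic of any given study are rarely printed,
and the choices here are documented conventions.

Modules are greedy-modularity communities of the |r| ≥ ρ* graph
(singletons discarded). Each module's eigenvector is the leading
right-singular vector of the z-scored member × time matrix, rescaled to
zero mean/unit variance; members negatively correlated with it carry
sign −1, and the global sign makes the mean member correlation positive.
Entities are (re)assigned by regressing their profile on each
eigenvector (F-test), BH over all entity × module tests, winner =
minimum FDR below 0.05, one module per entity. Enrichment expands each
entity's terms to all ancestors, so an entity counts once per ontology
level; p is the exact upper hypergeometric tail, BH across terms within
a module.

## Transcript–protein integration

Fold-changes are log₂(group mean / pre-heat mean); transcripts use TPM
with a +0.01 offset so silent genes stay defined, proteins use
normalized (imputed) intensities. The six windows are heat 0–1, 2–8,
16–24 h and recovery 0–2, 4–8, 24–48 h; window values are arithmetic
means of member time points. Pairing is by shared gene identifier
(ambiguous groups pair with each member). Per term (tree-expanded, to
match the enrichment convention) and window, Pearson r is computed over
the member pairs; terms with fewer than 3 pairs are suppressed since r
is meaningless below that. Densities of the per-term r values use a
Gaussian KDE with Silverman's bandwidth, floored at 1e-3 for degenerate
spread. The global scatter reports the all-pairs r, the OLS line of
protein on transcript fold-change, and the top-correlated term.

## Calculators

*Growth*: dilution events are relative OD drops exceeding half the
turbidostat band within one sampling step; log₂(OD₆₈₀) is fitted by
least squares per inter-dilution segment; the full segment is used (the
trace is exponential throughout under turbidostatic control). Doubling
time = 1/slope, reported only for positive slopes.

*Pigments*: the four printed linear equations, evaluated as-is; negative
concentrations are flagged, never clipped. chl a + chl b ≡ chl total is
an algebraic identity of the coefficients and is enforced by test.

*Fluorescence*: standard pulse-amplitude definitions (Fv/Fm, ΦPSII,
NPQ, qL with measured Fo′, QA redox = 1 − qL). LEF = I·ΦPSII·(PSII
fraction) in relative units — no absorptance calibration is applied, so
LEF comparisons are valid within an experiment only. Fm′ > Fm is flagged
as a measurement anomaly but still computed.

*Exponential fits* (ECS relaxation, P700⁺ re-reduction): least squares
of A·e^(−t/τ) + c with log-linear initialization, τ bounded to
(1e-5, 100) s; hitting a bound is flagged. The misfit flag trips when
the residual RMS exceeds 3× the noise floor (estimated from first
differences), catching multi-exponential traces forced through a single
exponential. Replicate P700 traces on a common time base are averaged
before fitting. Noise-free recovery is exact to ≤ 1e-6 relative error;
at 5 % noise the median τ error stays within 5 % (100 seeds).

*77 K spectra*: normalized to the 686 nm PSII peak; the PSI peak is the
maximum in a 705–725 nm window (nominal 714 nm, accommodating the blue
shift toward ~710 nm seen in heat-treated cells);
PSII % = 1/(1 + P_PSI)·100.

*FACS ploidy*: 256 log-spaced bins, 5-bin edge-corrected moving-average
smoothing, peaks by prominence (default 2 % of the maximum). The
background staining signal is proportional to mean cell volume
(background = κ·volume, κ calibrated on a reference sample); "cell size"
proportionality to volume rather than diameter is a modelling choice
exposed through κ. Corrected peaks are labelled 1C, 2C, 4C, … by nearest
power-of-two ratio to the smallest peak; a step ratio outside [1.7, 2.3]
leaves the peak unlabelled. Peak position is the histogram mode, not a
mixture-model mean.

## Synthetic data generator

The generator emulates the study conditions so every stage is testable
offline: NB counts (φ = 0.1, a typical bulk RNA-seq dispersion) around
length- and library-scaled means (libraries uniform in 0.8–1.2 M),
baseline log2 TPM ~ Normal(4, 2); four archetype expression programs
(early heat burst, sustained heat, recovery peak, early-recovery dip,
60 genes each by default, 1.5× amplified in the 40 °C arm) with all
other genes null; log-normal protein intensities for a gene subset with
replicate noise sd 0.3 log2; transcript–protein coupling ρ = 0.8 during
heat and 0.2 during recovery, implemented as protein group-level log2FC
= ρ·(transcript log2FC) + σ·AR(1) noise whose amplitude preserves the
across-gene correlation and whose AR(1) coefficient (0.9) encodes slow
protein turnover; missingness = 5 % random plus a logistic
intensity-dependent dropout centred at the 5th intensity percentile
(LFQ-like); a MapMan-style ontology with one coherent bin per archetype
plus random filler bins. Truth tables record every planted effect.

Not emulated: circadian structure (negligible under constant light and
turbidostatic control), peptide-level identification noise, batch
effects between arms, and chained mean–variance relationships beyond the
NB/log-normal forms. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative assumptions, not
robustness to artefacts absent from the generator.

## Problem sizes

Simulated checks default to 300–2000 genes, 100–150 proteins, and
5–20 seeds per Monte-Carlo claim; these sizes were chosen so planted
effects are comfortably detectable at the study's replicate number while
the whole suite stays desk-scale. Headline counts from real datasets
(tens of thousands of genes, module sizes, specific RMT thresholds)
depend on the deposited data and are out of scope here.
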