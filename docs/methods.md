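# Methods

`netreconfig` implements a complete analysis chain for time-resolved
functional brain-network reconfiguration from parcellated resting-state BOLD
time series, together with a synthetic-cohort generator that plants every
construct the chain is meant to recover. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not establish about real data.

## Preprocessing model

The entry point is a T x N matrix of region-averaged BOLD signals with a
known sampling interval (TR). Image-space preprocessing (realignment,
normalization, atlas resampling) is assumed done upstream; the package
starts where a parcellated time series and an fMRIPrep-style confounds table
exist.

**Framewise displacement.** FD follows the Power convention: the sum of
absolute backward differences of the three translations (mm) plus the three
rotations (radians) scaled by a 50 mm head radius. The first volume's FD is
defined as 0. Fast multiband sampling makes respiratory pseudomotion
(~0.3 Hz) visible in the realignment parameters, so exclusion decisions use
FD computed on low-pass-filtered traces (FD_filt). The filter is a
zero-phase Butterworth, default cutoff 0.2 Hz, order 2 — order 2 attenuates
a 0.3 Hz respiratory component to below a quarter of its amplitude after
the forward–backward pass while leaving drift below 0.05 Hz essentially
untouched; a first-order section does not reach that attenuation.

**QC rule.** A subject is excluded when mean FD_filt exceeds 0.2 mm or when
more than 20 volumes have FD_filt above 0.25 mm; both comparisons are
strict. When the data are decimated to a slower virtual TR, FD for the
motion covariate is computed on the decimated raw traces without filtering,
since at the slow rate the respiratory component is no longer separable.

**Confound models.** Two nuisance-regression models are built from the six
realignment parameters and the mean white-matter (WM), cerebrospinal-fluid
(CSF), and global signals:

* *36-parameter*: {6 motion, WM, CSF, global} ∪ their backward-difference
  derivatives ∪ the squares of all 18;
* *26-parameter* (lenient): the Friston 24-parameter motion expansion
  (6 motion, derivatives, squares of those 12) plus WM and CSF.

Derivative columns use backward differences with the first element set to 0.

**Denoising.** Per node: demean, linear detrend, zero-phase first-order
Butterworth band-pass (default 0.01–0.08 Hz). The confound columns receive
the identical detrend/band-pass treatment so regression cannot reintroduce
out-of-band variance. Both data and confounds are re-demeaned after
filtering because filter edge transients leave a DC residue that would
otherwise break the exact orthogonality of residuals and regressors.
Residualization projects the data onto the orthogonal complement of the
confound span using an orthonormal (QR) basis; rank-deficient confound sets
are reduced to a maximal independent subset by pivoted QR with a logged
warning. Voxelwise despiking from image-space pipelines has no parcel-level
equivalent here; an optional winsorization was considered and deliberately
left out of the default path.

**Down-sampling** is pure decimation: every k-th volume starting at index 0,
virtual TR = k x TR. No anti-alias filter is applied — the operation
emulates acquiring sparser data, not resampling a band-limited signal — and
any accompanying motion trace is decimated on the same grid.

## Time-varying connectivity

Connectivity layers are Pearson correlations within sliding windows. The
window taper (Hamming, w(n) = 0.54 − 0.46 cos(2πn/(L−1))) enters as
observation weights in a weighted Pearson correlation — weighted means and
covariances — which reduces exactly to the plain coefficient for a flat
taper. Two schemes are supported: overlapping windows advanced by a fixed
step (default 1 TR) and nonoverlapping windows that tile the series. For a
series of T samples the window counts are (T − L)/step + 1 (floored) and
T/L (floored) respectively. Edges touching a node with zero variance inside
a window are set to 0 and logged.

Connectivity *dynamics* are quantified per edge as the sample SD of the
windowed correlation across layers, computed on raw correlations (the
Fisher transform enters only later, for modularity). Observed SDs are
benchmarked against phase-randomized surrogates: the discrete-Fourier
phases of **all** nodes are rotated by one shared uniformly random phase
vector (conjugate-symmetric, DC and Nyquist untouched). This preserves each
signal's amplitude spectrum — hence autocorrelation and PSD — and every
pair's cross-spectrum — hence the full stationary cross-correlation
structure — while destroying time-localized coupling changes. Per edge,
p = #{SD_surr ≥ SD_real}/n_surrogates with no +1 correction, so p = 0 is
attainable; the default is 500 surrogates. Benjamini–Hochberg FDR at .05 is
applied over the N(N−1)/2 edges of one subject. A node's *dynamic degree*
is its count of significant edges; the companion percentage divides by the
N−1 edges incident on the node (an all-edges denominator is available by
flag, since printed degree percentages in the literature are ambiguous
about the denominator).

## Multilayer modularity

Windowed correlation layers are prepared by zeroing negative correlations,
Fisher z-transforming (atanh) the rest — values at r = 1 are capped at
atanh(1 − 1e−7) — and zeroing the diagonal. The ordinal multilayer
modularity of an L x N partition g is

    Q = (1/2μ) Σ_{ijsr} [ (A_ij^s − γ k_i^s k_j^s / 2m_s) δ_sr
                          + ω δ_ij [|s−r| = 1] ] δ(g_is, g_jr)

with per-layer Newman–Girvan null terms and 2μ = Σ_s 2m_s + 2ωN(L−1); an
empty layer's null term is defined as 0. The resolution γ and ordinal
coupling ω are constant across layers, both defaulting to 1; sweeps over
either are supported. Q is invariant under community relabeling.

Optimization is a generalized Louvain: starting from singletons, a
randomized greedy node-move phase sweeps layers and nodes in seeded random
order, moving each node–layer copy to the community (drawn from its own
layer plus its temporal copies' communities) with the largest modularity
gain; only strictly positive gains above 1e−10 are accepted, which
prevents cycling on flat landscapes (where the singleton partition is
returned). Converged communities are aggregated into super-nodes — the
aggregated quality matrix carries internal weight as self-loops and the
inter-layer coupling mass — and a generic greedy phase runs on the
aggregate, iterating until no merge improves Q. Because the optimizer is
stochastic, `best_of_runs` repeats it (default 100 runs, matching standard
practice; 10 is typical for sweep-style analyses) with deterministically
derived seeds and keeps the highest-Q partition, ties broken by lowest run
index. Labels are canonicalized to first-appearance order before
serialization so runs compare across platforms. On a randomized suite of
small instances (≤ 10 supra-nodes, where exhaustive enumeration over all
set partitions is feasible) best-of-20 attains the enumerated global
optimum on all instances.

From the best partition, *flexibility* is the fraction of adjacent-layer
transitions in which a node changes community (changes/(L−1)), and
*promiscuity* is the fraction of all communities in the partition that the
node joins at least once. Node metrics are averaged over resting-state
networks (RSNs) from an atlas mapping and over all nodes (global).

## Brain–behavior statistics

Associations between network metrics and questionnaire scores use partial
Spearman correlations: metric, score and numerically encoded covariates
(age, gender as indicator columns with the most frequent level as
reference — a "diverse" level is supported — and mean FD) are
rank-transformed; metric and score ranks are residualized against the
covariate ranks by OLS and the residuals' Pearson correlation is reported
with a two-sided p on n − 2 − k degrees of freedom. With no covariates
this is exactly the plain Spearman coefficient. The full correlation grid
crosses every questionnaire with every (metric, level) feature and applies
BH-FDR within each (metric, level, scale) family — the family definition is
configurable since analyses differ on what "all comparisons" means.

Questionnaire internal consistency uses Cronbach's alpha,
k/(k−1)·(1 − Σ item variances / total variance), with the Feldt
F-distribution confidence interval (df1 = n−1, df2 = (n−1)(k−1)). The power
of a correlational design is computed with the Fisher-z approximation:
power = Φ(z√(n−3) − z_crit) + Φ(−z√(n−3) − z_crit), z = atanh(ρ). Spatial
similarity of two nodal metric maps is their Spearman correlation across
nodes; scheme comparisons of degree use a paired t test.

## Synthetic cohorts

The generator emulates a fast multiband resting-state acquisition: 900
volumes at TR = 0.675 s, 100 nodes, signal power confined to 0.01–0.08 Hz
(defaults; every value configurable). Community signals are white noise
band-limited by zeroing FFT bins outside the passband — the analysis only
ever sees this band, so a richer generative model (hemodynamic forward
models, neural mass models) would add realism the verification cannot use.
Node i mixes its community's shared signal with private band-limited noise
as sqrt(w)·s_c + sqrt(1−w)·ε with w = snr/(1+snr), snr defaulting to 4.
Planted constructs:

* **Community switches** — instantaneous label reassignments at scheduled
  volumes (no transition ramp), giving exactly recoverable flexibility
  ground truth.
* **Dynamic edges** — a sinusoidally modulated cross-loading of the
  partner's community signal with period ≥ 2x any analysis window (default
  300 volumes), elevating windowed-correlation SD by construction.
* **Motion** — a smoothed random walk (slow drift; step 0.02 mm at the
  native TR) plus an optional ~0.3 Hz respiratory sinusoid on the
  translations (default amplitude 0.1 mm). With these defaults mean
  FD_filt at the native TR is ≈ 0.04 mm, i.e. a compliant young-adult
  cohort; the packaged test fixture at a slow TR uses smaller amplitudes
  because the aliased respiratory component there falls near the FD filter
  cutoff.
* **Behavioral scores** — three questionnaire-like scales (10, 6 and 13
  items). The coupling parameter is the target *rank* correlation between
  the score and a planted per-subject trait; since the trait and score are
  jointly Gaussian the generator mixes with the Pearson equivalent
  2 sin(πρ/6). Items are the scale total split by zero-sum deviations, so
  items always sum exactly to the total, with deviation variance solved so
  the expected inter-item correlation equals `inter_item_r` (default 0.5):
  σ_d² = Var(s)(1−r)/(k(1+r(k−1))). No effect-size anchor exists for a true
  metric–behavior coupling (the empirical literature's result is a null),
  so coupling magnitudes are free parameters, not defaults to trust.

One RNG stream per subject is split by purpose (signal/noise/motion/
scores/trait), so regenerating any one component never perturbs the others,
and per-subject seeds in the pipeline are stable hashes of (master seed,
subject id), so extending a cohort never changes existing subjects.

**What synthetic passes do not show.** The generator produces stationary
Gaussian band-limited signals between scheduled events; real BOLD has
1/f-like broadband structure, hemodynamic smoothing, non-Gaussian artifacts
and spatially structured noise. Recovery of planted switches therefore
demonstrates that the chain is correctly wired and sensitive at realistic
SNR, not that any particular effect exists in real data; type-I control
under the phase-randomization null is exact only for the stationary-
Gaussian class the null models.

## Problem sizes and defaults used in verification

Verification cohorts are scaled to desk size: 20 subjects, 20 nodes, 300
volumes at TR 2.025 s for surrogate type-I control (500 surrogates each)
and switch recovery; 10 subjects for the overlapping-vs-nonoverlapping
windowing comparison (step-1 windows of 50 samples vs nonoverlapping
windows of 20); 200 subjects for behavioral-coupling recovery; Louvain
restarts 5–20 in tests (the production default remains 100). The windowing
comparison reproduces the qualitative signatures expected of the method:
step-1 overlap shrinks flexibility magnitude by roughly an order of
magnitude (adjacent layers become nearly identical, and each layer border
crosses fewer community changes per transition) while the spatial pattern
across nodes stays positively correlated between schemes.

## Known limitations

* The greedy optimizer guarantees only local optima; the oracle equivalence
  is established on small instances and the restart strategy is the usual
  mitigation at scale.
* Surrogate p-values are granular at 1/n_surrogates and can be exactly 0;
  with 500 surrogates the smallest nonzero p is 0.002.
* Decimation aliases out-of-band structure by design; it is an emulation of
  slow acquisition, not a resampling operator.
* The correlation grid treats subjects as exchangeable; no hierarchical or
  longitudinal structure is modeled.
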