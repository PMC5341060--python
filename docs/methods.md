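# Methods

This note documents the statistical model the package implements, the
estimators and their numerical conventions, what the synthetic generators do
and do not emulate, and the design choices made where the method leaves room.

## The thresholding method

An acoustic signal enters as an amplitude series A(t); the analysis object
is the instantaneous energy ε(t) = |A(t)|², which is nonnegative and, up to
constants, has units of energy per time. Integer PCM samples are divided by
the full-scale magnitude of their width (32768 for 16-bit), so ε ∈ [0, 1]
per sample for real audio; normalization can be switched off, in which case
the type bin width below is interpreted in raw-unit energies.

The single free parameter is the threshold Θ, given as the percentage of
samples that remain at/above the resolved energy level (Θ = 80% ⇒ 20% of
samples below). Resolution uses the order statistic of rank
⌊qN⌋ + 1 with q = (100 − Θ)/100: the fraction of samples strictly below the
resolved value is as close to q as ties permit and never exceeds it. A
constant series has no resolvable threshold and is rejected as degenerate.

**Tokens and silences.** A token is a *maximal* run of samples with
ε strictly above the resolved level; ties count as silence (the defining
inequality is strict). Each token carries E_v (sum of ε over the run) and
T_v (run length over the sample rate). Conservation holds by construction:
Σ E_v equals the total above-threshold energy exactly (up to float
round-off), and tokens plus silences tile the series. Edge runs touching
the series boundary can optionally be dropped (`boundary_policy="drop"`);
the default keeps them, since for long recordings the truncation bias of
two edge runs is negligible and keeping them preserves the conservation
identities.

**Types.** Tokens map to types by linear binning of E_v with bin width
b = 0.01 into half-open bins [E₀ + kb, E₀ + (k+1)b). The origin E₀ defaults
to the smallest observed token energy; it can be fixed explicitly for
cross-file comparability. Duration plays no role in type identity: two
tokens in one energy bin are the same type regardless of their durations.
Bin edges are enforced exactly against the computed edge values, so a token
sitting on an edge goes to the upper bin irrespective of floating-point
rounding. Logarithmic type binning (labels counting log₁₀-widths) is
available as an alternative convention but is not the default; linear
binning is the convention the rest of the analysis assumes, and log binning
is otherwise used only for histogram *estimation* of heavy-tailed curves.

## The four laws and their collapses

Per threshold the package measures four curves, each with a rescaling that
removes the trivial Θ-dependence. Threshold-invariance of the rescaled
curves is the operational criticality diagnostic.

| law | curve | rescaling |
|---|---|---|
| energy release | log-binned density P_Θ(E) | E → E⟨E⟩/⟨E²⟩, P → P⟨E²⟩²/⟨E⟩³ |
| Zipf | N_Θ(n) = #types occurring exactly n times | n → nV/L, N → N/V |
| Heaps | V(k) = #distinct types among first k tokens | (L, V) → (L/L_max, V/V_max) |
| brevity | M_Θ(t) = type frequency vs. mean duration | t → t/⟨T⟩, frequencies unit-sum |

Notes on the choices that were genuinely open:

* The Zipf rescaling is the normalization-preserving reading of the
  "rescale by powers of V and L" recipe: with n → nV/L and N → N/V the sum
  rules Σ N(n) = V and Σ n·N(n) = L map to exactly 1 on both rescaled
  axes. Other groupings of V and L do not preserve any invariant.
* Heaps and brevity collapses use endpoint/mean rescaling, the simplest
  convention that maps every curve onto the unit box; for Heaps the
  collapsed curve's log-log slope is α′ = α/(1+α) when V ~ L^α.
* **Overlap score.** Collapse quality is scored as the mean over curve
  pairs of the *median* |Δlog₁₀ y| between the two rescaled log-log
  interpolants on their common support (0 = perfect collapse; order of
  curves irrelevant). The median, rather than a trapezoidal mean area, is
  deliberate: log-densities estimated from the sparse histogram tail
  fluctuate by large factors even when the underlying curves coincide, and
  a mean-area score is dominated by that estimation noise rather than by
  genuine shape disagreement. The score is a relative diagnostic — compare
  a signal against its shuffled surrogate at the same thresholds — not an
  absolute goodness measure.

**Exponent identities.** ζ = 1 + 1/z, ζ = 1 + α, α′ = α/(1+α), and the
prediction z ≈ φ linking the energy law to the Zipf rank law. These are
implemented as a pure-algebra fixpoint fill-in over an exponent set with
per-field provenance ("fitted" vs "derived"); measured values are never
overwritten, and the φ-prediction is only used when no measured Zipf
exponent is present. Out-of-domain inputs (z ≤ 0, α′ ≥ 1, ζ ≤ 1 on
inversion) raise immediately.

## Power-law estimation

* **Continuous MLE** (default): α̂ = 1 + n/Σln(x_i/xmin) over the tail
  x ≥ xmin. A user-fixed xmin accepts tails down to 2 points (the closed
  form is defined there); the KS scan keeps a 10-sample floor.
* **Discrete MLE**: numerical maximization of the Hurwitz-zeta likelihood,
  bounded search on α ∈ (1, 25], absolute tolerance 1e-8.
* **xmin selection**: KS-distance scan over observed values (thinned to at
  most 150 candidates, evenly spaced through the sorted sample, when the
  support is large), choosing the candidate minimizing the KS distance
  between the tail and its own best fit.
* **Fit window below a cutoff.** The energy law is a power law saturated by
  an exponential cutoff at scale E_ξ. Rather than a truncated-power-law
  likelihood, the fit window is restricted with `xmax` — but the
  likelihood used on the window is the power law *truncated to
  [xmin, xmax]* (normalization (α−1)/(xmin^{1−α} − xmax^{1−α}), α ≤ 1
  permitted). Fitting the untruncated form to a windowed sample biases the
  exponent upward by several tenths; the truncated form recovers the
  generating exponent to ~0.01 when the window stays a factor ≳20 below
  E_ξ. The matching truncated CDFs are used for KS distances and bootstrap
  sampling.
* **Goodness of fit**: parametric bootstrap. Draw n_tail points from the
  fitted tail model, refit, record the KS distance; p = fraction of
  replicate distances ≥ the empirical one, so small p rejects the power
  law. The conventional replicate count is 2500; the continuous fixed-xmin
  path is fully vectorized. Under the true model this p-value is
  approximately uniform (verified by a KS test across 200 seeded runs).
* **Confidence half-width**: 1.96 sd of the exponent over a nonparametric
  bootstrap of the tail (default 200 replicates).
* Every stochastic routine takes an explicit seed; the seed is recorded in
  the FitResult and in the pipeline's config echo, which suffices to re-run
  a report bit-identically.

Regression-type exponents (Heaps α, brevity β) use least squares on
log₁₀–log₁₀ coordinates. Heaps is fitted over the pre-saturation window
L ∈ [10, 0.1·L_max] by default, on ~200 log-spaced points so the dense
large-L region does not dominate; brevity over the initial decay region
(durations up to the median of the table).

## Synthetic generators

The generators provide ground truth for every stage; their defaults are the
package's study conditions.

**Voiced signal** (`synth_voice_signal`): alternating silence gaps and
voice events at 16 kHz.

* Gap durations: power law, exponent 2, shortest gap 1 ms, exponential
  cutoff ~1/8 s; gap samples are background-noise texture uniform on
  (0, 1e-6) in event-energy units.
* Event energies: power law of exponent φ = 1.15 with exponential cutoff
  1e6, smallest event energy 1000. The energy unit is set so that the
  default bin width resolves the smallest event into 1000 bins, matching
  the multi-decade dynamic range real voiced signals display; with the
  cutoff three decades above the smallest event, extracted token energies
  span ~6 decades.
* Durations: T = 64·(E/E_min)^{1/2} samples — the avalanche geometry
  E ~ T², which also makes longer events more energetic, the
  brevity-compatible direction — with lognormal scatter (σ = 1) around the
  coupling law, spreading the per-sample energy marginal over several
  decades (the fat-tailed marginal the method presumes). Durations span
  ~4–130 ms, so voice occupies ~90% of samples, consistent with a
  threshold convention in which Θ = 80% of samples sit above the level.
* Within-event profile: raised cosine with a 0.1 pedestal, hard-clipped
  away from zero and normalized to integrate to exactly E. The profile is
  *unimodal*, so an event contributes at most one token at any threshold;
  the generator therefore returns an exact ground-truth event list plus the
  `design_theta_percent` that resolves the threshold precisely between the
  noise floor and the weakest event sample — at that threshold segmentation
  recovers every event exactly. An optional lognormal within-event texture
  (`amplitude_sigma`) makes events multimodal and fragmenting, for
  experiments on threshold decimation.

What this generator does **not** emulate: pitch periodicity, formant
structure, amplitude correlations across events, genuine scale-invariant
(SOC) dynamics, or recording artifacts. Consequently its threshold collapse
is only approximate — thresholds that cut into events distort the curve
near its lower edge in a Θ-dependent way — and passing the null-model
contrast here shows that the pipeline *discriminates* temporal structure
from its absence, not that the generator is critical. Conclusions about
real voice require real recordings.

**Power-law samplers**: continuous inverse-CDF sampling (exponential cutoff
via rejection with acceptance e^{−(x−xmin)/cutoff}); discrete zeta-law
sampling by exact inverse CDF over a 1e6-value table with the (tiny)
remaining tail mass drawn from the continuous approximation.

**Zipf streams** (`zipf_stream`): i.i.d. draws with p(r) ∝ r^−z. For a
finite vocabulary the law is normalized over it. For an *unbounded*
vocabulary the first 1e6 ranks are sampled exactly from the zeta-normalized
law and draws falling in the remaining tail mass each receive a fresh
unique label. This matters: for z close to 1 (the Heaps-relevant regime)
roughly a quarter of the total mass lies beyond rank 1e6, and truncating
plus renormalizing instead depresses vocabulary growth well below the
asymptotic V ~ L^{1/z}. With the lazily-extended scheme a stream of 1e6
tokens at z = 1/0.91 recovers a vocabulary-growth slope of 0.91 over
L ∈ [100, 1e5]. Deep-tail draws are treated as pairwise distinct; their
true collision probability contributes < 1% to V at these sizes.

**Brevity tables** (`brevity_synth`): type mean-durations from a power law
(5 ms lower scale), frequencies assigned ∝ t^−β and normalized — the table
decays with exponent exactly β, so recovery tests the fitting window and
regression machinery, not sampling noise.

## Degenerate inputs and edge conventions

* Constant energy series → degenerate-threshold error; zero tokens at a
  threshold is legal and reported as an empty entry (the pipeline fails
  only if *every* threshold is empty).
* Single-token distributions are rejected; single-valued samples log-bin
  into one bin of width √ratio on each side.
* Brevity rows with exactly tied mean durations are merged so the abscissa
  stays strictly increasing.
* Curves with disjoint rescaled supports score their median-level offset
  rather than an interpolated one.
* All half-open interval logic is enforced against computed bin edges, not
  against raw floating-point quotients.

## Known limitations

* The energy-law exponent fitted on tokens extracted at intermediate
  thresholds (where events are truncated by the threshold) is a windowed
  effective exponent; the clean recovery target is the design threshold.
* The discrete bootstrap sampler uses the standard rounding approximation
  of the zeta tail; for xmin = 1 and exponents near 1 its small-k bias is
  visible in p-values at very large n_boot (the exact table sampler is used
  for data generation, not for bootstrap replicates, for speed).
* Likelihood-ratio comparisons against alternative heavy-tailed families
  (lognormal, stretched exponential) are out of scope; the GOF p-value
  tests only the power-law hypothesis itself.
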