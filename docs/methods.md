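# Methods

## The surrogate model

The quantity of interest is the probability P(EB) that a single stochastic
realization of a ventricular myocyte model produces an ectopic beat,
detected as the membrane potential strictly exceeding 0 mV within the
simulated window. For a batch of n realizations at one set of myocyte
model inputs (MMIs), the event count k is binomial with parameter P(EB),
and the surrogate models

P(EB | x) = logistic(b₀ + Bᵀ φ(x)),

where φ(x) are the MMIs min–max scaled to [0, 1] over a fixed region of
interest (ROI) plus a subset of pairwise quadratic terms (squares and
cross products of the scaled coordinates). Scaling bounds are frozen into
the model at fit time and serialized with it; prediction never re-derives
them from data, and inputs outside the ROI scale to values outside [0, 1]
without clipping, so the model extrapolates smoothly. That extrapolation
is load-bearing: the normal-myocyte G_K1 uncertainty study centres the
uncertain input exactly on the ROI boundary, with half its probability
mass outside.

Fitting is maximum likelihood on the binomial counts via iteratively
reweighted least squares — identical to the ML solution on expanded
per-realization Bernoulli rows at a fraction of the cost. Convergence is
declared when the relative log-likelihood change falls below 1e-10
(at most 100 iterations); a diverged fit with any |weight| > 1e3, or a
dataset whose event fractions are all exactly 0 or all exactly 1, raises
a distinct complete-separation error. A dataset with constant event
fraction strictly inside (0, 1) is accepted: it identifies the
intercept-only solution (zero weights) and is a useful degenerate case
rather than an error. Standard errors are Wald SEs from the observed
information matrix at the optimum; the likelihood includes the binomial
coefficients so reported log-likelihoods are absolute, not relative.
Feature importance is ranked by |weight| on the scaled features (which is
what makes weights comparable across axes); exact ties — which do not
arise in practice — keep the canonical feature order.

The logistic link is evaluated with `scipy.special.expit`, which is stable
for the linear-predictor magnitudes (~|40|, and far beyond) this model
produces.

## The two-iteration sampling design

The probability surface over the ROI is mostly plateau (P ≈ 0 or ≈ 1)
with a narrow transition domain between; uniform sampling alone starves
the fit of information exactly where the model matters. The pipeline
therefore runs:

1. *Iteration 1*: `sets_per_iteration` (default 100) MMI sets uniform over
   the ROI, `realizations_per_set` (default 100) realizations each, and a
   linear-features-only preliminary fit.
2. *Iteration 2*: the same number of sets drawn by rejection sampling —
   uniform proposals kept iff the preliminary model predicts a probability
   inside the transition band — and another round of batches.
3. *Selection*: all 2^(d(d+1)/2) quadratic subsets (1024 for d = 4), each
   keeping all linear terms, are fitted to the pooled observations; the
   subset minimising the selection criterion wins. Ties break toward fewer
   terms, then lexicographically, making the choice independent of
   enumeration order. Candidates that fail to fit are skipped with a
   warning. Exhaustive search is capped at d = 5 axes (32 768 fits).

The transition band defaults to [0.025, 0.975]: at 100 realizations per
set, probabilities outside that band are not reliably distinguishable
from 0 or 1, so it is the natural "resolvable" transition domain for the
default batch size. It is configurable. Rejection sampling is used rather
than any inversion of the transition region because the region is an
implicit nonlinear set in 4-D; rejection is exact, and the sampler raises
(advising a wider band) if the implied acceptance rate drops below 1e-5.

The selection criterion defaults to Bozdogan's consistent AIC,
−2 lnL + k(ln N + 1), with N = the total number of Bernoulli trials (Σn);
both the criterion (`caic`/`aic`) and the sample-size convention
(`total_trials`/`n_sets`) are configuration switches, since reasonable
conventions differ and the choice is deliberately exposed rather than
hard-coded.

## The toy simulator

`toy_myocyte` stands in for the expensive stochastic myocyte model so the
pipeline can be exercised and validated at desk scale. Its ground truth is
an explicit logistic-in-quadratic-features surface (by default the
reconstructed published surface, so synthetic experiments live in the same
probability landscape: a narrow transition domain inside a mostly-plateau
ROI). Each realization draws a Bernoulli event and emits a schematic
triangular voltage trace — rest (−93.4 mV) to peak and back within the
800 ms window, peak +35 mV for events and uniform in [−80, −40] mV for
subthreshold DADs — so the strict >0 mV detection rule is exercised on
actual trace data. The comparison is strict ("exceeds 0 mV"), so a trace
peaking at exactly 0 mV is not an event.

What the toy model emulates: binomial sampling noise at realistic batch
sizes, the plateau/transition geometry, and the detection rule. What it
does not emulate: any Ca²⁺ release biophysics, waveform morphology,
realization-to-realization correlation, or model misspecification — the
true surface *is* logistic in the features, so pipeline-recovery results
show that the machinery works, not that a logistic surrogate suffices for
any particular biophysical model.

Randomness: each batch derives two named substreams (event draws, waveform
draws) from one `SeedSequence`, so the event count is identical whether or
not traces are materialised, and any (point, n, seed) triple reproduces
exactly. This is cheaper than per-realization substreams with the same
reproducibility guarantees.

## The reconstructed published model

The published surrogate is specified by 10 importance-ranked weights ± SE
on scaled features but no intercept. The intercept is derived from the
published anchor: the MMI set (150 nM, 500 μM, k_RyR_sf = 1,
G_K1_sf = 0.338) has P(EB) = 0.5, i.e. zero linear predictor, giving
b₀ = −Bᵀφ(anchor) ≈ −44.010. The reconstruction is validated only through
the probabilities the study prints — 0.02 / 0.97 at the neighbouring G_K1
values, 0.76 at the default diastolic set, 0.008 / 0.918 at the
normal/heart-failure G_K1 points, and the Monte Carlo means and SDs
0.0294 ± 0.0611 and 0.8788 ± 0.1183 — all of which `replicate_scenarios`
recomputes within 0.005 (points) and 0.003/0.005 (MC means/SDs). Whether
the original intercept satisfied the anchor exactly is unknowable from the
printed weights; agreement on all nine scenario quantities is the
operative check. The printed "±" values are treated as Wald SEs.

## Uncertainty propagation

Uncertain MMIs are independent normals N(mean, σ²) in native units; draws
are *not* truncated or clipped at the ROI (see extrapolation above).
Propagation is Monte Carlo with 10⁶ draws by default. When exactly one
input is uncertain and appears in no quadratic term, the linear predictor
is itself normal and P(EB) is exactly logit-normal; `analytic_distribution`
returns that closed form (histogram masses as normal-CDF differences,
moments by 201-node Gauss–Hermite quadrature) and signals not-applicable
otherwise, in which case callers fall back to Monte Carlo.

The induced distribution on [0, 1] is summarised by a 100-equal-bin
histogram; Shannon entropy is computed over bin masses in nats (bin count
and the log base are parameters). Entropy rather than variance is the
headline uncertainty measure because the distribution becomes bimodal at
large input uncertainty, where variance understates how uninformative the
prediction is.

Modality is a coarse three-way label on the smoothed histogram (3-bin
moving average, reflect-padded so edge bins are not deflated):

* *uniform_like* if the largest smoothed bin mass is within a factor 3 of
  the median bin mass — a genuinely flat histogram has all bins near
  1/n_bins, and any pronounced peak blows this ratio up. The ratio is
  taken against the median rather than the minimum because even a
  textbook near-uniform logit-normal dips toward zero in the outermost
  bins, which would defeat a max/min test.
* otherwise *bimodal* if both outermost bins are strict local maxima *and*
  each holds ≥ 2% of the total mass — bimodality here means probability
  concentrating on *both* plateaus, and the mass floor prevents a
  sub-percent sliver at one plateau from flipping the label of a clearly
  one-sided distribution.
* otherwise *unimodal* (one peak, wherever it sits, including hard against
  one plateau).

All three thresholds (window, ratio, edge-mass floor) are keyword
arguments.

A caution on the "mean converges to 0.5" phenomenology: the convergence of
the propagated mean toward 0.5 with growing input uncertainty is real but
asymptotic. For an off-centre set whose transition midpoint sits Δ away
from the input mean, the large-σ mean approaches Φ(±Δ/σ); with Δ ≈ 40 μM
(set 2 of the SR-load study) the mean at σ = 100 μM is ≈ 0.34, still
0.16 away from the limit. Only the centred anchor set is at 0.5 for
every σ.

## Problem sizes and numerical choices

* Pipeline-recovery experiments run at the published design scale
  (2 × 100 training sets × 100 realizations, 100 test sets); the in-package
  IRLS makes the 1024-candidate exhaustive selection cost roughly a second.
* Unit tests use 10⁵–2×10⁵ Monte Carlo draws with tolerances ≥ 3 standard
  errors (SE of a mean on [0, 1] is ≤ 0.5/√n); end-to-end checks use the
  full 10⁶.
* IRLS working weights are floored at 1e-12 to keep the weighted
  least-squares step finite on plateau observations.
* The logit-normal density is validated by quadrature normalization
  (|∫−1| < 1e-6) and by Kolmogorov–Smirnov distance < 0.005 between 10⁶
  Monte Carlo draws and the analytic CDF.
* Model files are schema-versioned JSON carrying the space bounds, feature
  names, intercept, weights, SEs and provenance ("fit" vs "reconstructed");
  observation files are plain CSV in native units. Exports are CSV/JSON
  only; no plotting layer is included.

## Known limitations

* The toy waveforms are placeholders; nothing about DAD/EB morphology is
  physiological beyond the rest value and the 0 mV threshold semantics.
* The surrogate is only as good as the logistic-in-quadratic-features
  family; against a real myocyte model the fit quality must be re-checked
  (the validation metrics exist for exactly that purpose).
* Uncertainty propagation assumes independent normal inputs; correlated or
  non-normal measurement error is out of scope.
* Exhaustive feature selection scales as 2^(d(d+1)/2) and is capped at
  d = 5 axes.
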