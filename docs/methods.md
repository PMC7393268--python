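# Methods

`behavts` analyzes the temporal structure of densely sampled behavioral data
— annotation-derived event streams, nominal state series and binary spike
trains — with three complementary techniques: burstiness analysis of
inter-onset intervals, chromatic/anisotropic cross-recurrence quantification
of dyadic interaction, and point-process Granger causality among multivariate
behavioral spike ensembles. This note records the models, the conventions
that were genuinely open choices, the defaults and their rationale, and the
limits of what the simulation-based tests demonstrate.

## Data model and conversion conventions

Samples are 0-based and sample `i` covers the half-open interval
`[i/rate, (i+1)/rate)`. When events are sampled onto a grid
(`events_to_timeseries`) a sample carries the code of the event overlapping
its **midpoint** `(i+0.5)/rate`. These two conventions together make
event → timeseries → event a true identity for sample-aligned,
non-overlapping events (a randomized property test exercises this); they are
conventions, not facts about annotation software, and are therefore isolated
here. Event offsets are treated as exclusive (half-open events); annotation
tools differ on this and exports with inclusive offsets should be padded by
one frame before import.

Overlapping events are rejected by default. Many coding schemes are
exclusive by construction; where they are not, `last_onset_wins=True`
resolves a sampled instant in favor of the later-onset event. The
background/no-event code is 0 everywhere; negative integers are reserved for
signed match categories in the cross-recurrence matrix, which lives in its
own type and never flows back into a `NominalTimeSeries`.

Timestamps may be plain seconds, `hh:mm:ss(.fff)`, or Unix epoch seconds
(wearable-sensor exports); epoch times (≥ 1e8 s) are shifted so the earliest
onset is 0. Interval statistics use the n−1 (sample) normalization for
σ_τ, matching the default of the numerical environments these analyses are
usually run in.

`presence_resample` reduces region-of-interest annotations to per-code
presence/absence bins (bin = 1 iff any matching event overlaps it). The
default bin width in the examples is 333 ms, a common choice for gaze and
manual-activity streams; it is a resolution parameter, not a constant of the
method.

## Burstiness

For an inter-onset interval (IOI) distribution with mean μ_τ and standard
deviation σ_τ,

    B = (σ_τ − μ_τ) / (σ_τ + μ_τ)  ∈ [−1, 1].

B = −1 iff σ_τ = 0 (periodic); B ≈ 0 for a memoryless process (exponential
IOIs have σ = μ); B > 0 for right-skewed, heavy-tailed IOI distributions.
B is invariant under rescaling of the intervals, so the sampling rate only
matters for interpretation, not for the value.

The plain estimator is biased at small interval counts n. The finite-size
variant used here, with r = σ_τ/μ_τ,

    B_n = (√(n+1)·r − √(n−1)) / ((√(n+1) − 2)·r + √(n−1)),

converges to B as n grows; empirically the two agree to better than 0.05
once n exceeds ~100–200, which is the package's recommended regime for
reporting either.

The memory coefficient M is the lag-1 Pearson autocorrelation of consecutive
IOIs. For a constant interval sequence it is 0/0 and is reported as
*undefined* rather than 0 — a perfectly periodic train has no meaningful
memory, and silently mapping it to 0 would place it among memoryless trains
in the (M, B) plane.

Because B's magnitude is not comparable across datasets with different n and
rates, `classify_regime` offers a bootstrap classification instead of raw
thresholds: `replicates` (default 1000) exponential IOI sets of the train's
own n and μ_τ are simulated, and the central `coverage` (default 95%)
quantile interval of their B values bounds the Poisson regime at that n;
the train is labelled bursty above, periodic below. The report surfaces n
next to every B and makes no cross-dataset comparability claim.

## Chromatic and anisotropic CRQA

Two equal-length nominal series x (horizontal axis) and y (vertical axis)
define an N×N cross-recurrence matrix `rec[i, j] = rule(x_j, y_i)`. A
`MatchRule` assigns each ordered code pair a signed integer match category
(0 = no match). The default rule is plain code equality (one category,
background excluded); multi-category ("chromatic") rules such as +1 for one
joint state and −1 for another are supplied as a small mapping table.
Unequal-length inputs are an error, never silently truncated (the CLI has an
explicit `--truncate`).

Chromatic rates: `RR_c = #{rec = c}/N²` (canonical) and
`rRR_c = #{rec = c}/#{rec ≠ 0}` (relative), so `Σ_c rRR_c = 1` whenever any
match exists and `rRR_c = RR_c/Σ RR_c` identically.

Anisotropic measures are computed per orientation from the distribution of
maximal run lengths (vertical: within columns; horizontal: within rows) of
the **binarized** matrix — all match categories are treated as equal for the
line analysis, with per-category line measures available behind a flag:

* `LAM` = (points in runs of length ≥ l_min) / (all recurrent points),
* `TT`  = mean length of qualifying runs,
* `Max_L` = longest qualifying run,
* `Ent_L` = Shannon entropy (natural log) of the qualifying run-length
  distribution.

`l_min = 2` by default: a single isolated cell is not a "pattern" in either
orientation. Runs touching the matrix border count as ordinary runs (no edge
correction). The vertical measures of crqa(x, y) equal the horizontal
measures of crqa(y, x) exactly, which the tests assert; all five measures
are verified cell-for-cell against a brute-force run-enumeration oracle on
random small matrices.

## Point-process Granger causality

Each variable's per-bin event indicator is modeled by a Bernoulli GLM with a
logit link on the lagged values (lags 1..p) of **all** m variables,
including the target's own history. The Bernoulli-logit likelihood is the
canonical choice for presence/absence bins; at the small per-bin rates
typical of 333 ms behavioral bins it is practically indistinguishable from a
log-link point-process intensity model.

*Order selection.* p is chosen per target by AIC over full models with
p = 1..p_max, fitted on the common outcome window t ≥ p_max so the AIC
values are comparable; ties break toward the smaller p. `p_max` defaults to
3 bins (≈ 1 s at 3 Hz); the identifiability guard
T − p_max ≥ 10·(1 + m·p_max) should hold before trusting the asymptotics.

*Test.* For source X and target Y the reduced model drops X's lag block
only. Both models are fitted on identical rows and

    Δ = deviance(reduced) − deviance(full) ~ χ²_p under the null,

with df = p excluded lags. The influence *magnitude* is the signed LR
statistic, sign(Σ X-lag coefficients in the full model)·Δ — the sign
convention gives "significantly positive/negative influence" semantics and
is isolated in one function so it can be swapped. All m(m−1) ordered-pair
p-values are corrected together by Benjamini–Hochberg at level q (default
0.05); significance is coded 1/−1/0.

*Numerical choices.* Constant design columns (e.g. a never-active source)
are dropped and recorded, with zero coefficients reported. If the IRLS fit
fails to converge or diverges (complete separation), the model is refitted
with a small ridge penalty (10⁻⁴) via L-BFGS and the *unpenalized* deviance
at that optimum is used, which makes the resulting LR statistic — and hence
the pair's p-value — conservative; such fits are flagged. Negative Δ beyond
−10⁻⁶ is logged and clipped at 0.

*Calibration caveat.* The χ² null calibration is asymptotic: it requires the
event count to be large relative to the parameter count, and AIC order
selection performed on the same data adds a small post-selection inflation
of the type-I rate. In null simulations the pairwise test is accurately
calibrated at T = 2000 bins with p fixed (KS agreement with χ²_p, type-I
rate within the binomial 99% interval of 0.05), and BH keeps the average
false-discovery proportion at q with p_max = 2; at T ≲ 1000 bins or with
deeper selection windows the rejection rate runs one to a few percentage
points above nominal. Practical guidance: with m = 3–5 variables, prefer
sessions of ≥ 2000 bins (≈ 11 min at 3 Hz) and a modest p_max.

## Synthetic data

The generators define the conditions under which everything above is
tested; all are deterministic given their seed.

* `simulate_periodic_train` — onsets at k·ioi with optional rounded uniform
  jitter (< ioi); jitter 0 gives B = −1 exactly, small jitter keeps
  −1 < B < 0.
* `simulate_poisson_train` — i.i.d. Bernoulli(rate) bins, the discrete-time
  Poisson process (geometric IOIs). Note the discretization makes B slightly
  negative rather than exactly 0: r = √(1−rate) < 1, e.g. ≈ −0.026 at
  rate 0.1. This sits well inside the |B| < 0.05 band used for the random
  regime and vanishes as the rate → 0.
* `simulate_bursty_train` — lognormal IOIs with arithmetic mean `mu` and
  shape `sigma_log` (default regime σ ≈ 1.5), rounded to whole samples with
  a floor of 1. Rounding (rather than ceiling) is used so the σ→0 limit
  degenerates to an exactly periodic train. The lognormal is one convenient
  heavy-tailed family; any family with r > 1 lands in the bursty regime.
* `simulate_coupled_nominal_dyad` — partner A is a sticky Markov chain over
  K categories (self-transition 0.8); partner B copies A at lag `lag` with
  probability `follow_prob`, else steps its own chain. Equality-rule RR is
  monotone in `follow_prob`; at follow_prob 1, lag 0 the streams are
  identical and RR = Σ_c π̂_c² exactly.
* `simulate_coupled_spike_ensemble` — the generative twin of the GC model:
  each bin is Bernoulli(logistic(logit(base_rate) + planted lagged
  effects)), with connectivity given as lag-resolved coefficient matrices.
  This closes the recovery loop: planted edges (e.g. +2 at lag 1) are
  re-estimated with the correct sign. Parameterizations that pin per-bin
  probabilities at 0/1 for > 10% of bins trigger a warning.

What the generators do **not** emulate: non-stationarity (session-level
drifts, fatigue), annotation noise and coder disagreement, unequal trial
lengths, and continuous-valued signals. Tests passing on these generators
show the estimators are correct under their stated models, not that any
particular empirical stream satisfies those models.

## Problem sizes in the test suite

The suite's simulation scales were chosen as the smallest sizes at which
the asymptotic claims they check are expected to hold with comfortable
Monte-Carlo margins: null calibration over 500 independent pairs at
T = 2000; edge recovery over 50 seeds at T = 3000; FDR control over 200
null ensembles (m = 3, T = 2000); estimator convergence over 50 seeds at
n = 200 intervals; oracle equivalence on 100 random matrices up to 50×50.

## Known limitations

* Continuous-valued (metric) recurrence analysis with embedding/radius and
  diagonal-line measures are out of scope, as is continuous-valued
  (Gaussian VAR) Granger causality — established toolboxes cover both.
* Granger analysis assumes one uninterrupted session; trials of unequal
  length are not supported.
* The GC magnitude (signed LR statistic) and sign rule are conventions;
  magnitudes are comparable within an analysis, not across datasets.
* MAT input is supported only for simple sample-data layouts; all native
  I/O is CSV.
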