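"""Seeded generators for every input class the analyses consume.

Spike trains spanning the three burstiness regimes (periodic, Poisson,
bursty), coupled two-partner nominal category streams for cross-recurrence
analysis, and multivariate binary ensembles driven by a history-dependent
logistic GLM with known directed connectivity for Granger-causality
parameter recovery. Every generator is deterministic given its seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import BinarySpikeTrain, NominalTimeSeries
from .errors import InvalidInputError
from .granger import SpikeEnsemble

__all__ = [
    "simulate_periodic_train",
    "simulate_poisson_train",
    "simulate_bursty_train",
    "simulate_coupled_nominal_dyad",
    "simulate_coupled_spike_ensemble",
]


def _train_from_onsets(onsets: np.ndarray, rate: float, label: str) -> BinarySpikeTrain:
    onsets = np.unique(onsets.astype(int))
    values = np.zeros(int(onsets[-1]) + 1, dtype=int)
    values[onsets] = 1
    return BinarySpikeTrain(values, rate=rate, label=label)


def simulate_periodic_train(
    ioi: int,
    n_onsets: int,
    jitter: float = 0.0,
    seed: int | None = None,
    rate: float = 1.0,
) -> BinarySpikeTrain:
    """Periodic spike train: onsets at k·ioi plus optional rounded uniform
    jitter in [−jitter, jitter] samples. jitter = 0 gives exactly constant
    inter-onset intervals (burstiness −1)."""
    if ioi < 1:
        raise InvalidInputError("ioi must be >= 1 sample")
    if jitter < 0:
        raise InvalidInputError("jitter must be >= 0")
    if jitter >= ioi:
        raise InvalidInputError("jitter >= ioi would allow onset-order violations")
    if n_onsets < 1:
        raise InvalidInputError("need at least one onset")
    base = np.arange(n_onsets) * ioi
    if jitter > 0:
        rng = np.random.default_rng(seed)
        base = base + np.round(rng.uniform(-jitter, jitter, size=n_onsets)).astype(int)
    base = base - base.min()
    return _train_from_onsets(base, rate, "periodic")


def simulate_poisson_train(
    rate: float,
    T: int,
    seed: int | None = None,
    sample_rate: float = 1.0,
) -> BinarySpikeTrain:
    """Memoryless train: i.i.d. Bernoulli(rate) per bin — the discrete-time
    Poisson process, whose inter-onset intervals are geometric."""
    if not 0 < rate < 1:
        raise InvalidInputError("event rate must lie in (0, 1) per bin")
    if T < 1:
        raise InvalidInputError("T must be >= 1")
    rng = np.random.default_rng(seed)
    values = (rng.random(T) < rate).astype(int)
    return BinarySpikeTrain(values, rate=sample_rate, label="poisson")


def simulate_bursty_train(
    mu: float,
    sigma_log: float,
    n_onsets: int,
    seed: int | None = None,
    rate: float = 1.0,
) -> BinarySpikeTrain:
    """Bursty train: lognormal inter-onset intervals with arithmetic mean
    ``mu`` samples and shape ``sigma_log``, rounded to whole samples (>= 1).

    A heavy right tail (sigma_log around 1–2) mixes many short intervals with
    rare long gaps, pushing the coefficient of variation above 1 and the
    burstiness parameter above 0.
    """
    if sigma_log <= 0:
        raise InvalidInputError("sigma_log must be > 0")
    if mu <= 0:
        raise InvalidInputError("mean interval must be positive")
    if n_onsets < 2:
        raise InvalidInputError("need at least two onsets")
    rng = np.random.default_rng(seed)
    # choose the underlying normal mean so the lognormal's arithmetic mean is mu
    mu_log = np.log(mu) - sigma_log**2 / 2.0
    iois = np.round(rng.lognormal(mu_log, sigma_log, size=n_onsets - 1)).astype(int)
    iois = np.maximum(iois, 1)  # discretized to samples, floor of one sample
    onsets = np.concatenate(([0], np.cumsum(iois)))
    return _train_from_onsets(onsets, rate, "bursty")


def simulate_coupled_nominal_dyad(
    N: int,
    n_categories: int = 5,
    follow_prob: float = 0.5,
    lag: int = 0,
    seed: int | None = None,
    self_stick: float = 0.8,
    rate: float = 1.0,
) -> tuple[NominalTimeSeries, NominalTimeSeries]:
    """Two coupled nominal category streams emulating a dyadic interaction.

    Partner A runs a sticky Markov chain over categories 1..K (self-transition
    probability ``self_stick``, otherwise a uniform switch). Partner B at time
    t copies A at t−lag with probability ``follow_prob`` and otherwise draws
    from its own sticky chain. Higher follow_prob yields higher equality-rule
    recurrence between the streams.
    """
    if n_categories < 2:
        raise InvalidInputError("need >= 2 categories")
    if not 0 <= follow_prob <= 1:
        raise InvalidInputError("follow_prob must lie in [0, 1]")
    if lag < 0:
        raise InvalidInputError("lag must be >= 0")
    if N < 1:
        raise InvalidInputError("N must be >= 1")
    rng = np.random.default_rng(seed)
    cats = np.arange(1, n_categories + 1)

    def step(state):
        if rng.random() < self_stick:
            return state
        choices = cats[cats != state]
        return int(rng.choice(choices))

    a = np.empty(N, dtype=int)
    b = np.empty(N, dtype=int)
    a[0] = int(rng.choice(cats))
    b[0] = int(rng.choice(cats))
    for t in range(1, N):
        a[t] = step(a[t - 1])
    for t in range(N):
        if t - lag >= 0 and rng.random() < follow_prob:
            b[t] = a[t - lag]
        elif t > 0:
            b[t] = step(b[t - 1])
    return (
        NominalTimeSeries(a, rate=rate, label="partnerA"),
        NominalTimeSeries(b, rate=rate, label="partnerB"),
    )


def simulate_coupled_spike_ensemble(
    m: int,
    T: int,
    connectivity: np.ndarray | None = None,
    base_rate: float = 0.1,
    seed: int | None = None,
    labels: list[str] | None = None,
    sample_rate: float = 3.0,
) -> SpikeEnsemble:
    """Multivariate binary ensemble from a history-dependent logistic GLM.

    ``connectivity`` is either an (m, m) matrix of lag-1 coefficients or an
    (L, m, m) stack where entry [l, i, j] is the effect of variable i at lag
    l+1 on variable j's log-odds. Each bin of each train is drawn
    Bernoulli(logistic(intercept + planted lagged effects)) with intercept
    logit(base_rate); a positive planted coefficient is an excitatory directed
    edge recoverable by the Granger analysis.
    """
    if not 0 < base_rate < 1:
        raise InvalidInputError("base_rate must lie in (0, 1)")
    if m < 2 or T < 2:
        raise InvalidInputError("need m >= 2 variables and T >= 2 bins")
    if connectivity is None:
        W = np.zeros((1, m, m))
    else:
        W = np.asarray(connectivity, dtype=float)
        if W.ndim == 2:
            W = W[None, :, :]
        if W.shape[1:] != (m, m) or W.ndim != 3:
            raise InvalidInputError("connectivity must be (m, m) or (L, m, m)")
        if not np.isfinite(W).all():
            raise InvalidInputError("connectivity coefficients must be finite")
    L = W.shape[0]
    rng = np.random.default_rng(seed)
    intercept = float(np.log(base_rate / (1.0 - base_rate)))
    data = np.zeros((T, m), dtype=int)
    pinned = 0
    for t in range(T):
        eta = np.full(m, intercept)
        for l in range(min(L, t)):
            eta += W[l].T @ data[t - 1 - l]
        prob = 1.0 / (1.0 + np.exp(-eta))
        pinned += int(np.sum((prob < 1e-9) | (prob > 1 - 1e-9)))
        data[t] = rng.random(m) < prob
    if pinned > 0.10 * T * m:
        warnings.warn(
            "explosive parameterization: per-bin probability pinned at 0/1 "
            f"for {pinned / (T * m):.0%} of bins",
            RuntimeWarning,
        )
    return SpikeEnsemble(data, rate=sample_rate, labels=labels)
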