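"""Point-process Granger causality among binary behavioral spike trains.

Each variable's per-bin event probability is modeled by a Bernoulli GLM with
a logit link over the lagged histories (lags 1..p) of *every* variable in the
ensemble, its own included. Variable X Granger-causes Y if removing X's
history block from Y's full model significantly worsens the fit: the test
statistic is the deviance difference

    Δ = deviance(reduced) − deviance(full)  ~  χ²_p  under the null,

with p degrees of freedom (the number of excluded source lags). The history
order p is selected per target by AIC over a common outcome window, and the
m(m−1) ordered-pair p-values are corrected by Benjamini–Hochberg FDR. Each
pair's influence is reported as a signed magnitude, sign(Σ source lag
coefficients)·Δ, and a {1, −1, 0} significance code: significantly positive
(excitatory), significantly negative (inhibitory), or not significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .data import BinarySpikeTrain
from .errors import FitFailureError, InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeEnsemble",
    "GCConfig",
    "GCPairResult",
    "GCMatrixResult",
    "build_history_design",
    "fit_event_glm",
    "select_history_order",
    "gc_pair",
    "gc_all_pairs",
]


@dataclass
class SpikeEnsemble:
    """m aligned binary spike trains of common length T and sampling rate."""

    data: np.ndarray  # T x m, values in {0, 1}
    rate: float
    labels: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=int)
        if self.data.ndim != 2:
            raise InvalidInputError("ensemble data must be T x m")
        if self.m < 2:
            raise InvalidInputError("an ensemble needs at least 2 variables")
        if not np.isin(self.data, (0, 1)).all():
            raise InvalidInputError("ensemble values must be 0 or 1")
        if self.labels is None:
            self.labels = [f"var{i + 1}" for i in range(self.m)]
        if len(self.labels) != self.m:
            raise InvalidInputError("one label per variable required")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_trains(cls, trains: list[BinarySpikeTrain]) -> "SpikeEnsemble":
        if len({len(t) for t in trains}) != 1 or len({t.rate for t in trains}) != 1:
            raise InvalidInputError("trains must share length and rate")
        return cls(
            np.column_stack([t.values for t in trains]),
            rate=trains[0].rate,
            labels=[t.label or f"var{i + 1}" for i, t in enumerate(trains)],
        )


@dataclass
class GCConfig:
    """Analysis configuration: maximum history window (samples), FDR level."""

    p_max: int = 3
    q: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.p_max < 1:
            raise InvalidInputError("p_max must be >= 1")
        if not 0 < self.q < 1:
            raise InvalidInputError("q must lie in (0, 1)")


@dataclass
class FitResult:
    llf: float
    deviance: float
    params: np.ndarray  # aligned with design columns incl. intercept (col 0)
    dropped: list[int]  # design columns dropped as degenerate (0-based, no intercept)
    penalized: bool = False


@dataclass
class GCPairResult:
    source: int
    target: int
    magnitude: float
    p_value: float
    df: int
    available: bool = True


@dataclass
class GCMatrixResult:
    gcause: np.ndarray  # m x m signed magnitudes, nan diagonal
    significance: np.ndarray  # m x m in {1, -1, 0}
    orders: list[int]  # selected history order per target
    pairs: list[GCPairResult] = field(default_factory=list)
    labels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels or [str(i) for i in range(self.gcause.shape[0])]
        rows = [
            {
                "source": labels[p.source],
                "target": labels[p.target],
                "magnitude": p.magnitude,
                "p_value": p.p_value,
                "significance": int(self.significance[p.source, p.target]),
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows)

    def pretty(self) -> str:
        """Readable all-pairs report of influence magnitudes and significance."""
        labels = self.labels or [str(i) for i in range(self.gcause.shape[0])]
        marks = {1: "significantly positive", -1: "significantly negative", 0: "n.s."}
        lines = []
        for p in sorted(self.pairs, key=lambda r: -abs(r.magnitude)):
            sig = int(self.significance[p.source, p.target])
            lines.append(
                f"{labels[p.source]:>12s} -> {labels[p.target]:<12s} "
                f"magnitude {p.magnitude:+8.3f}  p={p.p_value:.4f}  {marks[sig]}"
            )
        return "\n".join(lines)


def build_history_design(
    ensemble: SpikeEnsemble,
    target: int,
    p: int,
    first_row: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged-history design for one target variable.

    Outcome rows run from ``first_row`` (default p) to T−1; the predictor
    block holds lags 1..p of every variable (target's own history included),
    ordered variable-major: columns ``j*p + (l-1)`` hold variable j at lag l.
    The intercept is *not* included (added at fit time).
    """
    if p < 1:
        raise InvalidInputError("history order must be >= 1")
    start = p if first_row is None else first_row
    if start < p:
        raise InvalidInputError("first_row must be >= p")
    if ensemble.T <= start:
        raise InsufficientDataError(
            f"series length {ensemble.T} too short for history window {start}"
        )
    rows = np.arange(start, ensemble.T)
    y = ensemble.data[rows, target].astype(float)
    cols = []
    for j in range(ensemble.m):
        for lag in range(1, p + 1):
            cols.append(ensemble.data[rows - lag, j])
    X = np.column_stack(cols).astype(float)
    return X, y


def source_columns(m: int, source: int, p: int) -> np.ndarray:
    """Design-column indices (intercept excluded) of one source's lag block."""
    return np.arange(source * p, (source + 1) * p)


def _penalized_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1e-4) -> FitResult:
    """Ridge-penalized Bernoulli-logit ML fit, used when the plain IRLS fit
    fails (separation / non-convergence). The reported deviance is the
    *unpenalized* deviance at the penalized optimum, making the LR statistic
    conservative."""
    Xc = sm.add_constant(X, has_constant="add")

    def negll(beta):
        eta = Xc @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta)) + alpha * beta @ beta

    def grad(beta):
        mu = special.expit(Xc @ beta)
        return -Xc.T @ (y - mu) + 2 * alpha * beta

    res = optimize.minimize(
        negll, np.zeros(Xc.shape[1]), jac=grad, method="L-BFGS-B",
        options={"maxiter": 500},
    )
    eta = Xc @ res.x
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return FitResult(llf=llf, deviance=-2.0 * llf, params=res.x, dropped=[], penalized=True)


def fit_event_glm(X: np.ndarray, y: np.ndarray) -> FitResult:
    """Maximum-likelihood Bernoulli-logit fit of a lagged design.

    Constant (degenerate) columns are dropped and recorded; their entries in
    the returned coefficient vector are 0. On separation or non-convergence
    the fit is retried with a small quadratic penalty and flagged.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidInputError("outcome must be binary")
    if y.sum() == 0 or y.sum() == len(y):
        raise FitFailureError("outcome has no variation (all 0 or all 1)")
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [j for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.debug("dropping %d degenerate design columns", len(dropped))
    Xk = X[:, keep]
    Xc = sm.add_constant(Xk, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, Xc, family=sm.families.Binomial())
            fit = model.fit(maxiter=100)
        converged = getattr(fit, "converged", True)
        finite = np.isfinite(fit.params).all() and np.abs(fit.params).max() < 1e3
        if converged and finite:
            params = np.zeros(X.shape[1] + 1)
            params[0] = fit.params[0]
            for out_pos, j in enumerate(keep):
                params[j + 1] = fit.params[out_pos + 1]
            return FitResult(
                llf=float(fit.llf),
                deviance=float(fit.deviance),
                params=params,
                dropped=dropped,
            )
    except Exception:
        pass
    pen = _penalized_logit(Xk, y)
    params = np.zeros(X.shape[1] + 1)
    params[0] = pen.params[0]
    for out_pos, j in enumerate(keep):
        params[j + 1] = pen.params[out_pos + 1]
    return FitResult(
        llf=pen.llf, deviance=pen.deviance, params=params,
        dropped=dropped, penalized=True,
    )


def select_history_order(
    ensemble: SpikeEnsemble, target: int, p_max: int
) -> int:
    """AIC selection of the history window for one target's full model.

    Full models with p = 1..p_max are fitted on the common outcome window
    t >= p_max so their AIC values are comparable; ties break toward the
    smallest p.
    """
    if p_max < 1:
        raise InvalidInputError("p_max must be >= 1")
    best_p, best_aic = None, np.inf
    for p in range(1, p_max + 1):
        X, y = build_history_design(ensemble, target, p, first_row=p_max)
        try:
            fit = fit_event_glm(X, y)
        except FitFailureError:
            continue
        k = X.shape[1] - len(fit.dropped) + 1
        aic = 2 * k - 2 * fit.llf
        if aic < best_aic - 1e-12:
            best_p, best_aic = p, aic
    if best_p is None:
        raise FitFailureError(f"all candidate fits failed for target {target}")
    return best_p


def gc_pair(
    ensemble: SpikeEnsemble,
    source: int,
    target: int,
    p: int,
    _full_fit: FitResult | None = None,
    _design: tuple[np.ndarray, np.ndarray] | None = None,
) -> GCPairResult:
    """Likelihood-ratio Granger test of one directed pair at history order p.

    Full and reduced models are fitted on identical rows; the reduced model
    keeps every variable's lags except the source's. Magnitude is the signed
    deviance difference; p-value from χ² with df = p.
    """
    if source == target:
        raise InvalidInputError("source and target must differ")
    X, y = _design if _design is not None else build_history_design(ensemble, target, p)
    try:
        full = _full_fit if _full_fit is not None else fit_event_glm(X, y)
        cols = source_columns(ensemble.m, source, p)
        reduced_X = np.delete(X, cols, axis=1)
        reduced = fit_event_glm(reduced_X, y)
    except FitFailureError as exc:
        logger.warning("pair %d->%d unavailable: %s", source, target, exc)
        return GCPairResult(source, target, 0.0, 1.0, p, available=False)
    delta = reduced.deviance - full.deviance
    if delta < -1e-6:
        logger.warning(
            "negative deviance difference %.3g for pair %d->%d (numerical)",
            delta, source, target,
        )
    delta = max(delta, 0.0)
    coef_sum = float(full.params[1 + cols].sum())
    sign = 1.0 if coef_sum >= 0 else -1.0
    p_value = float(stats.chi2.sf(delta, df=p))
    return GCPairResult(source, target, sign * delta, p_value, df=p)


def gc_all_pairs(ensemble: SpikeEnsemble, config: GCConfig | None = None) -> GCMatrixResult:
    """All-pairs Granger influence matrix with BH-FDR significance coding.

    For every target the history order is AIC-selected, the full model fitted
    once, and each of the m−1 reduced models tested against it. The m(m−1)
    p-values are corrected together at level q; significance is
    sign(magnitude) where rejected, else 0 (unavailable pairs report 0).
    """
    config = config or GCConfig()
    m = ensemble.m
    gcause = np.full((m, m), np.nan)
    significance = np.zeros((m, m), dtype=int)
    orders = []
    pairs: list[GCPairResult] = []
    for target in range(m):
        p_star = select_history_order(ensemble, target, config.p_max)
        orders.append(p_star)
        X, y = build_history_design(ensemble, target, p_star)
        try:
            full = fit_event_glm(X, y)
        except FitFailureError:
            full = None
        for source in range(m):
            if source == target:
                continue
            if full is None:
                pairs.append(GCPairResult(source, target, 0.0, 1.0, p_star, available=False))
            else:
                pairs.append(
                    gc_pair(ensemble, source, target, p_star,
                            _full_fit=full, _design=(X, y))
                )
    available = [p for p in pairs if p.available]
    if available:
        reject, _, _, _ = multipletests(
            [p.p_value for p in available], alpha=config.q, method="fdr_bh"
        )
        for pair, rej in zip(available, reject):
            if rej:
                significance[pair.source, pair.target] = int(np.sign(pair.magnitude)) or 1
    for pair in pairs:
        gcause[pair.source, pair.target] = pair.magnitude
    return GCMatrixResult(
        gcause=gcause,
        significance=significance,
        orders=orders,
        pairs=pairs,
        labels=list(ensemble.labels),
    )
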