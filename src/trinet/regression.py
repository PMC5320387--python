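"""Streamwise sparse regression with variance-inflation-corrected testing.

The selection problem is l0-penalized least squares,

    argmin_beta  ||y - X beta||_2^2 + lambda0 * ||beta||_0,

with p >> n, where exhaustive search over the 2^p supports is hopeless.
The streamwise procedure visits candidate predictors one at a time in a
seeded random order and tests each against the current residual.  The raw
marginal t-statistic is optimistically large when the candidate is
correlated with predictors already in the model; it is therefore deflated
by the square root of rho, the fraction of the candidate's variance left
after projecting it onto the current support.  Estimating rho on a small
presample of the rows keeps each step O(n * k) instead of O(n * p).

Admission is decided by alpha-investing: a wealth budget w starts at w0,
the test level at step i is alpha_i = w / (2 i), an admitted predictor
pays out d_w into the wealth, and a rejection costs alpha_i / (1 -
alpha_i).  The schedule controls the number of false selections over the
stream, playing the role of the nominal penalty weight lambda0 (which is
kept only for objective reporting).  After each pass the model is refit by
ordinary least squares and support members whose refit p-value no longer
meets the level that admitted them are pruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: Lower clamp for the variance-inflation ratio; exact collinearity would
#: otherwise send the corrected t-statistic to infinity.
RHO_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# small closed-form pieces
# ---------------------------------------------------------------------------

def adjusted_r2(rss: float, tss: float, n: int, k: int) -> float:
    """Adjusted coefficient of determination.

    R^2 = 1 - rss/tss, penalized for model size:
    adj R^2 = 1 - (1 - R^2) (n - 1) / (n - k - 1).

    Raises for ``n <= k + 1`` where the statistic is undefined.
    """
    if tss <= 0:
        raise ValidationError("total sum of squares must be positive")
    if rss < 0:
        raise ValidationError("residual sum of squares must be nonnegative")
    if n <= k + 1:
        raise ValidationError(
            f"adjusted R^2 undefined for n={n}, k={k} (need n > k + 1)")
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def evaluate_l0_objective(y: np.ndarray, X: np.ndarray,
                          beta: np.ndarray, lambda0: float) -> float:
    """||y - X beta||^2 + lambda0 * (number of nonzero coefficients)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if lambda0 < 0:
        raise ValidationError("lambda0 must be nonnegative")
    if X.shape[0] != y.shape[0] or X.shape[1] != beta.shape[0]:
        raise ValidationError(
            f"dimension mismatch: y {y.shape}, X {X.shape}, beta {beta.shape}")
    resid = y - X @ beta
    return float(resid @ resid + lambda0 * np.count_nonzero(beta))


def vif_correction(candidate: np.ndarray, support_columns: np.ndarray,
                   presample: np.ndarray) -> float:
    """Variance-inflation ratio rho in (0, 1], estimated on the presample.

    rho is the residual variance of the candidate after least-squares
    projection onto the current support's columns divided by the
    candidate's variance, both computed on the presample rows.  rho = 1
    when the support is empty (no inflation without a model); near-zero
    rho (candidate collinear with the support) is clamped at a small
    floor.  Falls back to rho = 1 with a warning when the presample is
    too small to fit the projection.
    """
    candidate = np.asarray(candidate, dtype=float).ravel()
    presample = np.asarray(presample, dtype=int)
    if support_columns is None or support_columns.size == 0:
        return 1.0
    support_columns = np.atleast_2d(np.asarray(support_columns, dtype=float))
    if support_columns.shape[0] != candidate.shape[0]:
        support_columns = support_columns.T
    k = support_columns.shape[1]
    if presample.size <= k + 1:
        logger.warning(
            "presample of %d rows too small for %d support columns; rho=1",
            presample.size, k)
        return 1.0
    xs = candidate[presample]
    var_x = xs.var()
    if var_x == 0.0:
        return 1.0
    Z = support_columns[presample]
    # include an intercept: the presample sub-columns are not centered
    Z1 = np.column_stack([np.ones(presample.size), Z])
    coef, *_ = np.linalg.lstsq(Z1, xs, rcond=None)
    resid = xs - Z1 @ coef
    rho = resid.var() / var_x
    return float(min(1.0, max(RHO_FLOOR, rho)))


# ---------------------------------------------------------------------------
# parameters and fitted-model record
# ---------------------------------------------------------------------------

@dataclass
class VifParams:
    """Tuning knobs of the streamwise selection.

    presample_size : rows used to estimate rho (capped at n at fit time).
    initial_wealth : starting alpha-investing budget w0, in (0, 1).
    payout : wealth added on each admission, in (0, 1).
    max_passes : maximum number of passes over the predictor stream.
    seed : root random seed (stream order, presample draw).
    lambda0 : nominal l0 penalty weight, kept for objective reporting only.
    """

    presample_size: int = 200
    initial_wealth: float = 0.05
    payout: float = 0.05
    max_passes: int = 2
    seed: int = 0
    lambda0: float = 0.0

    def __post_init__(self):
        if self.presample_size < 1:
            raise ValidationError("presample_size must be positive")
        if not 0.0 < self.initial_wealth < 1.0:
            raise ValidationError("initial_wealth must be in (0, 1)")
        if not 0.0 < self.payout < 1.0:
            raise ValidationError("payout must be in (0, 1)")
        if self.max_passes < 1:
            raise ValidationError("max_passes must be positive")
        if self.lambda0 < 0:
            raise ValidationError("lambda0 must be nonnegative")


@dataclass
class SparseLinearModel:
    """One target RNA's fitted sparse model.

    ``support`` holds selected predictor identifiers in admission order;
    ``coefficients`` are the ordinary-least-squares refit values over that
    support on the original predictor scale.
    """

    target_id: object
    support: list = field(default_factory=list)
    coefficients: list = field(default_factory=list)
    intercept: float = 0.0
    r2: float = 0.0
    adj_r2: float = 0.0

    @property
    def k(self) -> int:
        return len(self.support)

    def __post_init__(self):
        if len(self.support) != len(self.coefficients):
            raise ValidationError("support and coefficients length mismatch")
        if self.target_id in self.support:
            raise ValidationError("target may not appear in its own support")


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class StreamwiseVifRegressor:
    """Sparse linear regression by streamwise VIF-corrected selection.

    scikit-learn-compatible estimator: ``fit(X, y)`` then ``predict(X)``;
    fitted state lives in trailing-underscore attributes.

    Parameters
    ----------
    presample_size : int, default 200
        Number of rows in the presample used to estimate the
        variance-inflation ratio (capped at n).
    initial_wealth, payout : float, default 0.05
        Alpha-investing budget w0 and per-admission payout d_w.
    max_passes : int, default 2
        Upper bound on passes over the predictor stream; iteration stops
        early once a full pass (including the prune step) changes nothing.
    lambda0 : float, default 0.0
        Nominal l0 penalty weight, reported via
        :func:`evaluate_l0_objective`; the alpha-investing schedule is the
        operational penalty.
    random_state : int or None
        Seed for the stream order and the presample draw.  Fits are fully
        deterministic given (X, y, random_state).

    Attributes
    ----------
    support_ : ndarray of int
        Selected column indices, in admission order.
    coef_ : ndarray of shape (n_features,)
        Dense coefficient vector on the original X scale; zero off-support.
    intercept_ : float
    r2_, adj_r2_ : float
        Coefficient of determination of the OLS refit, plain and adjusted
        for model size.
    admission_thresholds_ : dict
        Column index -> the alpha-investing level that admitted it.
    n_features_in_ : int
    """

    def __init__(self, presample_size: int = 200, initial_wealth: float = 0.05,
                 payout: float = 0.05, max_passes: int = 2,
                 lambda0: float = 0.0, random_state: int | None = None):
        self.presample_size = presample_size
        self.initial_wealth = initial_wealth
        self.payout = payout
        self.max_passes = max_passes
        self.lambda0 = lambda0
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            "presample_size": self.presample_size,
            "initial_wealth": self.initial_wealth,
            "payout": self.payout,
            "max_passes": self.max_passes,
            "lambda0": self.lambda0,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "StreamwiseVifRegressor":
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- internals -----------------------------------------------------

    @staticmethod
    def _ols(Xs: np.ndarray, yc: np.ndarray, support: list):
        """OLS of centered y on standardized support columns.

        Returns (coef, residual, rss).  Empty support -> null model.
        """
        if not support:
            return np.empty(0), yc.copy(), float(yc @ yc)
        A = Xs[:, support]
        coef, *_ = np.linalg.lstsq(A, yc, rcond=None)
        resid = yc - A @ coef
        return coef, resid, float(resid @ resid)

    def _refit_pvalues(self, Xs, yc, support):
        """Two-sided p-values of each refit coefficient's t-statistic."""
        n = yc.shape[0]
        k = len(support)
        A = Xs[:, support]
        coef, resid, rss = self._ols(Xs, yc, support)
        df = n - k - 1  # centering consumed the intercept df
        if df <= 0:
            return coef, resid, rss, np.ones(k)
        sigma2 = rss / df
        try:
            cov = sigma2 * np.linalg.pinv(A.T @ A)
            se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
            tvals = coef / se
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        except np.linalg.LinAlgError:  # pragma: no cover
            pvals = np.zeros(k)
        return coef, resid, rss, pvals

    # -- fitting -------------------------------------------------------

    def fit(self, X, y) -> "StreamwiseVifRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        n, p = X.shape
        if y.shape[0] != n:
            raise ValidationError(
                f"X has {n} rows but y has {y.shape[0]} observations")
        if n < 3:
            raise ValidationError("need at least 3 observations")
        if p < 1:
            raise ValidationError("need at least 1 predictor")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValidationError("X and y must be finite")
        VifParams(presample_size=self.presample_size,
                  initial_wealth=self.initial_wealth,
                  payout=self.payout, max_passes=self.max_passes,
                  lambda0=self.lambda0)  # reuse its validation

        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        degenerate = x_sd == 0.0
        x_sd_safe = np.where(degenerate, 1.0, x_sd)
        Xs = (X - x_mean) / x_sd_safe
        y_mean = y.mean()
        yc = y - y_mean

        rng = np.random.default_rng(
            self.random_state if self.random_state is not None else 0)
        m = min(self.presample_size, n)
        presample = np.sort(rng.choice(n, size=m, replace=False))
        order = rng.permutation(p)

        tss = float(yc @ yc)
        support: list[int] = []
        thresholds: dict[int, float] = {}
        wealth = float(self.initial_wealth)
        step = 0

        _, resid, rss = self._ols(Xs, yc, support)
        if tss == 0.0:
            # constant response: null model, R^2 defined as 0
            self._finalize(X, y, Xs, yc, x_mean, x_sd_safe, y_mean,
                           [], {}, tss)
            return self

        for _pass in range(self.max_passes):
            changed = False
            for j in order:
                if j in support or degenerate[j]:
                    continue
                if n <= len(support) + 2:
                    logger.warning("support size reached n - 2; "
                                   "no further admissions")
                    break
                step += 1
                alpha = wealth / (2.0 * step)
                if alpha <= 0.0:
                    continue  # wealth exhausted: stop admitting, keep stream
                xj = Xs[:, j]
                rho = vif_correction(xj, Xs[:, support] if support else
                                     np.empty((n, 0)), presample)
                xtx = float(xj @ xj)
                k = len(support)
                df = n - k - 2  # candidate model: support + candidate, centered
                sigma2 = rss / max(df, 1)
                gamma = float(xj @ resid) / xtx
                se = np.sqrt(sigma2 / xtx)
                t_corr = (gamma / se) / np.sqrt(rho)
                pval = 2.0 * stats.norm.sf(abs(t_corr))
                if pval < alpha:
                    support.append(int(j))
                    thresholds[int(j)] = alpha
                    wealth += self.payout
                    _, resid, rss = self._ols(Xs, yc, support)
                    changed = True
                else:
                    wealth = max(0.0, wealth - alpha / (1.0 - alpha))

            # backward prune: drop members that no longer meet the level
            # that admitted them, worst first
            while support:
                _, resid, rss, pvals = self._refit_pvalues(Xs, yc, support)
                excess = [(pv - thresholds[idx], i)
                          for i, (idx, pv) in enumerate(zip(support, pvals))
                          if pv > thresholds[idx]]
                if not excess:
                    break
                _, worst = max(excess)
                dropped = support.pop(worst)
                thresholds.pop(dropped)
                changed = True
            _, resid, rss = self._ols(Xs, yc, support)
            if not changed:
                break

        self._finalize(X, y, Xs, yc, x_mean, x_sd_safe, y_mean,
                       support, thresholds, tss)
        return self

    def _finalize(self, X, y, Xs, yc, x_mean, x_sd, y_mean,
                  support, thresholds, tss):
        n, p = X.shape
        coef_std, resid, rss = self._ols(Xs, yc, support)
        coef = np.zeros(p)
        if support:
            coef[support] = coef_std / x_sd[support]
        intercept = y_mean - float(x_mean @ coef)
        if tss > 0:
            r2 = 1.0 - rss / tss
            k = len(support)
            adj = adjusted_r2(rss, tss, n, k) if n > k + 1 else -np.inf
        else:
            r2, adj = 0.0, 0.0
        self.support_ = np.asarray(support, dtype=int)
        self.coef_ = coef
        self.intercept_ = float(intercept)
        self.r2_ = float(min(max(r2, 0.0), 1.0)) if tss > 0 else 0.0
        # clip r2 into [0,1] only against float round-off; rss<=tss by OLS
        self.adj_r2_ = float(adj)
        self.admission_thresholds_ = dict(thresholds)
        self.n_features_in_ = p
        self.rss_ = float(rss)
        self.tss_ = float(tss)
        self.n_samples_ = n

    # -- prediction and scoring ---------------------------------------

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def score(self, X, y) -> float:
        """R^2 on the given data (sklearn regressor convention)."""
        y = np.asarray(y, dtype=float).ravel()
        resid = y - self.predict(X)
        yc = y - y.mean()
        tss = float(yc @ yc)
        if tss == 0.0:
            return 0.0
        return 1.0 - float(resid @ resid) / tss

    def objective(self) -> float:
        """The fitted model's l0-penalized residual sum of squares."""
        return self.rss_ + self.lambda0 * len(self.support_)


def fit_streamwise(y, X, params: VifParams | None = None,
                   predictor_ids=None, target_id=None) -> SparseLinearModel:
    """Fit one streamwise model and return a :class:`SparseLinearModel`.

    Thin functional wrapper over :class:`StreamwiseVifRegressor` keeping
    gene identifiers attached to the selected support.
    """
    params = params if params is not None else VifParams()
    est = StreamwiseVifRegressor(
        presample_size=params.presample_size,
        initial_wealth=params.initial_wealth,
        payout=params.payout,
        max_passes=params.max_passes,
        lambda0=params.lambda0,
        random_state=params.seed,
    ).fit(X, y)
    X = np.asarray(X, dtype=float)
    if predictor_ids is None:
        predictor_ids = list(range(X.shape[1]))
    predictor_ids = list(predictor_ids)
    return SparseLinearModel(
        target_id=target_id,
        support=[predictor_ids[j] for j in est.support_],
        coefficients=[float(est.coef_[j]) for j in est.support_],
        intercept=est.intercept_,
        r2=est.r2_,
        adj_r2=est.adj_r2_,
    )
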