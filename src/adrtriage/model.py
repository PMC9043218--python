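"""Proportional-odds and partial proportional-odds cumulative logit models.

The automatic causality assessment (ACA) model is an ordinal regression of
the 5-level causality category on the 11 Boolean report variables.  The
cumulative logits are

    logit P(Y <= j | x) = theta_j + beta' x_par + tau_j' x_non,   j = 1..J-1,

so a variable may either share one slope across all logits (the *parallel*
assumption of the proportional-odds model) or carry a logit-specific slope
tau_j (a *non-parallel* variable).  With no non-parallel variables the model
is exactly the proportional-odds model.

Sign convention
---------------
The linear predictor enters with a **plus** sign: a positive coefficient
increases P(Y <= j) and therefore pushes probability mass toward the LOW
(less certain) categories.  Many packages parameterize theta_j - beta'x
instead; negate coefficients to compare.

Fitting is exact maximum likelihood: the multinomial log-likelihood over
logistic-CDF differences is maximized by quasi-Newton iteration (L-BFGS-B)
with an analytic gradient, started from the closed-form intercept-only
solution with zero slopes.  Cut points are fitted unconstrained; since a
partial proportional-odds model can produce crossing cumulative curves,
monotonicity is checked at every training point afterwards and recorded in
``monotone_ok``.  At prediction time a negative category probability is
floored at 1e-12 and the vector renormalized, with the event counted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2, norm
from statsmodels.tools.numdiff import approx_hess

from .schema import PREDICTOR_COLUMNS, ReportTable

__all__ = [
    "ModelPartition",
    "FitOptions",
    "PPOParameters",
    "PartialProportionalOdds",
    "PPOResults",
    "ParallelTestResult",
    "fit_model",
    "cumulative_logit",
    "category_probabilities",
    "log_likelihood",
    "predict_category",
    "lr_test_parallel",
    "select_partition",
]

_PROB_FLOOR = 1e-12
_ALL_CATEGORIES = np.arange(1, 6)


@dataclass(frozen=True)
class ModelPartition:
    """Split of the predictors into parallel and non-parallel sets."""

    parallel_vars: tuple[str, ...]
    nonparallel_vars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.parallel_vars) & set(self.nonparallel_vars)
        if overlap:
            raise ValueError(f"variables in both partitions: {sorted(overlap)}")

    @property
    def all_vars(self) -> tuple[str, ...]:
        return self.parallel_vars + self.nonparallel_vars

    @property
    def q(self) -> int:
        return len(self.nonparallel_vars)

    @classmethod
    def all_parallel(cls, names: Sequence[str] = PREDICTOR_COLUMNS) -> "ModelPartition":
        return cls(tuple(names), ())


@dataclass(frozen=True)
class FitOptions:
    """Optimizer and policy settings for maximum-likelihood fitting."""

    max_iterations: int = 500
    gradient_tolerance: float = 1e-7
    ridge_penalty: float = 0.0
    seed: int = 0
    empty_category_policy: str = "error"  # or "merge"

    def __post_init__(self) -> None:
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be > 0")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be >= 0")
        if self.empty_category_policy not in ("error", "merge"):
            raise ValueError("empty_category_policy must be 'error' or 'merge'")


@dataclass
class PPOParameters:
    """A concrete parameter set (cut points, slopes, partition).

    ``var_names`` orders the predictor columns; ``beta`` aligns with the
    parallel variables and ``tau`` (one row per cut point) with the
    non-parallel ones, both in ``partition`` order.  ``categories`` lists the
    outcome levels the cut points refer to (ascending; normally 1..5).
    """

    theta: np.ndarray
    beta: np.ndarray
    tau: np.ndarray
    partition: ModelPartition
    categories: np.ndarray = field(default_factory=lambda: _ALL_CATEGORIES.copy())

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float).reshape(len(self.theta), -1)
        self.categories = np.asarray(self.categories, dtype=int)
        if len(self.theta) != len(self.categories) - 1:
            raise ValueError("theta must have one entry per cut (J - 1)")
        if len(self.beta) != len(self.partition.parallel_vars):
            raise ValueError("beta length must match parallel_vars")
        if self.tau.shape[1] != self.partition.q:
            raise ValueError("tau width must match nonparallel_vars")

    @property
    def var_names(self) -> tuple[str, ...]:
        return self.partition.all_vars

    @property
    def n_cuts(self) -> int:
        return len(self.theta)

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = len(self.var_names)
        if X.shape[1] != p:
            raise ValueError(f"expected {p} predictor columns, got {X.shape[1]}")
        k = len(self.partition.parallel_vars)
        return X[:, :k], X[:, k:]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """eta_j(x) = theta_j + beta'x_par + tau_j'x_non, an n x (J-1) array."""
        Xp, Xn = self._split(X)
        return self.theta[None, :] + (Xp @ self.beta)[:, None] + Xn @ self.tau.T

    def cumulative_probabilities(self, X: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))


@dataclass
class ParallelTestResult:
    """Likelihood-ratio test of the parallel assumption for one variable."""

    variable: str
    statistic: float
    df: int
    p_value: float
    reliable: bool


class PartialProportionalOdds:
    """Partial proportional-odds cumulative logit model.

    Parameters
    ----------
    endog : array-like of int
        Outcome categories, coded 1..5.
    exog : array-like, n x p
        Predictor matrix (Boolean in the report schema; real values are
        accepted by the likelihood).
    var_names : sequence of str, optional
        Names for the columns of ``exog``; defaults to the 11 schema names
        when p == 11, else ``x1..xp``.
    nonparallel : sequence of str, optional
        Variables given logit-specific slopes.  Empty means the plain
        proportional-odds model.
    """

    def __init__(
        self,
        endog,
        exog,
        var_names: Sequence[str] | None = None,
        nonparallel: Sequence[str] = (),
    ) -> None:
        self.endog = np.asarray(endog, dtype=int)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        n, p = self.exog.shape
        if len(self.endog) != n:
            raise ValueError("endog and exog lengths differ")
        if not np.isin(self.endog, _ALL_CATEGORIES).all():
            bad = self.endog[~np.isin(self.endog, _ALL_CATEGORIES)][0]
            raise ValueError(f"labels must lie in 1..5; found {bad}")
        if var_names is None:
            var_names = PREDICTOR_COLUMNS if p == len(PREDICTOR_COLUMNS) else tuple(
                f"x{i + 1}" for i in range(p)
            )
        if len(var_names) != p:
            raise ValueError("var_names length must match exog width")
        unknown = [v for v in nonparallel if v not in var_names]
        if unknown:
            raise ValueError(f"nonparallel variable(s) not in model: {unknown}")
        parallel = tuple(v for v in var_names if v not in nonparallel)
        self.partition = ModelPartition(parallel, tuple(v for v in var_names if v in nonparallel))
        self._orig_names = tuple(var_names)
        order = [list(var_names).index(v) for v in self.partition.all_vars]
        self._X = self.exog[:, order]

    @classmethod
    def from_report_table(
        cls,
        table: ReportTable,
        nonparallel: Sequence[str] = (),
        predictors: Sequence[str] = PREDICTOR_COLUMNS,
    ) -> "PartialProportionalOdds":
        """Build the model from a labeled report table."""
        X = table.df[list(predictors)].to_numpy(dtype=float)
        return cls(table.labels(), X, var_names=tuple(predictors), nonparallel=nonparallel)

    from_dataframe = from_report_table

    # -- likelihood machinery -------------------------------------------------

    def _prepare(self, opts: FitOptions) -> tuple[np.ndarray, np.ndarray]:
        """Resolve empty categories; returns (categories, label indices)."""
        present = np.unique(self.endog)
        absent = np.setdiff1d(_ALL_CATEGORIES, present)
        if absent.size and opts.empty_category_policy == "error":
            raise ValueError(
                f"outcome category {absent[0]} absent from training data; its cut "
                "point is unidentified (use empty_category_policy='merge')"
            )
        # merge: an absent category contributes no likelihood term, so the fit
        # simply runs on the J' present levels with J'-1 cut points; each
        # absent level is mapped to its nearest present neighbour (lower
        # preferred) for likelihood evaluation on new data.
        cat_index = {int(c): i for i, c in enumerate(present)}
        y_idx = np.array([cat_index[int(y)] for y in self.endog])
        return present, y_idx

    @staticmethod
    def _unpack(params: np.ndarray, n_cuts: int, k: int, q: int):
        theta = params[:n_cuts]
        beta = params[n_cuts : n_cuts + k]
        tau = params[n_cuts + k :].reshape(n_cuts, q) if q else np.zeros((n_cuts, 0))
        return theta, beta, tau

    def _nll_grad(self, params, y_idx, n_cuts, ridge):
        k = len(self.partition.parallel_vars)
        q = self.partition.q
        theta, beta, tau = self._unpack(params, n_cuts, k, q)
        Xp, Xn = self._X[:, :k], self._X[:, k:]
        eta = theta[None, :] + (Xp @ beta)[:, None] + Xn @ tau.T
        F = expit(eta)                                    # n x (J-1)
        n = len(y_idx)
        Fpad = np.hstack([np.zeros((n, 1)), F, np.ones((n, 1))])
        rows = np.arange(n)
        p = Fpad[rows, y_idx + 1] - Fpad[rows, y_idx]
        p_safe = np.clip(p, _PROB_FLOOR, None)
        nll = -np.sum(np.log(p_safe)) + 0.5 * ridge * (beta @ beta + np.sum(tau * tau))

        # dp/deta_j = f_j * ([j == y] - [j == y-1]) with f = F(1-F)
        f = F * (1.0 - F)
        G = np.zeros_like(F)
        upper = y_idx < n_cuts       # cut index y contributes +f
        G[rows[upper], y_idx[upper]] = f[rows[upper], y_idx[upper]]
        lower = y_idx > 0            # cut index y-1 contributes -f
        G[rows[lower], y_idx[lower] - 1] -= f[rows[lower], y_idx[lower] - 1]
        W = G / p_safe[:, None]
        g_theta = -W.sum(axis=0)
        g_beta = -(Xp.T @ W.sum(axis=1)) + ridge * beta
        grad = [g_theta, g_beta]
        if q:
            g_tau = -(W.T @ Xn) + ridge * tau
            grad.append(g_tau.ravel())
        return nll, np.concatenate(grad)

    def loglike(self, params: PPOParameters) -> float:
        """Exact log-likelihood of a parameter set on the training data."""
        probs = _raw_category_probabilities(params, self._X, reorder=False)
        idx = _map_labels(self.endog, params.categories)
        p = probs[np.arange(len(idx)), idx]
        if (p <= 0).any():
            bad = int(np.argmax(p <= 0))
            raise ValueError(f"record {bad}: fitted P(Y = y) <= 0")
        return float(np.sum(np.log(p)))

    # -- fitting --------------------------------------------------------------

    def fit(self, opts: FitOptions | None = None) -> "PPOResults":
        """Maximize the log-likelihood; deterministic given data and options."""
        opts = opts or FitOptions()
        cats, y_idx = self._prepare(opts)
        n_cuts = len(cats) - 1
        k = len(self.partition.parallel_vars)
        q = self.partition.q
        n = len(y_idx)
        n_params = n_cuts + k + n_cuts * q
        if n < n_params:
            raise ValueError(f"n = {n} below the {n_params} free parameters")

        # closed-form intercept-only start: theta_j = logit(empirical P(Y <= j))
        counts = np.bincount(y_idx, minlength=n_cuts + 1)
        cum = np.cumsum(counts)[:-1] / n
        theta0 = logit(np.clip(cum, 1e-10, 1 - 1e-10))
        x0 = np.concatenate([theta0, np.zeros(k + n_cuts * q)])

        res = minimize(
            self._nll_grad,
            x0,
            args=(y_idx, n_cuts, opts.ridge_penalty),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": opts.max_iterations,
                "gtol": opts.gradient_tolerance,
                "ftol": 1e-14,
            },
        )
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"fit did not converge: {res.message}", stacklevel=2)
        theta, beta, tau = self._unpack(res.x, n_cuts, k, q)
        params = PPOParameters(theta, beta, tau, self.partition, cats)

        # monotonicity of cumulative probabilities at every training point
        eta = params.linear_predictor(self._X)
        monotone_ok = bool(np.all(np.diff(eta, axis=1) >= -1e-12)) if n_cuts > 1 else True
        if not monotone_ok:
            warnings.warn(
                "fitted cumulative probabilities cross at some training points; "
                "predictions will floor and renormalize", stacklevel=2,
            )

        llf = -self._nll_grad(res.x, y_idx, n_cuts, 0.0)[0]
        try:
            hess = approx_hess(res.x, lambda p: self._nll_grad(p, y_idx, n_cuts, opts.ridge_penalty)[0])
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((n_params, n_params), np.nan)
            bse = np.full(n_params, np.nan)
        return PPOResults(
            model=self,
            params=params,
            llf=float(llf),
            converged=converged,
            monotone_ok=monotone_ok,
            nobs=n,
            bse_flat=bse,
            cov_params=cov,
            options=opts,
            n_iterations=int(res.nit),
        )


def _map_labels(labels: np.ndarray, categories: np.ndarray) -> np.ndarray:
    """Map 1..5 labels onto indices of the model's (possibly merged) levels."""
    idx = np.searchsorted(categories, labels)
    idx = np.clip(idx, 0, len(categories) - 1)
    # prefer the lower present neighbour for absent levels
    too_high = categories[idx] > labels
    idx[too_high & (idx > 0)] -= 1
    return idx


def _raw_category_probabilities(
    params: PPOParameters, X: np.ndarray, reorder: bool = False
) -> np.ndarray:
    """Unfloored logistic-CDF differences over the model's own levels."""
    F = params.cumulative_probabilities(X)
    n = F.shape[0]
    Fpad = np.hstack([np.zeros((n, 1)), F, np.ones((n, 1))])
    return np.diff(Fpad, axis=1)


class PPOResults:
    """Fitted partial proportional-odds model.

    Carries the estimates (``theta``, ``beta``, ``tau``), their standard
    errors, the maximized log-likelihood, convergence and monotonicity
    diagnostics, and prediction methods.  ``n_crossing_events`` counts how
    often a negative category probability had to be floored at prediction
    time.
    """

    def __init__(self, model, params, llf, converged, monotone_ok, nobs,
                 bse_flat, cov_params, options, n_iterations):
        self.model = model
        self.params = params
        self.llf = llf
        self.converged = converged
        self.monotone_ok = monotone_ok
        self.nobs = nobs
        self.bse_flat = bse_flat
        self.cov_params = cov_params
        self.options = options
        self.n_iterations = n_iterations
        self.n_crossing_events = 0

    # parameter views ---------------------------------------------------------
    @property
    def theta(self) -> np.ndarray:
        return self.params.theta

    @property
    def beta(self) -> np.ndarray:
        return self.params.beta

    @property
    def tau(self) -> np.ndarray:
        return self.params.tau

    @property
    def partition(self) -> ModelPartition:
        return self.params.partition

    @property
    def param_names(self) -> list[str]:
        names = [f"theta_{j}" for j in range(1, len(self.theta) + 1)]
        names += [f"beta[{v}]" for v in self.partition.parallel_vars]
        for j in range(1, len(self.theta) + 1):
            names += [f"tau_{j}[{v}]" for v in self.partition.nonparallel_vars]
        return names

    @property
    def params_flat(self) -> np.ndarray:
        return np.concatenate([self.theta, self.beta, self.tau.ravel()])

    # prediction --------------------------------------------------------------
    def _as_matrix(self, x) -> np.ndarray:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        names = self.partition.all_vars
        orig = self.model._orig_names
        if tuple(names) != tuple(orig):
            order = [list(orig).index(v) for v in names]
            X = X[:, order]
        return X

    def cumulative_logit(self, x, j: int) -> float:
        """eta_j(x) for cut index j in 1..J-1."""
        if not 1 <= j <= len(self.theta):
            raise ValueError(f"cut index j={j} outside 1..{len(self.theta)}")
        eta = self.params.linear_predictor(self._as_matrix(x))
        return float(eta[0, j - 1])

    def category_probabilities(self, x) -> np.ndarray:
        """P(Y = 1..5 | x); rows sum to 1.

        Crossing cumulative curves (possible under non-parallel slopes) are
        handled by flooring negative entries at 1e-12 and renormalizing;
        each such row increments ``n_crossing_events``.
        """
        X = self._as_matrix(x)
        probs = _raw_category_probabilities(self.params, X)
        if not np.isfinite(probs).all():
            raise FloatingPointError("non-finite linear predictor")
        neg = probs < 0
        if neg.any():
            self.n_crossing_events += int(neg.any(axis=1).sum())
            probs = np.clip(probs, _PROB_FLOOR, None)
            probs /= probs.sum(axis=1, keepdims=True)
        cats = self.params.categories
        if len(cats) == 5:
            out = probs
        else:
            out = np.zeros((probs.shape[0], 5))
            out[:, cats - 1] = probs
        return out[0] if np.asarray(x).ndim == 1 else out

    predict_proba = category_probabilities

    def predict_category(self, x) -> np.ndarray | int:
        """Argmax category; exact ties break toward the lower category."""
        probs = np.atleast_2d(self.category_probabilities(x))
        best = probs.max(axis=1, keepdims=True)
        pred = np.argmax(probs >= best - 1e-12, axis=1) + 1
        return int(pred[0]) if np.asarray(x).ndim == 1 else pred

    def log_likelihood(self, table: ReportTable) -> float:
        """Sum of log category probabilities of the labels; empty table -> 0."""
        if len(table) == 0:
            return 0.0
        X = table.df[list(self.partition.all_vars)].to_numpy(dtype=float)
        probs = _raw_category_probabilities(self.params, X)
        idx = _map_labels(table.labels(), self.params.categories)
        p = probs[np.arange(len(idx)), idx]
        if (p <= 0).any():
            bad = int(np.argmax(p <= 0))
            raise ValueError(f"record {bad}: fitted P(Y = y) <= 0")
        return float(np.sum(np.log(p)))

    # reporting ---------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text coefficient table in the style of statsmodels."""
        lines = [
            "Partial proportional-odds cumulative logit (logit P(Y<=j) = theta_j + b'x)",
            f"n = {self.nobs}   log-likelihood = {self.llf:.4f}   "
            f"converged = {self.converged}   monotone = {self.monotone_ok}",
            f"parallel: {', '.join(self.partition.parallel_vars) or '(none)'}",
            f"non-parallel: {', '.join(self.partition.nonparallel_vars) or '(none)'}",
            "-" * 72,
            f"{'parameter':<32}{'coef':>10}{'std err':>10}{'z':>9}{'P>|z|':>9}",
            "-" * 72,
        ]
        for name, est, se in zip(self.param_names, self.params_flat, self.bse_flat):
            z = est / se if se > 0 else np.nan
            pz = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"{name:<32}{est:>10.4f}{se:>10.4f}{z:>9.2f}{pz:>9.3f}")
        lines.append("-" * 72)
        return "\n".join(lines)

    # serialization -----------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "adrtriage-ppo-model",
            "version": 1,
            "theta": self.theta.tolist(),
            "beta": self.beta.tolist(),
            "tau": self.tau.tolist(),
            "categories": self.params.categories.tolist(),
            "partition": {
                "parallel_vars": list(self.partition.parallel_vars),
                "nonparallel_vars": list(self.partition.nonparallel_vars),
            },
            "diagnostics": {
                "log_likelihood": self.llf,
                "converged": self.converged,
                "monotone_ok": self.monotone_ok,
                "n_train": self.nobs,
                "n_iterations": self.n_iterations,
            },
            "bse": self.bse_flat.tolist(),
            "options": asdict(self.options),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PPOResults":
        """Rebuild a fitted model for prediction from its JSON document."""
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        doc = json.loads(text)
        part = ModelPartition(
            tuple(doc["partition"]["parallel_vars"]),
            tuple(doc["partition"]["nonparallel_vars"]),
        )
        params = PPOParameters(
            np.array(doc["theta"]), np.array(doc["beta"]), np.array(doc["tau"]),
            part, np.array(doc["categories"]),
        )
        diag = doc["diagnostics"]
        shell = PartialProportionalOdds(
            np.array([params.categories[0]]),
            np.zeros((1, len(part.all_vars))),
            var_names=part.all_vars,
            nonparallel=part.nonparallel_vars,
        )
        return cls(
            model=shell, params=params, llf=diag["log_likelihood"],
            converged=diag["converged"], monotone_ok=diag["monotone_ok"],
            nobs=diag["n_train"], bse_flat=np.array(doc["bse"]),
            cov_params=None, options=FitOptions(**doc["options"]),
            n_iterations=diag["n_iterations"],
        )


# -- functional surface -------------------------------------------------------

def fit_model(
    data: ReportTable,
    partition: ModelPartition | None = None,
    opts: FitOptions | None = None,
) -> PPOResults:
    """Fit the ACA model on a labeled report table."""
    partition = partition or ModelPartition.all_parallel()
    model = PartialProportionalOdds.from_report_table(
        data, nonparallel=partition.nonparallel_vars, predictors=partition.all_vars
    )
    return model.fit(opts)


def cumulative_logit(result: PPOResults, x, j: int) -> float:
    return result.cumulative_logit(x, j)


def category_probabilities(result: PPOResults, x) -> np.ndarray:
    return result.category_probabilities(x)


def log_likelihood(result: PPOResults, data: ReportTable) -> float:
    return result.log_likelihood(data)


def predict_category(result: PPOResults, x):
    return result.predict_category(x)


def lr_test_parallel(
    data: ReportTable,
    variable: str,
    opts: FitOptions | None = None,
    predictors: Sequence[str] = PREDICTOR_COLUMNS,
) -> ParallelTestResult:
    """Likelihood-ratio test of the parallel assumption for one variable.

    Null: all predictors parallel.  Alternative: ``variable`` free across the
    J-1 logits.  The statistic 2*(ll_alt - ll_null) is referred to chi-square
    with J-2 degrees of freedom (3 for a fully observed 5-level outcome).
    """
    if variable not in predictors:
        raise ValueError(f"unknown predictor {variable!r}")
    opts = opts or FitOptions()
    null = fit_model(data, ModelPartition(tuple(predictors), ()), opts)
    alt = fit_model(
        data,
        ModelPartition(tuple(v for v in predictors if v != variable), (variable,)),
        opts,
    )
    stat = 2.0 * (alt.llf - null.llf)
    df = len(alt.theta) - 1
    stat = max(stat, 0.0) if stat > -1e-8 else stat
    return ParallelTestResult(
        variable=variable,
        statistic=float(stat),
        df=df,
        p_value=float(chi2.sf(max(stat, 0.0), df)),
        reliable=null.converged and alt.converged,
    )


def select_partition(
    data: ReportTable,
    alpha: float = 0.05,
    opts: FitOptions | None = None,
    predictors: Sequence[str] = PREDICTOR_COLUMNS,
) -> ModelPartition:
    """Screen every predictor with ``lr_test_parallel`` at level ``alpha``.

    Variables rejecting the parallel null (p < alpha) become non-parallel.
    Each test is run against the same all-parallel null, not sequentially.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    nonpar = []
    for v in predictors:
        if alpha > 0 and lr_test_parallel(data, v, opts, predictors).p_value < alpha:
            nonpar.append(v)
    return ModelPartition(
        tuple(v for v in predictors if v not in nonpar), tuple(nonpar)
    )
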