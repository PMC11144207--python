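"""Logistic risk models for grade-≥2 radiation pneumonitis and the four
variable-selection strategies applied to the functional dose-volume
covariates V5…V60.

The module houses:

* a maximum-likelihood logistic fitter (iteratively reweighted least
  squares) with explicit separation and singularity diagnostics;
* bidirectional stepwise selection under AIC, starting from the full model;
* exhaustive best-subset selection (all 2^p sub-models);
* an L1-penalized (lasso) logistic path solved by penalized-IRLS coordinate
  descent on standardized covariates, with the regularization weight chosen
  by K-fold cross-validated deviance;
* a bagged-tree (random-forest style) importance ranking with out-of-bag
  permutation-accuracy and total-Gini-decrease measures;
* the published risk models shipped as constants. Their printed "Risk"
  right-hand sides are linear predictors on the logit scale (they come from
  binomial GLM fits); event probability is the logistic sigmoid of that
  value. Covariates enter in percent units (0–100).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LogisticModel",
    "SelectionResult",
    "fit_logistic",
    "stepwise_select",
    "best_subset_select",
    "lasso_select",
    "lasso_kkt_violation",
    "ensemble_importance",
    "predict_risk",
    "PUBLISHED_STEPWISE_MODEL",
    "PUBLISHED_LASSO_MODEL",
    "PerfectSeparationError",
]

logger = logging.getLogger(__name__)

OUTCOME_COLUMN = "rp_grade2plus"

#: Coefficient magnitude on the standardized scale beyond which the fit is
#: declared separated (the MLE is diverging to infinity).
SEPARATION_BOUND = 15.0


class PerfectSeparationError(ValueError):
    """The likelihood has no finite maximum (a covariate separates the classes)."""


@dataclass
class LogisticModel:
    """Intercept + named coefficients on the logit scale.

    ``covariate_scale`` documents the units the coefficients act on: the
    functional dose-volume covariates are percentages of the high-function
    lung volume, in [0, 100].
    """

    intercept: float
    coefficients: Dict[str, float]
    covariate_scale: str = "percent"
    standard_errors: Optional[Dict[str, float]] = None
    log_likelihood: Optional[float] = None
    aic: Optional[float] = None
    n_obs: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        for name, beta in self.coefficients.items():
            if not np.isfinite(beta):
                raise ValueError(f"coefficient {name} must be finite")

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Vectorized logit-scale predictor over a cohort table."""
        lp = np.full(len(table), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            if name not in table.columns:
                raise KeyError(f"covariate {name} missing from table")
            lp += beta * table[name].to_numpy(dtype=float)
        return lp

    def predict_probability(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table))

    def to_json(self, **extra) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "scale": self.covariate_scale,
        }
        payload.update(extra)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        payload = json.loads(text)
        return cls(
            intercept=payload["intercept"],
            coefficients=dict(payload["coefficients"]),
            covariate_scale=payload.get("scale", "percent"),
        )


#: Final stepwise/best-subset risk model reported for the reference cohort:
#: Risk = 0.23656 − 0.13784·V35 + 0.37445·V30 − 0.38317·V25 + 0.21341·V20
#:        − 0.10209·V15 + 0.03815·V10   (logit scale, covariates in %).
PUBLISHED_STEPWISE_MODEL = LogisticModel(
    intercept=0.23656,
    coefficients={
        "V35": -0.13784,
        "V30": 0.37445,
        "V25": -0.38317,
        "V20": 0.21341,
        "V15": -0.10209,
        "V10": 0.03815,
    },
)

#: Lasso-selected risk model reported for the same cohort (logit scale).
PUBLISHED_LASSO_MODEL = LogisticModel(
    intercept=-1.052542,
    coefficients={
        "V60": -1.109038e-01,
        "V50": 3.400737e-02,
        "V35": -4.149203e-02,
        "V30": 1.388844e-01,
        "V15": -1.720682e-01,
        "V10": 1.125483e-01,
        "V5": -5.982490e-06,
    },
)


@dataclass
class SelectionResult:
    """Outcome of one variable-selection strategy."""

    method: str
    selected: List[str]
    criterion_trace: list
    final_model: Optional[LogisticModel] = None
    importances: Optional[Dict[str, Dict[str, float]]] = None
    lambdas: Optional[np.ndarray] = None
    coef_path: Optional[np.ndarray] = None
    cv_deviance: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# maximum-likelihood logistic fit (IRLS)


def _design(table: pd.DataFrame, covariates: Sequence[str], outcome: str):
    y = table[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table))]
        + [table[c].to_numpy(dtype=float) for c in covariates]
    )
    return X, y


def fit_logistic(
    table: pd.DataFrame,
    covariates: Sequence[str],
    max_iter: int = 100,
    tol: float = 1e-8,
    outcome: str = OUTCOME_COLUMN,
) -> LogisticModel:
    """Maximum-likelihood logistic regression by IRLS.

    Convergence is declared when every component of the score vector
    X'(y − p) is below ``tol · n``. Perfect (quasi-)separation is reported as
    an error naming the offending covariate, detected when a standardized
    coefficient magnitude exceeds 15.
    """
    covariates = list(covariates)
    y01 = table[outcome].to_numpy()
    classes = np.unique(y01)
    if not set(classes) <= {0, 1}:
        raise ValueError(f"outcome must be binary 0/1, found {classes}")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present to fit")
    n = len(table)
    if n <= len(covariates) + 1:
        raise ValueError(
            f"n = {n} must exceed the number of parameters ({len(covariates) + 1})"
        )

    X, y = _design(table, covariates, outcome)
    sd = X.std(axis=0)
    sd[0] = 1.0  # intercept
    if np.any(sd[1:] == 0):
        const = covariates[int(np.argmin(sd[1:]))]
        raise ValueError(f"singular design: covariate {const} is constant")

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = expit(eta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol * n:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        XtWX = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular design for covariates {covariates}") from exc
        beta = beta + delta
        std_mag = np.abs(beta * sd)
        if np.any(std_mag[1:] > SEPARATION_BOUND):
            worst = covariates[int(np.argmax(std_mag[1:]))]
            raise PerfectSeparationError(
                f"perfect separation detected: covariate {worst} drives its "
                f"standardized coefficient beyond {SEPARATION_BOUND}"
            )
    if not converged:
        warnings.warn(
            f"IRLS did not reach score tolerance {tol} in {max_iter} iterations",
            RuntimeWarning,
        )

    eta = np.clip(X @ beta, -30.0, 30.0)
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    k = X.shape[1]
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))

    names = ["(Intercept)"] + covariates
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(covariates, beta[1:])},
        standard_errors={nm: float(s) for nm, s in zip(names, se)},
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * k,
        n_obs=n,
    )


def predict_risk(
    model: LogisticModel, fv: Union[Mapping[str, float], pd.Series]
) -> Tuple[float, float]:
    """Evaluate a risk model on one covariate vector.

    Returns ``(linear_predictor, probability)`` where the linear predictor is
    intercept + Σ βx·Vx on the logit scale and probability is its sigmoid.
    """
    values = getattr(fv, "v", fv)  # accept FvVector-like objects
    lp = model.intercept
    for name, beta in model.coefficients.items():
        if name not in values:
            raise KeyError(f"covariate {name} missing from the supplied vector")
        lp += beta * float(values[name])
    return float(lp), float(expit(lp))


# ---------------------------------------------------------------------------
# stepwise (bidirectional, AIC)


def _aic_of(table, subset, outcome) -> float:
    return fit_logistic(table, subset, outcome=outcome).aic


def stepwise_select(
    table: pd.DataFrame,
    candidates: Sequence[str],
    direction: str = "both",
    criterion: str = "aic",
    outcome: str = OUTCOME_COLUMN,
) -> SelectionResult:
    """Bidirectional stepwise selection under AIC, starting from the full model.

    At each step the single add or drop that most reduces AIC is applied;
    the procedure stops when no single move improves the criterion, so the
    result is a local optimum of AIC over one-variable moves.
    """
    if direction != "both":
        raise ValueError("only bidirectional ('both') stepwise is implemented")
    if criterion.lower() != "aic":
        raise ValueError("only the AIC criterion is implemented")
    candidates = list(candidates)
    current = list(candidates)
    current_aic = _aic_of(table, current, outcome)
    trace = [{"action": "start", "variable": None, "criterion": current_aic}]

    while True:
        moves = []
        for var in current:
            subset = [c for c in current if c != var]
            try:
                moves.append(("drop", var, _aic_of(table, subset, outcome)))
            except ValueError:
                continue
        for var in candidates:
            if var in current:
                continue
            try:
                moves.append(("add", var, _aic_of(table, current + [var], outcome)))
            except ValueError:
                continue
        if not moves:
            break
        action, var, aic = min(moves, key=lambda m: m[2])
        if aic >= current_aic - 1e-10:
            break
        if action == "drop":
            current.remove(var)
        else:
            current.append(var)
        current_aic = aic
        trace.append({"action": action, "variable": var, "criterion": aic})

    selected = [c for c in candidates if c in current]
    final = fit_logistic(table, selected, outcome=outcome)
    return SelectionResult(
        method="stepwise", selected=selected, criterion_trace=trace, final_model=final
    )


# ---------------------------------------------------------------------------
# exhaustive best subset (AIC)


def best_subset_select(
    table: pd.DataFrame,
    candidates: Sequence[str],
    criterion: str = "aic",
    outcome: str = OUTCOME_COLUMN,
) -> SelectionResult:
    """Exhaustive best-subset selection: fit all 2^p sub-models, keep the
    AIC-minimal one. Ties (within 1e-9) break toward fewer variables, then
    toward earlier candidate order. Non-convergent subsets are skipped with a
    logged warning.
    """
    if criterion.lower() != "aic":
        raise ValueError("only the AIC criterion is implemented")
    candidates = list(candidates)
    p = len(candidates)
    if p > 20:
        raise ValueError(f"exhaustive enumeration limited to 20 candidates, got {p}")

    trace = []
    for size in range(p + 1):
        for idx in itertools.combinations(range(p), size):
            subset = [candidates[i] for i in idx]
            try:
                aic = _aic_of(table, subset, outcome)
            except ValueError as exc:
                logger.warning("skipping non-convergent subset %s: %s", subset, exc)
                continue
            trace.append({"subset": tuple(subset), "index": idx, "criterion": aic})
    if not trace:
        raise ValueError("no subset produced a convergent fit")

    best_aic = min(t["criterion"] for t in trace)
    ties = [t for t in trace if t["criterion"] <= best_aic + 1e-9]
    winner = min(ties, key=lambda t: (len(t["index"]), t["index"]))
    selected = list(winner["subset"])
    final = fit_logistic(table, selected, outcome=outcome)
    return SelectionResult(
        method="best_subset",
        selected=selected,
        criterion_trace=trace,
        final_model=final,
    )


# ---------------------------------------------------------------------------
# lasso (coordinate descent on standardized covariates)


def _lasso_grad(X: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray):
    """(1/n)·X'(y − p): the negative gradient of mean negative log-likelihood."""
    p = expit(np.clip(intercept + X @ beta, -30.0, 30.0))
    return X.T @ (y - p) / len(y)


def lasso_kkt_violation(
    X_std: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray, lam: float
) -> float:
    """Maximum violation of the L1 stationarity conditions at (intercept, beta).

    For the objective (1/n)·negloglik + λ·Σ|β_j| the conditions are
    g_j = λ·sign(β_j) for β_j ≠ 0 and |g_j| ≤ λ for β_j = 0, where
    g = (1/n)·X'(y − p); the intercept must have zero gradient.
    """
    g = _lasso_grad(X_std, y, intercept, beta)
    p = expit(np.clip(intercept + X_std @ beta, -30.0, 30.0))
    viol = abs(float(np.mean(y - p)))  # intercept stationarity
    nz = beta != 0
    if np.any(nz):
        viol = max(viol, float(np.max(np.abs(g[nz] - lam * np.sign(beta[nz])))))
    if np.any(~nz):
        viol = max(viol, max(0.0, float(np.max(np.abs(g[~nz])) - lam)))
    return viol


def _fit_lasso_point(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    intercept: float,
    beta: np.ndarray,
    kkt_tol: float = 1e-9,
    max_outer: int = 100,
):
    """Penalized IRLS with inner coordinate descent; warm-started.

    Bails out early when coefficients diverge on the standardized scale
    (quasi-separation at small λ); the caller detects the unmet
    stationarity tolerance and truncates the path.
    """
    n, p = X.shape
    beta = beta.copy()
    best_viol = np.inf
    stall = 0
    for _ in range(max_outer):
        if np.max(np.abs(beta), initial=0.0) > SEPARATION_BOUND:
            break
        viol = lasso_kkt_violation(X, y, intercept, beta, lam)
        if viol < kkt_tol:
            break
        if viol > 0.7 * best_viol:
            stall += 1
            if stall > 10:
                break
        else:
            stall = 0
        best_viol = min(best_viol, viol)
        eta = np.clip(intercept + X @ beta, -30.0, 30.0)
        prob = expit(eta)
        w = np.clip(prob * (1 - prob), 1e-6, None)
        z = eta + (y - prob) / w
        # absorb the unpenalized intercept by weighted centering, then run
        # coordinate descent in covariance (Gram) form: O(p) per coordinate
        w_sum = float(np.sum(w))
        xbar = (w @ X) / w_sum
        zbar = float(w @ z) / w_sum
        Xc = X - xbar
        G = (Xc * w[:, None]).T @ Xc / n
        b = (Xc * w[:, None]).T @ (z - zbar) / n
        beta = _cd_passes(np.ascontiguousarray(G), b, beta, lam, 2000, 1e-13)
        intercept = zbar - float(xbar @ beta)
    return intercept, beta


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_passes_py(G, b, beta, lam, max_pass, tol):
    """Cyclic coordinate descent on ½β'Gβ − b'β + λ|β|₁ (in place)."""
    p = beta.size
    Gb = G @ beta
    for _ in range(max_pass):
        max_step = 0.0
        for j in range(p):
            bj = beta[j]
            rho = b[j] - Gb[j] + G[j, j] * bj
            if rho > lam:
                nb = (rho - lam) / G[j, j]
            elif rho < -lam:
                nb = (rho + lam) / G[j, j]
            else:
                nb = 0.0
            if nb != bj:
                d = nb - bj
                for k in range(p):
                    Gb[k] += G[k, j] * d
                if abs(d) > max_step:
                    max_step = abs(d)
                beta[j] = nb
        if max_step < tol:
            break
    return beta


try:  # compiled kernel: the cyclic passes are the hot loop of the path solver
    from numba import njit

    _cd_passes = njit(cache=False)(_cd_passes_py)
except ImportError:  # pragma: no cover
    _cd_passes = _cd_passes_py


def _standardize(table: pd.DataFrame, candidates: Sequence[str]):
    X = table[list(candidates)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, glmnet-style
    if np.any(sd == 0):
        const = list(candidates)[int(np.argmin(sd))]
        raise ValueError(f"constant covariate {const} cannot be standardized")
    return (X - mean) / sd, mean, sd


def _lambda_path(X_std, y, n_lambda: int):
    n = len(y)
    lam_max = float(np.max(np.abs(X_std.T @ (y - y.mean()))) / n)
    ratio = 1e-4 if n > X_std.shape[1] else 1e-2
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _lasso_path(
    X_std,
    y,
    lambdas,
    kkt_tol: float = 1e-9,
    dev_explained_max: float = 0.99,
    fill_tail: bool = False,
):
    """Warm-started solution path over a descending λ sequence.

    The path stops early once the fit approaches saturation (fraction of
    null deviance explained above ``dev_explained_max``) or a point fails to
    reach the stationarity tolerance — the usual guards against the
    quasi-separated, unstable near-MLE end of the path on small cohorts.
    With ``fill_tail`` the last converged point is carried forward over the
    remaining λ values (used for fold fits during cross-validation);
    otherwise the returned arrays are truncated.
    """
    n, p = X_std.shape
    ybar = y.mean()
    null_dev = _binomial_deviance(y, np.full(n, ybar))
    intercept = float(np.log(ybar / (1 - ybar)))
    beta = np.zeros(p)
    used, intercepts, betas = [], [], []
    for lam in lambdas:
        intercept_new, beta_new = _fit_lasso_point(
            X_std, y, lam, intercept, beta.copy(), kkt_tol
        )
        if lasso_kkt_violation(X_std, y, intercept_new, beta_new, lam) > 1e-7:
            break  # unstable (quasi-separated) point: truncate the path here
        intercept, beta = intercept_new, beta_new
        used.append(lam)
        intercepts.append(intercept)
        betas.append(beta.copy())
        prob = expit(np.clip(intercept + X_std @ beta, -30.0, 30.0))
        if 1.0 - _binomial_deviance(y, prob) / null_dev > dev_explained_max:
            break
    if fill_tail:
        while len(used) < len(lambdas):
            used.append(lambdas[len(used)])
            intercepts.append(intercepts[-1])
            betas.append(betas[-1].copy())
    return np.asarray(used), np.asarray(intercepts), np.asarray(betas)


def _binomial_deviance(y, prob):
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return -2.0 * np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob))


def lasso_select(
    table: pd.DataFrame,
    candidates: Sequence[str],
    n_lambda: int = 100,
    cv_folds: int = 10,
    seed: int = 20240601,
    outcome: str = OUTCOME_COLUMN,
) -> SelectionResult:
    """L1-penalized logistic regression path with cross-validated λ choice.

    Covariates are standardized (mean 0, population sd 1); the path runs from
    λ_max — the smallest λ at which every coefficient is exactly zero — down a
    log-spaced grid, warm-starting each point. The selected set is the
    support of the coefficient vector at the λ minimizing K-fold
    cross-validated binomial deviance. The reported final model is
    back-transformed to the original percent scale.
    """
    candidates = list(candidates)
    y = table[outcome].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    X_std, mean, sd = _standardize(table, candidates)
    lambdas, intercepts, betas = _lasso_path(
        X_std, y, _lambda_path(X_std, y, n_lambda)
    )

    # K-fold CV deviance along the same (truncated) lambda sequence
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_dev = np.zeros(len(lambdas))
    for train_idx, val_idx in skf.split(X_std, y):
        Xt, yt = X_std[train_idx], y[train_idx]
        _, ints_t, betas_t = _lasso_path(
            Xt, yt, lambdas, kkt_tol=1e-8, fill_tail=True
        )
        for i in range(len(lambdas)):
            prob = expit(ints_t[i] + X_std[val_idx] @ betas_t[i])
            cv_dev[i] += _binomial_deviance(y[val_idx], prob)
    cv_dev /= len(y)

    best_i = int(np.argmin(cv_dev))
    beta_std = betas[best_i]
    support = beta_std != 0
    selected = [c for c, s in zip(candidates, support) if s]

    beta_orig = beta_std / sd
    intercept_orig = float(intercepts[best_i] - np.sum(beta_std * mean / sd))
    final = LogisticModel(
        intercept=intercept_orig,
        coefficients={c: float(b) for c, b in zip(candidates, beta_orig) if b != 0},
    )
    coef_path_orig = betas / sd[None, :]
    trace = [
        {"lambda": float(l), "cv_deviance": float(d)} for l, d in zip(lambdas, cv_dev)
    ]
    return SelectionResult(
        method="lasso",
        selected=selected,
        criterion_trace=trace,
        final_model=final,
        lambdas=lambdas,
        coef_path=coef_path_orig,
        cv_deviance=cv_dev,
    )


# ---------------------------------------------------------------------------
# bagged-tree importance (random-forest style)


def ensemble_importance(
    table: pd.DataFrame,
    candidates: Sequence[str],
    n_trees: int = 500,
    seed: int = 20240601,
    outcome: str = OUTCOME_COLUMN,
) -> SelectionResult:
    """Random-forest style importance ranking of the candidate covariates.

    Bagged CART trees (Gini splitting, √p random feature subsets, bootstrap
    resampling). Importance is reported two ways, following the usual forest
    conventions: mean decrease in out-of-bag accuracy under per-feature
    permutation, and mean total Gini impurity decrease. The returned
    ``selected`` list is the permutation-importance ranking in descending
    order; no final model is fitted.
    """
    candidates = list(candidates)
    X = table[candidates].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=int)
    n = len(y)
    if n < 10:
        raise ValueError(f"n = {n} too small for out-of-bag estimates (need >= 10)")

    rng = np.random.default_rng(seed)
    acc_drop = np.zeros((n_trees, len(candidates)))
    acc_count = np.zeros(len(candidates))
    gini = np.zeros((n_trees, len(candidates)))
    used = 0
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        gini[t] = tree.tree_.compute_feature_importances(normalize=False)
        if oob.size == 0:
            continue
        used += 1
        base_acc = float(np.mean(tree.predict(X[oob]) == y[oob]))
        for j in range(len(candidates)):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            acc_drop[t, j] = base_acc - float(np.mean(tree.predict(Xp) == y[oob]))
            acc_count[j] += 1

    mda = acc_drop.sum(axis=0) / np.maximum(acc_count, 1)
    mdg = gini.mean(axis=0)
    order = np.argsort(-mda, kind="stable")
    importances = {
        "mean_decrease_accuracy": {c: float(v) for c, v in zip(candidates, mda)},
        "mean_decrease_gini": {c: float(v) for c, v in zip(candidates, mdg)},
    }
    trace = [
        {"variable": candidates[j], "mda": float(mda[j]), "mdg": float(mdg[j])}
        for j in order
    ]
    return SelectionResult(
        method="ensemble_importance",
        selected=[candidates[j] for j in order],
        criterion_trace=trace,
        importances=importances,
    )
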