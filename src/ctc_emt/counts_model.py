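"""Multi-response Poisson regression with exhaustive cross-validated selection.

The central statistical machinery of the pipeline.  Counts of the three CTC
phenotypes (eCTC, emCTC, mCTC) are modeled simultaneously as three Poisson
log-linear regressions sharing one predictor subset; the joint
log-likelihood is their sum (no cross-response covariance is modeled, and
effects — incidence-rate ratios, IRRs — are reported per response).

Model selection enumerates every predictor subset (2^p models for p
candidates), scores each by repeated k-fold cross-validation (held-out
log-likelihood, training AIC, held-out count-scale RMSE pooled over the
three responses; averaged over folds, then over repetitions), and ranks
competing models lexicographically by (min avg.RMSE, max avg.logLik,
min avg.AIC).  Subsets containing a user-declared excluded predictor pair,
and subsets whose fits fail to converge in cross-validation (a practical
symptom of quasi-separation), are flagged and do not compete.

Explained variability uses the Nagelkerke pseudo-R² against the
intercept-only model,

    R² = [1 − exp((2/n)(ℓ₀ − ℓ₁))] / [1 − exp((2/n) ℓ₀)],

and a predictor's partial pseudo-R² for a response is the drop in that
response's R² when the predictor is removed from the full model.

The Poisson fits themselves are iteratively reweighted least squares
(IRLS) maximum likelihood on small dense design matrices, with a
separation guard (any |β| above a bound marks the fit non-converged);
the compact fitter keeps the ~10^5 fits of a repeated-CV exhaustive
search affordable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .phenotyping import PHENOTYPES

Z_95 = 1.959964  # two-sided 95% normal quantile

# ---------------------------------------------------------------------------
# model space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """One candidate model: an ordered predictor subset for all 3 responses."""

    predictors: tuple[str, ...]
    responses: tuple[str, ...] = PHENOTYPES
    rule_flagged: bool = False  # contains an excluded predictor pair

    @property
    def is_null(self) -> bool:
        return not self.predictors

    def label(self) -> str:
        return " + ".join(self.predictors) if self.predictors else "(intercept only)"


def enumerate_models(
    candidates: Sequence[str],
    exclusions: Iterable[tuple[str, str]] = (),
) -> list[DesignSpec]:
    """All 2^p predictor subsets in deterministic (size, index) order.

    Subsets containing any excluded pair are kept in the output but
    flagged ``rule_flagged`` so selection skips them.
    """
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate predictor names")
    exclusion_sets = [frozenset(pair) for pair in exclusions]
    specs = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            flagged = any(es <= set(combo) for es in exclusion_sets)
            specs.append(DesignSpec(predictors=combo, rule_flagged=flagged))
    return specs


# ---------------------------------------------------------------------------
# Poisson IRLS fit
# ---------------------------------------------------------------------------


@dataclass
class PoissonFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    names: tuple[str, ...]
    n: int

    @property
    def k(self) -> int:
        return len(self.beta)


def fit_poisson(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    beta_bound: float = 15.0,
) -> PoissonFit:
    """Poisson log-linear ML fit via IRLS.

    Non-convergence within ``max_iter`` iterations, a numerically singular
    weighted normal system, or any |β| exceeding ``beta_bound`` (a
    practical separation guard) yield ``converged=False``; the fit is
    still returned so cross-validation can apply its exclusion logic.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("y must be (n,), X must be (n, p)")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    # warm start for an intercept column of ones
    ones = np.all(X[:, 0] == 1.0)
    if ones:
        beta[0] = np.log(max(y.mean(), 1e-8))
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        XtW = X.T * mu
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ (eta + (y - mu) / mu))
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > beta_bound:
        converged = False

    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    try:
        cov = np.linalg.inv((X.T * mu) @ X)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    loglik = float(np.sum(y * eta - mu - gammaln(y + 1.0)))
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    return PoissonFit(beta=beta, se=se, loglik=loglik, converged=converged,
                      names=tuple(names), n=n)


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood of counts ``y`` at means ``mu``."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, None)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def build_design(
    data: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix [1 | predictor columns] from a patient table."""
    missing = [p for p in predictors if p not in data.columns]
    if missing:
        raise ValueError(f"predictors not in data: {missing}")
    X = np.column_stack(
        [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in predictors]
    )
    return X, ("intercept", *predictors)


def round_counts(y: np.ndarray) -> np.ndarray:
    """Half-up rounding of (possibly volume-extrapolated fractional) counts.

    The Poisson likelihood needs integers; descriptive statistics keep the
    fractional values, only model fits round.
    """
    return np.floor(np.asarray(y, dtype=float) + 0.5)


# ---------------------------------------------------------------------------
# multi-response fit
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    spec: DesignSpec
    per_response: dict[str, PoissonFit]
    loglik: float
    k: int
    aic: float
    converged: bool


def fit_multiresponse(data: pd.DataFrame, spec: DesignSpec, **fit_kwargs) -> ModelFit:
    """Fit one Poisson regression per response on the shared predictor subset.

    Joint log-likelihood is the sum over responses, k the total parameter
    count, AIC = 2k − 2·logLik; convergence requires all responses.
    """
    missing = [r for r in spec.responses if r not in data.columns]
    if missing:
        raise ValueError(f"response columns not in data: {missing}")
    X, names = build_design(data, spec.predictors)
    fits: dict[str, PoissonFit] = {}
    for resp in spec.responses:
        y = round_counts(data[resp].to_numpy())
        fits[resp] = fit_poisson(y, X, names=names, **fit_kwargs)
    loglik = sum(f.loglik for f in fits.values())
    k = sum(f.k for f in fits.values())
    converged = all(f.converged for f in fits.values())
    aic = 2.0 * k - 2.0 * loglik if converged else float("inf")
    return ModelFit(spec=spec, per_response=fits, loglik=loglik, k=k,
                    aic=aic, converged=converged)


@dataclass(frozen=True)
class IrrEstimate:
    response: str
    predictor: str
    irr: float
    ci_low: float
    ci_high: float
    p_value: float


def irr_table(fit: ModelFit) -> list[IrrEstimate]:
    """Wald IRRs with 95% CIs, per response per predictor (intercept skipped)."""
    out = []
    for resp, pf in fit.per_response.items():
        for j, name in enumerate(pf.names):
            if name == "intercept":
                continue
            b, se = pf.beta[j], pf.se[j]
            z = b / se if se > 0 else np.inf * np.sign(b)
            out.append(
                IrrEstimate(
                    response=resp,
                    predictor=name,
                    irr=float(np.exp(b)),
                    ci_low=float(np.exp(b - Z_95 * se)),
                    ci_high=float(np.exp(b + Z_95 * se)),
                    p_value=float(2.0 * norm.sf(abs(z))),
                )
            )
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvMetrics:
    avg_loglik: float
    avg_aic: float
    avg_rmse: float
    n_failed_fits: int
    excluded: bool
    reason: str = ""


def crossval_model(
    data: pd.DataFrame,
    spec: DesignSpec,
    k: int = 10,
    reps: int = 500,
    seed: int = 0,
    max_failures: int = 0,
    **fit_kwargs,
) -> CvMetrics:
    """Repeated k-fold cross-validation of one candidate model.

    Each repetition draws a fresh random partition into ``k`` folds (sizes
    differing by at most one).  Per fold: the model is fit on the training
    folds; the held-out log-likelihood, the training-fit AIC, and the RMSE
    of predicted means vs observed counts (count scale, pooled over the
    three responses) are recorded.  Metrics are averaged over folds within
    a repetition, then over repetitions.

    Any fold with a non-converged response fit is dropped from the
    averages and counted; more than ``max_failures`` failed folds in total
    (default: any failure) marks the model excluded from competition.
    """
    n = len(data)
    if n < k:
        raise ValueError(f"need at least k={k} patients, got {n}")
    rng = np.random.default_rng(seed)
    X_all, _ = build_design(data, spec.predictors)
    Y_all = {r: round_counts(data[r].to_numpy()) for r in spec.responses}
    k_params = len(spec.responses) * X_all.shape[1]

    rep_loglik, rep_aic, rep_rmse = [], [], []
    n_failed = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        f_loglik, f_aic, f_rmse = [], [], []
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            X_tr, X_te = X_all[train_mask], X_all[test_idx]
            ll_train = 0.0
            ll_test = 0.0
            sq = 0.0
            n_resid = 0
            ok = True
            for resp in spec.responses:
                y_tr = Y_all[resp][train_mask]
                y_te = Y_all[resp][test_idx]
                try:
                    fit = fit_poisson(y_tr, X_tr, **fit_kwargs)
                except ValueError:
                    ok = False
                    break
                if not fit.converged:
                    ok = False
                    break
                mu_te = np.exp(np.clip(X_te @ fit.beta, -30.0, 30.0))
                ll_train += fit.loglik
                ll_test += poisson_loglik(y_te, mu_te)
                sq += float(np.sum((mu_te - y_te) ** 2))
                n_resid += len(y_te)
            if not ok:
                n_failed += 1
                continue
            f_loglik.append(ll_test)
            f_aic.append(2.0 * k_params - 2.0 * ll_train)
            f_rmse.append(np.sqrt(sq / n_resid))
        if f_loglik:
            rep_loglik.append(np.mean(f_loglik))
            rep_aic.append(np.mean(f_aic))
            rep_rmse.append(np.mean(f_rmse))

    excluded = n_failed > max_failures
    reason = (
        f"{n_failed} cross-validation fold fit(s) failed to converge"
        if excluded
        else ""
    )
    if not rep_loglik:
        return CvMetrics(float("nan"), float("inf"), float("inf"),
                         n_failed, True, reason or "all folds failed")
    return CvMetrics(
        avg_loglik=float(np.mean(rep_loglik)),
        avg_aic=float(np.mean(rep_aic)),
        avg_rmse=float(np.mean(rep_rmse)),
        n_failed_fits=n_failed,
        excluded=excluded,
        reason=reason,
    )


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    ranking: list[tuple[DesignSpec, CvMetrics]]  # competing models, best first
    best: DesignSpec
    non_competing: list[tuple[DesignSpec, CvMetrics, str]] = field(
        default_factory=list
    )


def select_best(
    metrics: Sequence[tuple[DesignSpec, CvMetrics]]
) -> SelectionResult:
    """Rank competing models by (min avg.RMSE, max avg.logLik, min avg.AIC).

    The ordering is lexicographic, so avg.RMSE decides unless exactly
    tied.  Rule-flagged subsets and convergence-excluded models do not
    compete but are reported with the reason.
    """
    competing: list[tuple[DesignSpec, CvMetrics]] = []
    dropped: list[tuple[DesignSpec, CvMetrics, str]] = []
    for spec, cv in metrics:
        if spec.rule_flagged:
            dropped.append((spec, cv, "contains excluded predictor pair"))
        elif cv.excluded:
            dropped.append((spec, cv, cv.reason))
        else:
            competing.append((spec, cv))
    if not competing:
        raise ValueError("all candidate models are excluded")
    competing.sort(key=lambda sc: (sc[1].avg_rmse, -sc[1].avg_loglik, sc[1].avg_aic))
    return SelectionResult(ranking=competing, best=competing[0][0],
                           non_competing=dropped)


def run_selection(
    data: pd.DataFrame,
    candidates: Sequence[str],
    exclusions: Iterable[tuple[str, str]] = (),
    k: int = 10,
    reps: int = 500,
    seed: int = 0,
) -> tuple[SelectionResult, list[tuple[DesignSpec, CvMetrics]]]:
    """Exhaustive cross-validated model search over all candidate subsets.

    Every model is evaluated on the *same* sequence of random fold
    partitions (one shared seed), so between-model metric differences
    reflect the models, not partition luck — a paired comparison.
    Rule-flagged subsets skip cross-validation entirely (they cannot
    compete) and carry NaN metrics.
    """
    specs = enumerate_models(candidates, exclusions)
    scored: list[tuple[DesignSpec, CvMetrics]] = []
    for spec in specs:
        if spec.rule_flagged:
            cv = CvMetrics(float("nan"), float("nan"), float("nan"), 0, True,
                           "contains excluded predictor pair")
        else:
            cv = crossval_model(data, spec, k=k, reps=reps, seed=seed)
        scored.append((spec, cv))
    return select_best(scored), scored


# ---------------------------------------------------------------------------
# pseudo-R²
# ---------------------------------------------------------------------------


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R² of a fitted model against its null on n units."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_full < loglik_null - 1e-8:
        warnings.warn(
            "full-model log-likelihood below null; check convergence",
            stacklevel=2,
        )
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_full))
    max_r2 = 1.0 - np.exp((2.0 / n) * loglik_null)
    if max_r2 <= 0:
        return 0.0
    return float(cox_snell / max_r2)


@dataclass
class R2Decomposition:
    overall_r2: float  # joint-likelihood Nagelkerke R² of the full model
    per_response_r2: dict[str, float]
    partial_r2: dict[tuple[str, str], float]  # (response, predictor) -> drop


def partial_r2(data: pd.DataFrame, full_spec: DesignSpec) -> R2Decomposition:
    """Nagelkerke partial pseudo-R² per predictor, separately per response.

    For each response, the partial R² of predictor p is the full model's
    R² minus the R² of the model with p removed, both against the
    intercept-only model for that response.  The joint ``overall_r2``
    uses the summed log-likelihoods with n = number of patients.
    """
    if not full_spec.predictors:
        raise ValueError("full model must contain at least one predictor")
    n = len(data)
    full = fit_multiresponse(data, full_spec)
    null = fit_multiresponse(data, DesignSpec(predictors=(),
                                              responses=full_spec.responses))
    overall = nagelkerke_r2(full.loglik, null.loglik, n)
    per_resp = {
        r: nagelkerke_r2(full.per_response[r].loglik,
                         null.per_response[r].loglik, n)
        for r in full_spec.responses
    }
    partial: dict[tuple[str, str], float] = {}
    for pred in full_spec.predictors:
        reduced_preds = tuple(p for p in full_spec.predictors if p != pred)
        reduced = fit_multiresponse(
            data, DesignSpec(predictors=reduced_preds,
                             responses=full_spec.responses)
        )
        for r in full_spec.responses:
            r2_reduced = nagelkerke_r2(
                reduced.per_response[r].loglik, null.per_response[r].loglik, n
            )
            partial[(r, pred)] = per_resp[r] - r2_reduced
    return R2Decomposition(overall_r2=overall, per_response_r2=per_resp,
                           partial_r2=partial)
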