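"""Cox proportional-hazards machinery for the prognostic gene model.

Implements, from the partial-likelihood definitions:

* Newton-Raphson maximum partial likelihood with Efron tie handling
  (follow-up is recorded at months resolution, so ties are common),
* the score test at beta = 0 (equal to the log-rank statistic for an
  untied binary covariate),
* L1-penalized (LASSO) Cox regression by cyclic coordinate descent on the
  quadratic approximation of the penalized partial likelihood, with a
  log-spaced lambda path, warm starts, and Verweij-van Houwelingen
  cross-validated partial-likelihood deviance for choosing lambda,
* the Breslow baseline hazard and a quantile-binned calibration table.

Kaplan-Meier curves and the log-rank test are delegated to lifelines, and
the IPCW cumulative/dynamic time-dependent AUC to scikit-survival; both are
standard estimators, not this package's contribution. Covariates enter as
z-scored log10(FPKM + 1) so the L1 penalty treats genes commensurately; the
transform is frozen on the development cohort and reapplied to validation
samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "CovariateTransform",
    "RiskModel",
    "efron_loglik",
    "newton_cox",
    "cox_score_test",
    "prepare_covariates",
    "univariate_cox_screen",
    "lasso_cox_fit",
    "lambda_max",
    "split_cohort",
    "risk_score",
    "km_logrank",
    "time_dependent_auc",
    "breslow_baseline",
    "calibration_at",
]

logger = logging.getLogger("ferrostrat")


# ---------------------------------------------------------------------------
# Efron partial likelihood and derivatives


def _efron_parts(time: np.ndarray, event: np.ndarray, X: np.ndarray, beta: np.ndarray,
                 order: int = 2):
    """Efron log partial likelihood and (optionally) gradient and Hessian.

    Fully vectorized over event times: risk-set sums come from suffix
    cumulative sums, tied-death corrections from reduceat over the tied
    blocks. Returns (loglik, grad, hess); grad/hess are None below the
    requested derivative order.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not event.any():
        z = np.zeros(p)
        return 0.0, (z if order >= 1 else None), (np.zeros((p, p)) if order >= 2 else None)

    srt = np.argsort(time, kind="stable")
    t, d, Xs = time[srt], event[srt], X[srt]
    eta = Xs @ beta
    eta -= eta.max()  # partial likelihood is shift-invariant; guards overflow
    w = np.exp(eta)

    wx = w[:, None] * Xs if order >= 1 else None
    wxx = (Xs[:, :, None] * Xs[:, None, :]) * w[:, None, None] if order >= 2 else None

    def suffix(a):
        return np.cumsum(a[::-1], axis=0)[::-1]

    S0 = suffix(w)
    S1 = suffix(wx) if order >= 1 else None
    S2 = suffix(wxx) if order >= 2 else None

    te, we, Xe = t[d], w[d], Xs[d]
    ut, start = np.unique(te, return_index=True)
    dk = np.diff(np.append(start, len(te)))
    first = np.searchsorted(t, ut, side="left")

    S0D = np.add.reduceat(we, start)
    S0R = S0[first]
    idx = np.repeat(np.arange(len(ut)), dk)
    phi = (np.arange(len(te)) - np.repeat(start, dk)) / dk[idx]

    S0a = S0R[idx] - phi * S0D[idx]
    loglik = float(eta[d].sum() - np.log(S0a).sum())
    grad = hess = None
    if order >= 1:
        S1D = np.add.reduceat(we[:, None] * Xe, start, axis=0)
        S1a = S1[first][idx] - phi[:, None] * S1D[idx]
        m = S1a / S0a[:, None]
        grad = Xe.sum(axis=0) - m.sum(axis=0)
    if order >= 2:
        S2D = np.add.reduceat((Xe[:, :, None] * Xe[:, None, :]) * we[:, None, None], start, axis=0)
        S2a = S2[first][idx] - phi[:, None, None] * S2D[idx]
        hess = -(S2a / S0a[:, None, None] - m[:, :, None] * m[:, None, :]).sum(axis=0)
    return loglik, grad, hess


def efron_loglik(time, event, X, beta) -> float:
    """Efron log partial likelihood at ``beta``."""
    ll, _, _ = _efron_parts(time, event, X, np.asarray(beta, dtype=float), order=0)
    return ll


# ---------------------------------------------------------------------------
# Newton-Raphson fit


@dataclass
class CoxFit:
    """Maximum partial-likelihood fit of one or more covariates."""

    coef: pd.Series
    se: pd.Series
    loglik: float
    n_iter: int
    converged: bool

    @property
    def hazard_ratio(self) -> pd.Series:
        return np.exp(self.coef).rename("HR")

    @property
    def z(self) -> pd.Series:
        return (self.coef / self.se).rename("z")

    @property
    def p_value(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.z)), index=self.coef.index, name="p")


def newton_cox(time, event, X, names=None, tol: float = 1e-8,
               max_iter: int = 50) -> CoxFit:
    """Newton-Raphson on the Efron partial likelihood with step-halving.

    Converges on the score (gradient) norm; a fit that exhausts
    ``max_iter`` or hits a singular Hessian is returned with
    ``converged=False``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    beta = np.zeros(p)
    ll, g, H = _efron_parts(time, event, X, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            break
        for _ in range(40):  # step-halving on likelihood decrease
            cand = beta + step
            ll_new = efron_loglik(time, event, X, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            break
        beta, ll = cand, ll_new
        ll, g, H = _efron_parts(time, event, X, beta)
    else:
        it = max_iter
    if not converged and np.linalg.norm(g) < tol:
        converged = True
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return CoxFit(
        coef=pd.Series(beta, index=names, name="coef"),
        se=pd.Series(se, index=names, name="se"),
        loglik=ll, n_iter=it, converged=converged,
    )


def cox_score_test(time, event, x) -> tuple[float, float]:
    """Cox score test of a single covariate at beta = 0.

    Returns (chi-square statistic, P). For an untied binary covariate this
    equals the two-sample log-rank test.
    """
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    _, g, H = _efron_parts(time, event, X, np.zeros(1))
    info = -H[0, 0]
    if info <= 0:
        return 0.0, 1.0
    stat = float(g[0] ** 2 / info)
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# covariate preparation and univariate screen


@dataclass
class CovariateTransform:
    """Frozen log10(FPKM + pc) -> z-score transform of the development cohort."""

    genes: list[str]
    means: pd.Series
    stds: pd.Series
    pseudocount: float = 1.0

    def apply(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Genes x samples FPKM -> samples x genes standardized covariates."""
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise KeyError(f"gene(s) absent from expression matrix: {missing}")
        logs = np.log10(expr.loc[self.genes].to_numpy(dtype=float) + self.pseudocount)
        z = (logs - self.means.to_numpy()[:, None]) / self.stds.to_numpy()[:, None]
        return pd.DataFrame(z.T, index=expr.columns, columns=self.genes)


def prepare_covariates(expr: pd.DataFrame, genes=None, pseudocount: float = 1.0,
                       transform: CovariateTransform | None = None):
    """Build the samples x genes covariate matrix for Cox modeling.

    With no ``transform``, means/SDs are estimated from ``expr`` (the
    development cohort) and returned as a frozen transform; constant genes
    get SD 1 so their z-scores are 0. Returns (X, transform).
    """
    if transform is None:
        genes = list(genes) if genes is not None else list(expr.index)
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise KeyError(f"gene(s) absent from expression matrix: {missing}")
        logs = np.log10(expr.loc[genes].to_numpy(dtype=float) + pseudocount)
        means = logs.mean(axis=1)
        stds = logs.std(axis=1, ddof=0)
        stds[stds == 0] = 1.0
        transform = CovariateTransform(
            genes=genes,
            means=pd.Series(means, index=genes),
            stds=pd.Series(stds, index=genes),
            pseudocount=pseudocount,
        )
    return transform.apply(expr), transform


def _aligned_arrays(X: pd.DataFrame, survival: pd.DataFrame):
    shared = X.index.intersection(survival.index)
    if len(shared) < len(X):
        logger.info("dropping %d sample(s) without survival records", len(X) - len(shared))
    surv = survival.loc[shared]
    return (X.loc[shared].to_numpy(dtype=float), surv["time"].to_numpy(dtype=float),
            surv["event"].to_numpy(dtype=int), shared)


def univariate_cox_screen(X: pd.DataFrame, survival: pd.DataFrame,
                          p_threshold: float = 0.1):
    """Single-covariate Cox fit per gene; retain genes with Wald P below
    ``p_threshold``.

    ``X`` is samples x genes (see :func:`prepare_covariates`). Returns
    (per-gene result table, retained gene list). Warns below 10 events;
    non-convergent genes are excluded from retention with a warning.
    """
    Xa, t, e, _ = _aligned_arrays(X, survival)
    if e.sum() < 10:
        warnings.warn(f"only {int(e.sum())} events; univariate screen is underpowered")
    rows = []
    for j, gene in enumerate(X.columns):
        fit = newton_cox(t, e, Xa[:, [j]], names=[gene])
        if not fit.converged:
            logger.warning("univariate Cox did not converge for %s; excluded", gene)
        rows.append({
            "gene": gene, "coef": float(fit.coef.iloc[0]), "hr": float(fit.hazard_ratio.iloc[0]),
            "se": float(fit.se.iloc[0]), "p_value": float(fit.p_value.iloc[0]),
            "converged": fit.converged,
        })
    table = pd.DataFrame(rows).set_index("gene")
    retained = table.index[(table["p_value"] < p_threshold) & table["converged"]].tolist()
    return table, retained


# ---------------------------------------------------------------------------
# LASSO Cox


def lambda_max(X: pd.DataFrame | np.ndarray, time, event) -> float:
    """Smallest penalty at which the all-zero solution is optimal, for the
    objective -pl(beta)/n + lambda * ||beta||_1."""
    Xa = np.asarray(X, dtype=float)
    _, g, _ = _efron_parts(time, event, Xa, np.zeros(Xa.shape[1]), order=1)
    return float(np.max(np.abs(g)) / len(Xa))


def _penalized_obj(t, e, X, beta, lam) -> float:
    return -efron_loglik(t, e, X, beta) / len(X) + lam * np.abs(beta).sum()


def _lasso_fit_one(t, e, X, lam, beta0, outer_tol=1e-7, max_outer=100,
                   inner_tol=1e-9, max_inner=1000) -> np.ndarray:
    """One penalized fit by outer quadratic approximation + inner cyclic
    coordinate descent, warm-started at ``beta0``."""
    n, p = X.shape
    beta = beta0.copy()
    for _ in range(max_outer):
        ll, g_ll, H_ll = _efron_parts(t, e, X, beta)
        g = -g_ll / n
        H = -H_ll / n
        H = H + 1e-10 * np.eye(p)  # guards a numerically singular quadratic model
        # inner CD on: g'(b-beta) + 1/2 (b-beta)' H (b-beta) + lam |b|_1
        delta = np.zeros(p)
        r = np.zeros(p)  # H @ delta, maintained incrementally
        for _ in range(max_inner):
            max_move = 0.0
            for j in range(p):
                uj_old = beta[j] + delta[j]
                cj = g[j] + r[j] - H[j, j] * delta[j]
                zj = H[j, j] * beta[j] - cj
                uj = np.sign(zj) * max(abs(zj) - lam, 0.0) / H[j, j]
                if uj != uj_old:
                    dj_new = uj - beta[j]
                    r += H[:, j] * (dj_new - delta[j])
                    delta[j] = dj_new
                    max_move = max(max_move, abs(uj - uj_old))
            if max_move < inner_tol:
                break
        cand = beta + delta
        # step-halving on the exact penalized objective
        obj0 = -ll / n + lam * np.abs(beta).sum()
        for _ in range(30):
            if _penalized_obj(t, e, X, cand, lam) <= obj0 + 1e-12:
                break
            cand = (beta + cand) / 2.0
        move = np.max(np.abs(cand - beta))
        beta = cand
        if move < outer_tol:
            break
    return beta


def _fit_path(t, e, X, lambdas) -> np.ndarray:
    """Warm-started coefficient path, shape (len(lambdas), p), lambdas descending."""
    p = X.shape[1]
    path = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = _lasso_fit_one(t, e, X, lam, beta)
        path[i] = beta
    return path


@dataclass
class RiskModel:
    """Fitted LASSO-Cox prognostic model."""

    genes: list[str]
    coef: pd.Series
    lambda_: float
    lambda_path: np.ndarray
    coef_path: pd.DataFrame            # lambdas x genes
    cv_deviance: pd.DataFrame | None   # lambda, mean, se
    transform: CovariateTransform | None = None
    training_samples: list[str] = field(default_factory=list)
    selection: str = "min"
    lambda_min: float | None = None
    lambda_1se: float | None = None

    @property
    def selected_genes(self) -> list[str]:
        return self.coef.index[self.coef != 0].tolist()


def lasso_cox_fit(X: pd.DataFrame, survival: pd.DataFrame, n_lambdas: int = 100,
                  lambda_min_ratio: float = 0.01, cv_folds: int = 5, seed: int = 0,
                  lambdas=None, transform: CovariateTransform | None = None,
                  selection: str = "min") -> RiskModel:
    """LASSO-penalized Cox fit with cross-validated lambda selection.

    The path is log-spaced over [lambda_max, lambda_min_ratio * lambda_max]
    (descending, warm-started); the CV loss is the mean Verweij-van
    Houwelingen cross-validated partial-likelihood deviance over
    ``cv_folds`` event-stratified folds. ``selection="min"`` (default)
    takes the deviance-minimizing lambda — the prediction-optimal choice,
    which typically carries a few small-coefficient extra genes;
    ``selection="1se"`` takes the largest lambda within one standard error
    of the minimum — the parsimonious choice appropriate when support
    recovery matters. The returned coefficients are the full-data path fit
    at the chosen lambda. An all-zero solution is legal but warned about.
    """
    if selection not in ("min", "1se"):
        raise ValueError(f"unknown selection rule {selection!r}")
    Xa, t, e, shared = _aligned_arrays(X, survival)
    n, p = Xa.shape
    if p < 1:
        raise ValueError("no covariates")
    if e.sum() == 0:
        raise ValueError("no events in the cohort")
    lmax = lambda_max(Xa, t, e)
    if lambdas is None:
        lambdas = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)

    path = _fit_path(t, e, Xa, lambdas)

    cv_table = None
    if cv_folds and cv_folds > 1:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        devs = np.zeros((cv_folds, len(lambdas)))
        for f, (tr, _) in enumerate(skf.split(Xa, e)):
            if e[tr].sum() == 0:
                raise ValueError(f"CV fold {f} has no events in its training part")
            sub_path = _fit_path(t[tr], e[tr], Xa[tr], lambdas)
            for i in range(len(lambdas)):
                pl_full = efron_loglik(t, e, Xa, sub_path[i])
                pl_train = efron_loglik(t[tr], e[tr], Xa[tr], sub_path[i])
                devs[f, i] = -2.0 * (pl_full - pl_train)
        mean_dev = devs.mean(axis=0)
        se_dev = devs.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        i_min = int(np.argmin(mean_dev))
        lam_min = float(lambdas[i_min])
        within = mean_dev <= mean_dev[i_min] + se_dev[i_min]
        lam_1se = float(lambdas[within].max())
        best = i_min if selection == "min" else int(np.argmax(lambdas == lam_1se))
        cv_table = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev, "se": se_dev})
    else:
        best = len(lambdas) - 1
        lam_min = lam_1se = float(lambdas[best])
    lam_star = float(lambdas[best])
    coef = pd.Series(path[best], index=X.columns, name="coef")
    if (coef == 0).all():
        warnings.warn("LASSO selected the all-zero model at lambda*")
    return RiskModel(
        genes=list(X.columns), coef=coef, lambda_=lam_star, lambda_path=lambdas,
        coef_path=pd.DataFrame(path, index=lambdas, columns=X.columns),
        cv_deviance=cv_table, transform=transform, training_samples=list(shared),
        selection=selection, lambda_min=lam_min, lambda_1se=lam_1se,
    )


# ---------------------------------------------------------------------------
# cohort split, risk scoring, evaluation


def split_cohort(survival: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0):
    """Event-stratified random split of the cohort into (development,
    validation) sample-id lists."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    from sklearn.model_selection import train_test_split

    dev, val = train_test_split(
        survival.index.to_numpy(), train_size=train_fraction,
        stratify=survival["event"].to_numpy(), random_state=seed,
    )
    for name, part in (("development", dev), ("validation", val)):
        if survival.loc[part, "event"].sum() == 0:
            raise ValueError(f"{name} part has zero events; cannot evaluate survival")
    return list(dev), list(val)


def risk_score(expr_or_X: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Linear predictor of the fitted model.

    Accepts either a genes x samples FPKM matrix (when the model carries a
    frozen transform) or an already-prepared samples x genes covariate
    matrix.
    """
    if model.transform is not None and all(g in expr_or_X.index for g in model.genes):
        X = model.transform.apply(expr_or_X)
    else:
        X = expr_or_X
    missing = [g for g in model.genes if g not in X.columns]
    if missing:
        raise KeyError(f"covariate(s) missing: {missing}")
    return (X[model.genes] @ model.coef).rename("risk_score")


def km_logrank(survival: pd.DataFrame, strata: pd.Series):
    """Kaplan-Meier curves per stratum plus the log-rank test (lifelines).

    Returns (curves dict stratum -> DataFrame[time, survival], statistic,
    p_value); with a single stratum the test entries are None.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    strata = strata.loc[survival.index.intersection(strata.index)]
    surv = survival.loc[strata.index]
    curves = {}
    for s in pd.unique(strata):
        sub = surv[strata == s]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(s))
        curves[s] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    if len(curves) < 2:
        return curves, None, None
    res = multivariate_logrank_test(surv["time"], strata, surv["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def time_dependent_auc(scores: pd.Series, survival: pd.DataFrame,
                       horizons=(12.0, 36.0)) -> pd.Series:
    """IPCW cumulative/dynamic AUC(t) at each horizon (scikit-survival).

    Horizons with no prior events, or beyond follow-up, are reported as
    NaN rather than raised.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    shared = scores.index.intersection(survival.index)
    surv = survival.loc[shared]
    sc = scores.loc[shared].to_numpy(dtype=float)
    y = Surv.from_arrays(event=surv["event"].astype(bool), time=surv["time"])
    out = {}
    t, e = surv["time"].to_numpy(), surv["event"].to_numpy()
    for h in horizons:
        if not ((t <= h) & (e == 1)).any() or h >= t.max():
            out[h] = float("nan")
            continue
        try:
            auc, _ = cumulative_dynamic_auc(y, y, sc, [h])
            out[h] = float(auc[0])
        except ValueError:
            out[h] = float("nan")
    return pd.Series(out, name="auc").rename_axis("horizon")


def breslow_baseline(time, event, eta):
    """Breslow cumulative baseline hazard H0 of a fitted Cox model.

    Returns (event_times, cumhaz) step-function arrays; evaluate with
    ``numpy.interp``-style searchsorted (H0(t) = cumhaz at the last event
    time <= t).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    eta = np.asarray(eta, dtype=float)
    srt = np.argsort(time, kind="stable")
    t, d, w = time[srt], event[srt], np.exp(eta[srt] - eta.max())
    scale = np.exp(eta.max())
    S0 = np.cumsum(w[::-1])[::-1]
    te = t[d]
    ut, start = np.unique(te, return_index=True)
    dk = np.diff(np.append(start, len(te)))
    first = np.searchsorted(t, ut, side="left")
    increments = dk / (S0[first] * scale)
    return ut, np.cumsum(increments)


def _baseline_at(times, cumhaz, t: float) -> float:
    i = np.searchsorted(times, t, side="right")
    return 0.0 if i == 0 else float(cumhaz[i - 1])


def calibration_at(scores: pd.Series, survival: pd.DataFrame, horizon: float = 36.0,
                   n_bins: int = 3) -> pd.DataFrame:
    """Predicted vs observed survival at ``horizon`` by risk-score quantile bin.

    Predicted: mean of exp(-H0(h) * exp(score)) per bin, with H0 the
    Breslow baseline of the scored cohort. Observed: within-bin
    Kaplan-Meier at the horizon. Tied scores may collapse bins (an
    all-equal score vector yields one bin, predicted = overall KM level);
    a bin left empty is an error.
    """
    from lifelines import KaplanMeierFitter

    shared = scores.index.intersection(survival.index)
    sc = scores.loc[shared]
    surv = survival.loc[shared]
    bt, bh = breslow_baseline(surv["time"], surv["event"], sc.to_numpy())
    h0 = _baseline_at(bt, bh, horizon)
    pred_surv = np.exp(-h0 * np.exp(sc.to_numpy()))
    if sc.nunique() <= 1:
        bins = pd.Series(0, index=sc.index)  # tied scores: one effective bin
    else:
        bins = pd.qcut(sc, q=n_bins, labels=False, duplicates="drop")
    if bins.isna().any():
        raise ValueError("risk-score bin assignment failed (NaN scores?)")
    rows = []
    for b in sorted(bins.unique()):
        members = bins.index[bins == b]
        if len(members) == 0:
            raise ValueError(f"bin {b} is empty")
        kmf = KaplanMeierFitter().fit(surv.loc[members, "time"], surv.loc[members, "event"])
        observed = float(kmf.predict(horizon))
        rows.append({
            "bin": int(b), "n": len(members),
            "predicted": float(pred_surv[bins.to_numpy() == b].mean()),
            "observed": observed,
        })
    return pd.DataFrame(rows).set_index("bin")
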