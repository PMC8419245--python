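"""Cap-thickness progression prediction: GLMM (PQL) and LSSVM under 5-fold CV.

The prediction target is the change in slice minimum cap thickness between
baseline (T1) and follow-up (T2), ΔMinCapT = MinCapT(T2) − MinCapT(T1),
always measured on the gold-standard IO data; a slice is *progressive*
(label +1) when ΔMinCapT < 0 and non-progressive (label −1) otherwise.
Nine baseline predictors are used: LA, PA, PB, MinCapT, MeanCapT, MaxCapS,
MeanCapS, MaxCapSn, MeanCapSn — taken from the IO or the IVUS arm
depending on the experiment.

Two classifiers are implemented:

* a logistic generalized linear mixed model with a per-patient random
  intercept, fitted by penalized quasi-likelihood (iterated working-
  response linearization around a weighted linear mixed model, the inner
  random-intercept LMM being profiled analytically per group);
* a least-squares SVM with Gaussian RBF kernel, trained by solving the
  KKT linear system, with (σ², γ) tuned by multi-start coordinate descent
  on inner-validation misclassification.

Model selection enumerates all non-empty predictor subsets (511 for nine
predictors) and ranks pooled 5-fold cross-validation results by AUC, then
accuracy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold

logger = logging.getLogger(__name__)

PREDICTOR_NAMES = (
    "LA",
    "PA",
    "PB",
    "MinCapT",
    "MeanCapT",
    "MaxCapS",
    "MeanCapS",
    "MaxCapSn",
    "MeanCapSn",
)

MORPHOLOGY_PREDICTORS = ("LA", "PA", "PB", "MinCapT", "MeanCapT")
MECHANICS_PREDICTORS = ("MaxCapS", "MeanCapS", "MaxCapSn", "MeanCapSn")


# ---------------------------------------------------------------------------
# records


def make_records(
    baseline: pd.DataFrame,
    follow_up: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTOR_NAMES,
) -> pd.DataFrame:
    """Assemble per-slice feature records with the progression label.

    ``baseline`` carries the predictors of the chosen arm (IO or IVUS) plus
    an IO baseline MinCapT column ``MinCapT_io``; ``follow_up`` carries the
    IO follow-up MinCapT (``MinCapT_io``).  ΔMinCapT is always computed
    from the IO values (the benchmark), whichever arm supplies the
    predictors.  Unmatched slices are excluded and logged.
    """
    keys = ["patient_id", "slice_id"]
    fu = follow_up.set_index(keys)["MinCapT_io"]
    rows = []
    for _, row in baseline.iterrows():
        key = (row["patient_id"], row["slice_id"])
        if key not in fu.index:
            logger.warning("slice %s has no matched follow-up; excluded", key)
            continue
        if row[list(predictors)].isna().any() or pd.isna(fu.loc[key]):
            logger.warning("slice %s has missing features; excluded", key)
            continue
        delta = float(fu.loc[key]) - float(row["MinCapT_io"])
        rows.append(
            {
                "patient_id": row["patient_id"],
                "slice_id": row["slice_id"],
                **{p: float(row[p]) for p in predictors},
                "delta_mincapt": delta,
                "label": 1 if delta < 0 else -1,
            }
        )
    return pd.DataFrame(rows)


def enumerate_subsets(predictor_names=PREDICTOR_NAMES) -> list[tuple[str, ...]]:
    """All non-empty predictor subsets in deterministic (size, order) order."""
    names = tuple(predictor_names)
    if not (1 <= len(names) <= 20):
        raise ValueError("between 1 and 20 predictor names expected")
    subsets = []
    for r in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(names, r))
    return subsets


# ---------------------------------------------------------------------------
# GLMM via penalized quasi-likelihood


@dataclass
class GlmmFit:
    """Logistic random-intercept GLMM fitted by PQL."""

    predictors: tuple[str, ...]
    beta: np.ndarray  # [intercept, coefficients...] on standardized scale
    intercepts: dict  # patient -> fitted random intercept
    tau2: float  # random-intercept variance
    sigma2: float  # working-residual variance
    x_mean: np.ndarray
    x_sd: np.ndarray
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    ridge: float = 0.0
    beta_se: np.ndarray | None = None  # GLS standard errors, standardized scale


def _profiled_lmm(z, X, w, groups, ridge=0.0):
    """Weighted random-intercept LMM by profiling the variance ratio.

    Scales by sqrt(w) so the residual is homoscedastic, then maximizes the
    profiled Gaussian likelihood over λ = τ²/σ² (each group block inverts
    analytically via Sherman–Morrison).  Returns (β, b per group, τ², σ²).
    """
    sw = np.sqrt(w)
    zs = z * sw
    Xs = X * sw[:, None]
    uniq, gidx = np.unique(groups, return_inverse=True)
    n, p = Xs.shape
    g_rows = [np.where(gidx == g)[0] for g in range(len(uniq))]

    def fit_at(lam):
        A = np.zeros((p, p))
        c = np.zeros(p)
        for rows in g_rows:
            Xg, zg, sg = Xs[rows], zs[rows], sw[rows]
            d = 1.0 + lam * (sg @ sg)
            XV = Xg.T - (lam / d) * np.outer(Xg.T @ sg, sg)
            A += XV @ Xg
            c += XV @ zg
        A += ridge * np.eye(p)
        Ainv = np.linalg.inv(A)
        beta = Ainv @ c
        rss = 0.0
        logdet = 0.0
        for rows in g_rows:
            rg = zs[rows] - Xs[rows] @ beta
            sg = sw[rows]
            d = 1.0 + lam * (sg @ sg)
            rss += rg @ rg - (lam / d) * (sg @ rg) ** 2
            logdet += np.log(d)
        sigma2 = max(rss / n, 1e-12)
        nll = 0.5 * (n * np.log(sigma2) + logdet + n)
        return beta, sigma2, nll, Ainv

    def obj(loglam):
        return fit_at(np.exp(loglam))[2]

    res = minimize_scalar(obj, bounds=(-12.0, 6.0), method="bounded", options={"xatol": 1e-4})
    lam = float(np.exp(res.x))
    # the boundary λ→0 is an ordinary weighted regression (no random effect)
    if obj(-12.0) <= res.fun + 1e-10:
        lam = 0.0
    beta, sigma2, _, Ainv = fit_at(lam if lam > 0 else 0.0)
    b = {}
    for g, rows in enumerate(g_rows):
        rg = zs[rows] - Xs[rows] @ beta
        sg = sw[rows]
        d = 1.0 + lam * (sg @ sg)
        b[uniq[g]] = float(lam * (sg @ rg) / d)
    tau2 = lam * sigma2
    beta_se = np.sqrt(np.clip(np.diag(Ainv) * sigma2, 0, None))
    return beta, b, tau2, sigma2, beta_se


def fit_glmm_pql(
    records: pd.DataFrame,
    subset: tuple[str, ...],
    max_iter: int = 50,
    tol: float = 1e-6,
    pin_tau2_zero: bool = False,
) -> GlmmFit:
    """Penalized quasi-likelihood fit of the logistic random-intercept GLMM.

    Predictors are z-scored (training statistics) before fitting.  On
    non-convergence or separation the fit falls back to a small fixed-effect
    ridge with a warning.  ``pin_tau2_zero`` forces the random-intercept
    variance to zero, reducing the model to ordinary logistic regression.
    """
    if len(records) < 10 or records["patient_id"].nunique() < 2:
        raise ValueError("need >= 10 records from >= 2 patients")
    y01 = (records["label"].to_numpy() == 1).astype(float)
    if y01.min() == y01.max():
        raise ValueError("all labels identical: model is not identifiable (separation)")
    Xraw = records[list(subset)].to_numpy(float)
    x_mean = Xraw.mean(axis=0)
    x_sd = Xraw.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    X = np.column_stack([np.ones(len(Xraw)), (Xraw - x_mean) / x_sd])
    groups = records["patient_id"].to_numpy()

    def run(ridge, damping=1.0):
        eta = logit(np.clip((y01 + 0.5) / 2.0, 0.02, 0.98))
        beta_old = np.zeros(X.shape[1])
        trace = []
        for it in range(max_iter):
            mu = expit(np.clip(eta, -30, 30))
            w = np.clip(mu * (1 - mu), 1e-6, None)
            z = np.clip(eta, -30, 30) + (y01 - mu) / w
            if pin_tau2_zero:
                A = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
                Ainv = np.linalg.inv(A)
                beta = Ainv @ ((X * w[:, None]).T @ z)
                b, tau2, sigma2 = {}, 0.0, 1.0
                beta_se = np.sqrt(np.clip(np.diag(Ainv), 0, None))
            else:
                beta, b, tau2, sigma2, beta_se = _profiled_lmm(z, X, w, groups, ridge)
            eta_new = X @ beta + np.array([b.get(g, 0.0) for g in groups])
            # damping stabilizes PQL under quasi-separation (oscillating η)
            eta = damping * eta_new + (1.0 - damping) * eta
            step = float(np.max(np.abs(beta - beta_old)))
            trace.append(step)
            if np.max(np.abs(beta)) > 1e3:
                raise FloatingPointError("separation: diverging fixed effects")
            if step < tol:
                return beta, b, tau2, sigma2, beta_se, trace, True
            beta_old = beta
        return beta, b, tau2, sigma2, beta_se, trace, False

    # escalate damping and ridge for (quasi-)separated data
    schedule = [(0.0, 1.0), (0.0, 0.5), (1e-3, 0.5), (1e-2, 0.5), (1e-1, 0.3)]
    conv = False
    trace: list = []
    ridge = 0.0
    for i, (ridge, damping) in enumerate(schedule):
        try:
            beta, b, tau2, sigma2, beta_se, trace, conv = run(ridge, damping)
        except (FloatingPointError, np.linalg.LinAlgError):
            conv = False
        if conv:
            if i > 0:
                logger.warning(
                    "PQL needed stabilization (ridge %.0e, damping %.1f)", ridge, damping
                )
            break
    if not conv:
        raise RuntimeError(f"PQL failed to converge (trace tail {trace[-3:]})")
    return GlmmFit(
        predictors=tuple(subset),
        beta=beta,
        intercepts=b,
        tau2=tau2,
        sigma2=sigma2,
        x_mean=x_mean,
        x_sd=x_sd,
        converged=conv,
        n_iter=len(trace),
        trace=trace,
        ridge=ridge,
        beta_se=beta_se,
    )


def predict_glmm(
    fit: GlmmFit, records: pd.DataFrame, population_level: bool = False
) -> np.ndarray:
    """Progression probability per record.

    For patients absent from the training data (or with
    ``population_level=True``) the random-intercept contribution is zero.
    """
    missing = [p for p in fit.predictors if p not in records.columns]
    if missing:
        raise ValueError(f"records lack predictors {missing}")
    X = records[list(fit.predictors)].to_numpy(float)
    Xs = np.column_stack([np.ones(len(X)), (X - fit.x_mean) / fit.x_sd])
    eta = Xs @ fit.beta
    if not population_level:
        eta = eta + np.array([fit.intercepts.get(g, 0.0) for g in records["patient_id"]])
    return expit(np.clip(eta, -30, 30))


# ---------------------------------------------------------------------------
# LSSVM


@dataclass
class LssvmFit:
    predictors: tuple[str, ...]
    alpha: np.ndarray
    bias: float
    sigma2: float
    gamma: float
    X_train: np.ndarray  # standardized training inputs
    y_train: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    kkt_residual: float


def _rbf(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / sigma2)


def fit_lssvm(
    records: pd.DataFrame,
    subset: tuple[str, ...],
    sigma2: float,
    gamma: float,
) -> LssvmFit:
    """Least-squares SVM classifier via its KKT linear system.

    Solves [[0, yᵀ], [y, Ω + I/γ]] (b, α) = (0, 1) with
    Ω_kl = y_k y_l K(x_k, x_l) and Gaussian kernel K; predictors are
    z-scored with training statistics.  A singular system is retried with
    increasing diagonal jitter (warned).
    """
    if sigma2 <= 0 or gamma <= 0:
        raise ValueError("sigma2 and gamma must be positive")
    Xraw = records[list(subset)].to_numpy(float)
    y = records["label"].to_numpy(float)
    x_mean = Xraw.mean(axis=0)
    x_sd = Xraw.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    X = (Xraw - x_mean) / x_sd
    n = len(X)
    K = _rbf(X, X, sigma2)
    omega = (y[:, None] * y[None, :]) * K
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], np.ones(n)])
    jitter = 0.0
    for attempt in range(6):
        try:
            sol = np.linalg.solve(A + np.diag([0.0] + [jitter] * n), rhs)
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0 else jitter * 100
            logger.warning("singular LSSVM system; retrying with jitter %.0e", jitter)
    else:
        raise RuntimeError("LSSVM system remained singular")
    b, alpha = float(sol[0]), sol[1:]
    resid = float(np.linalg.norm(A @ sol - rhs))
    return LssvmFit(tuple(subset), alpha, b, sigma2, gamma, X, y, x_mean, x_sd, resid)


def predict_lssvm(fit: LssvmFit, records: pd.DataFrame) -> np.ndarray:
    """Decision values f(x) = Σ α_k y_k K(x, x_k) + b (sign = class)."""
    X = (records[list(fit.predictors)].to_numpy(float) - fit.x_mean) / fit.x_sd
    K = _rbf(X, fit.X_train, fit.sigma2)
    return K @ (fit.alpha * fit.y_train) + fit.bias


def tune_lssvm(
    records: pd.DataFrame,
    subset: tuple[str, ...],
    seed: int = 0,
    n_inner: int = 3,
    grid_log_sigma2=(-0.5, 0.5, 1.5),
    grid_log_gamma=(-1.0, 0.5, 2.0),
) -> tuple[float, float]:
    """(σ², γ) by multi-start coordinate descent on inner-CV error.

    Starts from a 3×3 log10 grid and descends each coordinate with a
    shrinking step on the inner-validation misclassification rate of the
    training records only; deterministic for a fixed seed.  The returned
    point is never worse than every grid start.
    """
    y = records["label"].to_numpy()
    n_inner = min(n_inner, max(2, min((y == 1).sum(), (y == -1).sum())))
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    cache: dict[tuple[float, float], float] = {}

    def objective(ls, lg):
        key = (round(ls, 6), round(lg, 6))
        if key in cache:
            return cache[key]
        s2, g = 10.0**ls, 10.0**lg
        err = 0.0
        for tr, te in folds:
            fit = fit_lssvm(records.iloc[tr], subset, s2, g)
            pred = np.sign(predict_lssvm(fit, records.iloc[te]))
            pred[pred == 0] = 1
            err += float(np.mean(pred != y[te]))
        cache[key] = err / len(folds)
        return cache[key]

    starts = [(ls, lg) for ls in grid_log_sigma2 for lg in grid_log_gamma]
    best = min(starts, key=lambda p: objective(*p))
    best_val = objective(*best)
    step = 0.5
    point = best
    while step > 0.05:
        improved = False
        for dls, dlg in ((step, 0), (-step, 0), (0, step), (0, -step)):
            cand = (point[0] + dls, point[1] + dlg)
            v = objective(*cand)
            if v < best_val - 1e-12:
                point, best_val = cand, v
                improved = True
                break
        if not improved:
            step *= 0.5
    return 10.0 ** point[0], 10.0 ** point[1]


# ---------------------------------------------------------------------------
# cross-validation and the combination search


def classification_metrics(y: np.ndarray, scores: np.ndarray, threshold: float) -> dict:
    """Pooled Acc/Sen/Spe at a threshold plus rank-based AUC (midrank ties)."""
    y = np.asarray(y)
    scores = np.asarray(scores, float)
    pred = np.where(scores > threshold, 1, -1)
    acc = float(np.mean(pred == y))
    pos = y == 1
    sen = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    spe = float(np.mean(pred[~pos] == -1)) if (~pos).any() else float("nan")
    auc = float(roc_auc_score((y == 1).astype(int), scores))
    return {"Acc": acc, "Sen": sen, "Spe": spe, "AUC": auc}


def make_folds(
    n: int, labels: np.ndarray, k: int, seed: int, scheme: str = "stratified", groups=None
):
    """Fold index pairs; assignment depends only on (seed, n, labels)."""
    if scheme == "stratified":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(n), labels))
    if scheme == "patient":
        gkf = GroupKFold(n_splits=k)
        return list(gkf.split(np.zeros(n), labels, groups))
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(kf.split(np.zeros(n)))
    # a fold without both classes cannot be scored: redraw stratified
    for _, te in folds:
        if len(np.unique(labels[te])) < 2:
            logger.warning("degenerate fold (single class); redrawing stratified folds")
            return make_folds(n, labels, k, seed, "stratified")
    return folds


def crossvalidate(
    records: pd.DataFrame,
    method: str,
    subset: tuple[str, ...],
    k: int = 5,
    seed: int = 0,
    fold_scheme: str = "stratified",
) -> dict:
    """Pooled k-fold CV metrics for one predictor subset and method.

    Each record is tested exactly once; out-of-fold scores are pooled into
    a single ROC.  GLMM scores are probabilities (threshold 0.5) with
    population-level prediction for patients absent from the training
    folds; LSSVM scores are decision values (threshold 0).
    """
    y = records["label"].to_numpy()
    folds = make_folds(len(records), y, k, seed, fold_scheme, records["patient_id"].to_numpy())
    scores = np.full(len(records), np.nan)
    for tr, te in folds:
        train, test = records.iloc[tr], records.iloc[te]
        if method == "glmm":
            fit = fit_glmm_pql(train, subset)
            scores[te] = predict_glmm(fit, test)
        elif method == "lssvm":
            s2, g = tune_lssvm(train, subset, seed=seed)
            fit = fit_lssvm(train, subset, s2, g)
            scores[te] = predict_lssvm(fit, test)
        elif callable(method):
            scores[te] = method(train, test, subset)
        else:
            raise ValueError(f"unknown method {method!r}")
    assert not np.isnan(scores).any(), "each record must be scored exactly once"
    thr = 0.5 if method == "glmm" else 0.0
    name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    row = classification_metrics(y, scores, thr)
    row.update({"method": name, "subset": "+".join(subset), "n": len(records), "k": k})
    row["scores"] = scores
    return row


def run_combination_search(
    records: pd.DataFrame,
    method: str,
    predictors=PREDICTOR_NAMES,
    k: int = 5,
    seed: int = 0,
    fold_scheme: str = "stratified",
    n_repeats: int = 1,
) -> pd.DataFrame:
    """CV metrics for every non-empty predictor subset, ranked by AUC then Acc.

    ``n_repeats`` > 1 averages the metrics over repeated cross-validation
    with distinct fold seeds, reducing the fold-assignment noise of the
    ranking (top subsets often differ by less AUC than one fold draw
    moves).  Subsets whose fit fails are recorded with NaN metrics and the
    error message rather than silently dropped.
    """
    rows = []
    metrics = ("Acc", "Sen", "Spe", "AUC")
    for subset in enumerate_subsets(predictors):
        try:
            reps = []
            for r in range(n_repeats):
                rep = crossvalidate(
                    records, method, subset, k=k, seed=seed + 137 * r, fold_scheme=fold_scheme
                )
                reps.append(rep)
            row = {m: float(np.mean([rp[m] for rp in reps])) for m in metrics}
            row.update(
                {"method": reps[0]["method"], "subset": "+".join(subset),
                 "n": len(records), "k": k, "error": ""}
            )
        except Exception as exc:  # recorded, not dropped
            row = {
                "method": method if isinstance(method, str) else "custom",
                "subset": "+".join(subset),
                **{m: np.nan for m in metrics},
                "n": len(records),
                "k": k,
                "error": str(exc),
            }
            logger.warning("subset %s failed: %s", subset, exc)
        row["n_predictors"] = len(subset)
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["AUC", "Acc"], ascending=False, kind="mergesort").reset_index(drop=True)
    df.index.name = "rank"
    return df
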