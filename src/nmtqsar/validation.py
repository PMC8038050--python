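"""Ordinary-least-squares MLR and the QSAR validation battery.

Fitting statistics (R², R²adj, RMSE, MAE, s, F, Friedman LOF, Lin's CCC,
Todeschini's Kxx/ΔK), internal validation (leave-one-out via the hat-matrix
identity, leave-many-out, Y-scrambling), external validation (Q²F1/F2/F3,
CCCext, Golbraikh–Tropsha origin-regression criteria, r²m), the Williams-plot
applicability domain, and the rule-based model acceptance check.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MLRModel", "ValidationReport", "GTRecord", "ADReport", "LooResult",
    "AcceptanceResult", "fit_ols", "predict", "predict_many",
    "basic_fit_stats", "q2_loo", "q2_lmo", "y_scramble", "external_stats",
    "golbraikh_tropsha", "kxx_delta_k", "williams_ad", "acceptance_check",
    "ccc", "rmse_from_rss", "adjusted_r2", "residual_sd", "f_statistic",
    "friedman_lof", "leverage_cutoff",
]


# ---------------------------------------------------------------------------
# closed-form identities (also used to recompute printed statistic blocks)
# ---------------------------------------------------------------------------

def rmse_from_rss(rss: float, n: int) -> float:
    """RMSE = sqrt(RSS / n); also maps PRESS -> RMSEcv and PRESSext -> RMSEext."""
    return float(np.sqrt(rss / n))


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """R²adj = 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def residual_sd(rss: float, n: int, p: int) -> float:
    """s = sqrt(RSS / (n - p - 1))."""
    return float(np.sqrt(rss / (n - p - 1)))


def f_statistic(r2: float, n: int, p: int) -> float:
    """Fisher ratio F = (R²/p) / ((1 - R²)/(n - p - 1))."""
    return float((r2 / p) / ((1.0 - r2) / (n - p - 1)))


def friedman_lof(rss: float, n: int, p: int, d: float = 0.5) -> float:
    """Friedman's lack-of-fit: (RSS/n) / (1 - (p + 1 + d·p)/n)²."""
    return float((rss / n) / (1.0 - (p + 1 + d * p) / n) ** 2)


def leverage_cutoff(p: int, n_train: int) -> float:
    """Williams-plot warning leverage h* = 3(p + 1)/n."""
    return 3.0 * (p + 1) / n_train


def ccc(a, b) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(), b.var()
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(2.0 * cov / (va + vb + (a.mean() - b.mean()) ** 2))


# ---------------------------------------------------------------------------
# model container and fitting
# ---------------------------------------------------------------------------

@dataclass
class MLRModel:
    """An ordinary-least-squares MLR with named coefficients.

    ``coef_halfwidths`` are the two-sided 95% t-interval half-widths (the
    "(± …)" values of a published model equation). ``sigma``, ``rss``,
    ``y_train_mean`` and ``tss_train`` are retained from fitting so external
    statistics and the applicability domain can be scored later.
    """

    intercept: float
    coefficients: dict[str, float]
    coef_halfwidths: dict[str, float] = field(default_factory=dict)
    training_ids: list[str] = field(default_factory=list)
    n_train: int = 0
    p: int = 0
    sigma: float | None = None
    rss: float | None = None
    y_train_mean: float | None = None
    tss_train: float | None = None

    def __post_init__(self) -> None:
        if self.p == 0:
            self.p = len(self.coefficients)
        if self.p != len(self.coefficients):
            raise ValueError("p does not match the number of coefficients")
        if self.n_train and self.n_train <= self.p + 1:
            raise ValueError("n_train must exceed p + 1")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)


def _design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{i}" for i in range(arr.shape[1])]
    return arr, names


def fit_ols(X, y, names: list[str] | None = None,
            ids: list[str] | None = None) -> MLRModel:
    """Fit y = b0 + Σ bj·xj by ordinary least squares.

    Coefficient half-widths are 95% two-sided t intervals. Raises
    ``numpy.linalg.LinAlgError`` on a rank-deficient design.
    """
    arr, auto_names = _design(X)
    names = names or auto_names
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    Z = sm.add_constant(arr, has_constant="add")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(y, Z).fit()
    ci = res.conf_int(alpha=0.05)
    half = (ci[:, 1] - ci[:, 0]) / 2.0
    return MLRModel(
        intercept=float(res.params[0]),
        coefficients={nm: float(b) for nm, b in zip(names, res.params[1:])},
        coef_halfwidths={nm: float(h) for nm, h in zip(names, half[1:])},
        training_ids=list(ids) if ids is not None else [],
        n_train=n,
        p=p,
        sigma=residual_sd(float(res.ssr), n, p),
        rss=float(res.ssr),
        y_train_mean=float(y.mean()),
        tss_train=float(((y - y.mean()) ** 2).sum()),
    )


def predict(model: MLRModel, x) -> float:
    """Predict pIC50 for one molecule from named descriptor values."""
    missing = [nm for nm in model.coefficients if nm not in x]
    if missing:
        raise KeyError(f"missing descriptor value(s): {missing}")
    return float(model.intercept + sum(b * float(x[nm]) for nm, b in model.coefficients.items()))


def predict_many(model: MLRModel, X) -> np.ndarray:
    """Predict for a matrix; a DataFrame is aligned to the model's descriptors."""
    if isinstance(X, pd.DataFrame):
        arr = X[model.descriptor_names].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    beta = np.array([model.coefficients[nm] for nm in model.descriptor_names])
    return model.intercept + arr @ beta


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

@dataclass
class GTRecord:
    """Golbraikh–Tropsha origin-regression quantities on observed vs predicted."""

    k: float
    k_prime: float
    ro2: float
    r_prime_o2: float
    r2m: float
    r_prime_2m: float
    r2: float


@dataclass
class ValidationReport:
    """Every statistic of a published model block; fields fill in stages."""

    # fitting
    r2tr: float | None = None
    r2adj: float | None = None
    lof: float | None = None
    kxx: float | None = None
    delta_k: float | None = None
    rmse_tr: float | None = None
    mae_tr: float | None = None
    rss_tr: float | None = None
    ccc_tr: float | None = None
    s: float | None = None
    f_stat: float | None = None
    # cross-validation
    q2_loo: float | None = None
    rmse_cv: float | None = None
    mae_cv: float | None = None
    press_cv: float | None = None
    ccc_cv: float | None = None
    q2_lmo: float | None = None
    # scrambling
    r2_yscr: float | None = None
    q2_yscr: float | None = None
    # external
    rmse_ex: float | None = None
    mae_ex: float | None = None
    press_ext: float | None = None
    r2_ex: float | None = None
    q2_f1: float | None = None
    q2_f2: float | None = None
    q2_f3: float | None = None
    ccc_ex: float | None = None
    gt: GTRecord | None = None

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "gt"}
        if self.gt is not None:
            d["gt"] = {f.name: getattr(self.gt, f.name) for f in fields(GTRecord)}
        return d

    def merge(self, other: "ValidationReport") -> "ValidationReport":
        for f in fields(self):
            v = getattr(other, f.name)
            if v is not None:
                setattr(self, f.name, v)
        return self


@dataclass
class LooResult:
    q2: float
    press: float
    rmse_cv: float
    mae_cv: float
    ccc_cv: float
    y_loo: np.ndarray


@dataclass
class ADReport:
    """Williams-plot data: leverages and standardized residuals."""

    ids: list[str]
    leverages: np.ndarray
    std_residuals: np.ndarray
    sets: list[str]               # "train" / "ext" per molecule
    h_star: float
    outliers: list[str]           # |standardized residual| > 3
    influential: list[str]        # leverage > h*


# ---------------------------------------------------------------------------
# fitting statistics
# ---------------------------------------------------------------------------

def basic_fit_stats(model: MLRModel, X, y, lof_d: float = 0.5) -> ValidationReport:
    """Training-set statistics of a fitted model."""
    y = np.asarray(y, dtype=float)
    yhat = predict_many(model, X)
    n, p = len(y), model.p
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    resid = y - yhat
    rss = float((resid**2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    return ValidationReport(
        r2tr=r2,
        r2adj=adjusted_r2(r2, n, p),
        lof=friedman_lof(rss, n, p, lof_d),
        rmse_tr=rmse_from_rss(rss, n),
        mae_tr=float(np.abs(resid).mean()),
        rss_tr=rss,
        ccc_tr=ccc(y, yhat),
        s=residual_sd(rss, n, p),
        f_stat=f_statistic(r2, n, p),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _ols_core(Z: np.ndarray, y: np.ndarray):
    """Return (beta, residuals, hat diagonal) or None if the design is singular."""
    G = Z.T @ Z
    try:
        np.linalg.cholesky(G)  # cheap positive-definiteness gate
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(Ginv).all():
        return None
    beta = Ginv @ (Z.T @ y)
    resid = y - Z @ beta
    h = np.einsum("ij,jk,ik->i", Z, Ginv, Z)
    return beta, resid, h


def loo_predictions(X, y) -> np.ndarray:
    """Leave-one-out predictions via the hat-matrix identity.

    e_(i) = e_i / (1 - h_i); points with leverage ~1 fall back to an explicit
    refit without that point.
    """
    arr, _ = _design(X)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(len(y)), arr])
    core = _ols_core(Z, y)
    if core is None:
        raise np.linalg.LinAlgError("singular design in LOO")
    _, resid, h = core
    y_loo = np.empty_like(y)
    for i in range(len(y)):
        if h[i] < 1.0 - 1e-10:
            y_loo[i] = y[i] - resid[i] / (1.0 - h[i])
        else:  # exact-interpolation point: refit explicitly
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            beta_i = np.linalg.lstsq(Z[mask], y[mask], rcond=None)[0]
            y_loo[i] = Z[i] @ beta_i
    return y_loo


def q2_loo(X, y, subset: list | None = None) -> LooResult:
    """Leave-one-out Q² = 1 - PRESS/TSS with RMSEcv, MAEcv and CCCcv."""
    if subset is not None:
        X = X[subset] if isinstance(X, pd.DataFrame) else np.asarray(X)[:, subset]
    y = np.asarray(y, dtype=float)
    y_loo = loo_predictions(X, y)
    press = float(((y - y_loo) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return LooResult(
        q2=1.0 - press / tss,
        press=press,
        rmse_cv=rmse_from_rss(press, len(y)),
        mae_cv=float(np.abs(y - y_loo).mean()),
        ccc_cv=ccc(y, y_loo),
        y_loo=y_loo,
    )


def q2_lmo(X, y, subset: list | None = None, frac_out: float = 0.30,
           reps: int = 2000, seed: int = 0) -> float:
    """Leave-many-out Q²: mean over random repetitions with frac_out held out.

    Each repetition refits on the retained objects and scores
    1 - Σ(y_out - ŷ_out)² / Σ(y_out - ȳ_train)² on the held-out block.
    """
    if not 0.0 < frac_out < 1.0:
        raise ValueError("frac_out must lie strictly between 0 and 1")
    arr, _ = _design(X)
    if subset is not None:
        arr = arr[:, [X.columns.get_loc(s) for s in subset]] if isinstance(X, pd.DataFrame) \
            else arr[:, subset]
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    n_out = max(1, int(round(frac_out * n)))
    if n - n_out <= p + 1:
        raise ValueError("training remainder too small for the model size")
    rng = np.random.default_rng(seed)
    Z = np.column_stack([np.ones(n), arr])
    vals = []
    for _ in range(reps):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        core = _ols_core(Z[mask], y[mask])
        if core is None:
            log.warning("q2_lmo: degenerate subsample skipped")
            continue
        beta = core[0]
        pred = Z[out] @ beta
        denom = float(((y[out] - y[mask].mean()) ** 2).sum())
        if denom == 0.0:
            log.warning("q2_lmo: zero-variance held-out block skipped")
            continue
        vals.append(1.0 - float(((y[out] - pred) ** 2).sum()) / denom)
    if not vals:
        raise ValueError("all leave-many-out repetitions were degenerate")
    return float(np.mean(vals))


def y_scramble(X, y, subset: list | None = None, reps: int = 2000,
               seed: int = 0) -> tuple[float, float]:
    """Refit after random permutations of y; returns (mean R²scr, mean Q²scr)."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    arr, _ = _design(X)
    if subset is not None:
        arr = arr[:, [X.columns.get_loc(s) for s in subset]] if isinstance(X, pd.DataFrame) \
            else arr[:, subset]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    Z = np.column_stack([np.ones(len(y)), arr])
    r2s, q2s = [], []
    for _ in range(reps):
        ys = rng.permutation(y)
        core = _ols_core(Z, ys)
        if core is None:
            continue
        _, resid, h = core
        tss = float(((ys - ys.mean()) ** 2).sum())
        r2s.append(1.0 - float((resid**2).sum()) / tss)
        press = float(((resid / (1.0 - h)) ** 2).sum())
        q2s.append(1.0 - press / tss)
    return float(np.mean(r2s)), float(np.mean(q2s))


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

def external_stats(model: MLRModel, X_ext, y_ext,
                   y_train_mean: float | None = None,
                   tss_train_per_n: float | None = None) -> ValidationReport:
    """External-set statistics: RMSEext, MAEext, R²ext, Q²F1/F2/F3, CCCext.

    Q²F1 centres the reference variance on the training mean, Q²F2 on the
    external mean, and Q²F3 scales PRESS/n_ext by the training TSS/n_train.
    """
    y_ext = np.asarray(y_ext, dtype=float)
    if len(y_ext) == 0:
        raise ValueError("empty external set")
    if y_train_mean is None:
        y_train_mean = model.y_train_mean
    if tss_train_per_n is None:
        if model.tss_train is None or not model.n_train:
            raise ValueError("training TSS/n unavailable; pass tss_train_per_n")
        tss_train_per_n = model.tss_train / model.n_train
    yhat = predict_many(model, X_ext)
    press = float(((y_ext - yhat) ** 2).sum())
    n_ext = len(y_ext)
    r = np.corrcoef(y_ext, yhat)[0, 1]
    return ValidationReport(
        rmse_ex=rmse_from_rss(press, n_ext),
        mae_ex=float(np.abs(y_ext - yhat).mean()),
        press_ext=press,
        r2_ex=float(r**2),
        q2_f1=1.0 - press / float(((y_ext - y_train_mean) ** 2).sum()),
        q2_f2=1.0 - press / float(((y_ext - y_ext.mean()) ** 2).sum()),
        q2_f3=1.0 - (press / n_ext) / tss_train_per_n,
        ccc_ex=ccc(y_ext, yhat),
    )


def _origin_fit(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Slope of a ~ k·b through the origin and the corresponding Ro² of a."""
    k = float((a * b).sum() / (b * b).sum())
    ro2 = 1.0 - float(((a - k * b) ** 2).sum()) / float(((a - a.mean()) ** 2).sum())
    return k, ro2


def golbraikh_tropsha(y_obs, y_pred) -> GTRecord:
    """Origin-regression external criteria: k, k', Ro², R'o², r²m, r'²m."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) < 3:
        raise ValueError("need at least 3 points")
    if y_obs.var() == 0 or y_pred.var() == 0:
        raise ValueError("zero-variance inputs")
    r2 = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    k, ro2 = _origin_fit(y_obs, y_pred)        # observed vs predicted
    k_prime, r_prime_o2 = _origin_fit(y_pred, y_obs)  # predicted vs observed
    r2m = r2 * (1.0 - np.sqrt(abs(r2 - ro2)))
    r_prime_2m = r2 * (1.0 - np.sqrt(abs(r2 - r_prime_o2)))
    return GTRecord(k=k, k_prime=k_prime, ro2=ro2, r_prime_o2=r_prime_o2,
                    r2m=float(r2m), r_prime_2m=float(r_prime_2m), r2=r2)


def _k_index(corr: np.ndarray) -> float:
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    p = len(lam)
    frac = lam / lam.sum()
    return float(np.abs(frac - 1.0 / p).sum() / (2.0 * (p - 1) / p))


def kxx_delta_k(X, y) -> tuple[float, float]:
    """Todeschini's multivariate K correlation of the descriptor block.

    Kxx is computed from the eigenvalues of the descriptor correlation
    matrix; ΔK = Kxy - Kxx where Kxy appends the response. Kxx is 0 for
    mutually orthogonal descriptors and 1 in the rank-one limit.
    """
    arr, _ = _design(X)
    y = np.asarray(y, dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 descriptors")
    if np.any(arr.std(axis=0) == 0):
        raise ValueError("constant descriptor column")
    kxx = _k_index(np.corrcoef(arr, rowvar=False))
    kxy = _k_index(np.corrcoef(np.column_stack([arr, y]), rowvar=False))
    return kxx, kxy - kxx


# ---------------------------------------------------------------------------
# applicability domain
# ---------------------------------------------------------------------------

def williams_ad(model: MLRModel, X_train, y_train, X_ext=None, y_ext=None,
                ids_train: list[str] | None = None,
                ids_ext: list[str] | None = None) -> ADReport:
    """Williams-plot data: leverages against the training design, h* cutoff.

    External points are scored with the training (ZᵀZ)⁻¹; standardized
    residuals divide by the training residual SD s. The training leverages
    sum to p + 1 (projection-trace identity).
    """
    arr, _ = _design(X_train if not isinstance(X_train, pd.DataFrame)
                     else X_train[model.descriptor_names])
    y_train = np.asarray(y_train, dtype=float)
    Z = np.column_stack([np.ones(len(arr)), arr])
    try:
        Ginv = np.linalg.inv(Z.T @ Z)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular training design") from e
    h_tr = np.einsum("ij,jk,ik->i", Z, Ginv, Z)
    resid_tr = y_train - predict_many(model, X_train)
    s = model.sigma if model.sigma is not None else residual_sd(
        float((resid_tr**2).sum()), len(y_train), model.p)
    lev = [h_tr]
    std = [resid_tr / s]
    sets = ["train"] * len(y_train)
    ids = list(ids_train) if ids_train is not None else [f"train{i}" for i in range(len(y_train))]
    if X_ext is not None:
        arr_e, _ = _design(X_ext if not isinstance(X_ext, pd.DataFrame)
                           else X_ext[model.descriptor_names])
        Ze = np.column_stack([np.ones(len(arr_e)), arr_e])
        lev.append(np.einsum("ij,jk,ik->i", Ze, Ginv, Ze))
        resid_e = (np.asarray(y_ext, dtype=float) - predict_many(model, X_ext)
                   if y_ext is not None else np.zeros(len(arr_e)))
        std.append(resid_e / s)
        sets += ["ext"] * len(arr_e)
        ids += list(ids_ext) if ids_ext is not None else [f"ext{i}" for i in range(len(arr_e))]
    leverages = np.concatenate(lev)
    std_res = np.concatenate(std)
    h_star = leverage_cutoff(model.p, len(y_train))
    return ADReport(
        ids=ids,
        leverages=leverages,
        std_residuals=std_res,
        sets=sets,
        h_star=h_star,
        outliers=[i for i, r in zip(ids, std_res) if abs(r) > 3.0],
        influential=[i for i, h in zip(ids, leverages) if h > h_star],
    )


# ---------------------------------------------------------------------------
# acceptance rules
# ---------------------------------------------------------------------------

@dataclass
class AcceptanceResult:
    passed: bool
    rules: dict[str, dict]  # rule -> {"passed": bool, "value": ..., "detail": str}

    def failing(self) -> list[str]:
        return [r for r, d in self.rules.items() if not d["passed"]]


_RULE_FIELDS = [
    "r2tr", "q2_loo", "q2_lmo", "r2_ex", "rmse_tr", "rmse_cv", "delta_k",
    "ccc_ex", "q2_f1", "q2_f2", "q2_f3", "gt",
]


def acceptance_check(report: ValidationReport) -> AcceptanceResult:
    """Evaluate the model-selection rule set on a complete report.

    Rules: R²tr ≥ 0.6, Q²loo ≥ 0.5, Q²LMO ≥ 0.6, R² > Q², R²ex ≥ 0.6,
    RMSEtr < RMSEcv, ΔK ≥ 0.05, CCCex ≥ 0.80, Q²F1/F2/F3 ≥ 0.60,
    r²m and r'²m ≥ 0.5, an origin-regression branch
    ((1 - r²/Ro²) < 0.1 with 0.9 ≤ k ≤ 1.1, or the primed variant), and
    |Ro² - R'o²| < 0.3. Overall pass iff every rule passes.
    """
    missing = [f for f in _RULE_FIELDS if getattr(report, f) is None]
    if missing:
        raise ValueError(f"incomplete report; missing fields: {missing}")
    gt = report.gt
    rules: dict[str, dict] = {}

    def rule(name: str, passed: bool, value) -> None:
        rules[name] = {"passed": bool(passed), "value": value}

    rule("R2tr >= 0.6", report.r2tr >= 0.6, report.r2tr)
    rule("Q2loo >= 0.5", report.q2_loo >= 0.5, report.q2_loo)
    rule("Q2LMO >= 0.6", report.q2_lmo >= 0.6, report.q2_lmo)
    rule("R2 > Q2", report.r2tr > report.q2_loo, (report.r2tr, report.q2_loo))
    rule("R2ex >= 0.6", report.r2_ex >= 0.6, report.r2_ex)
    rule("RMSEtr < RMSEcv", report.rmse_tr < report.rmse_cv,
         (report.rmse_tr, report.rmse_cv))
    rule("deltaK >= 0.05", report.delta_k >= 0.05, report.delta_k)
    rule("CCCex >= 0.80", report.ccc_ex >= 0.80, report.ccc_ex)
    rule("Q2F1 >= 0.60", report.q2_f1 >= 0.60, report.q2_f1)
    rule("Q2F2 >= 0.60", report.q2_f2 >= 0.60, report.q2_f2)
    rule("Q2F3 >= 0.60", report.q2_f3 >= 0.60, report.q2_f3)
    rule("r2m >= 0.5", gt.r2m >= 0.5, gt.r2m)
    rule("r2m' >= 0.5", gt.r_prime_2m >= 0.5, gt.r_prime_2m)
    branch_plain = (1.0 - gt.r2 / gt.ro2) < 0.1 and 0.9 <= gt.k <= 1.1
    branch_prime = (1.0 - gt.r2 / gt.r_prime_o2) < 0.1 and 0.9 <= gt.k_prime <= 1.1
    rule("origin-regression branch", branch_plain or branch_prime,
         {"k": gt.k, "k'": gt.k_prime, "Ro2": gt.ro2, "R'o2": gt.r_prime_o2})
    rule("|Ro2 - R'o2| < 0.3", abs(gt.ro2 - gt.r_prime_o2) < 0.3,
         abs(gt.ro2 - gt.r_prime_o2))
    return AcceptanceResult(passed=all(d["passed"] for d in rules.values()), rules=rules)
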