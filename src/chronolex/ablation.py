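"""Decade-ablation model comparison for similarity and rating targets.

Two model families quantify how much each decade's corpus similarities
contribute to predicting behavior.  For association-based similarity
targets, an ordinary least-squares model regresses a cohort's RSM cells on
the ten decade RSMs' cells, and each decade is ablated in turn; impact is
measured by cross-validated differences in AIC, log-likelihood and R^2
plus a nested F-test on the full data.  For 0-6 relatedness ratings, a
cumulative-logit proportional-odds model plays the same role, with decade
impact measured by the k-fold expected log predictive density (ELPD)
difference between ablated and full models; an |ELPD difference| below 4
is flagged negligible, the conventional rule of thumb.

Fits are maximum likelihood throughout (statsmodels OLS / OrderedModel);
random-effect structures one would use on real repeated-measures data are
out of scope and approximated, when needed, by fixed subject offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "LinearFit",
    "OrdinalFit",
    "AblationResult",
    "fit_linear",
    "f_test_nested",
    "ablate_linear",
    "fit_ordinal",
    "ablate_ordinal",
    "fit_factorial_ordinal",
    "factorial_design",
]

_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Linear (Gaussian) family
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """OLS fit with Gaussian maximum-likelihood summaries.

    ``aic = 2 (k + 2) - 2 loglik`` where k is the number of slope
    predictors; the parameter count includes the intercept and the
    residual scale.
    """

    coefficients: pd.Series  # "const" then predictor names
    sigma: float
    loglik: float
    aic: float
    r_squared: float
    n: int
    rss: float
    columns: tuple[str, ...]

    @property
    def k_slopes(self) -> int:
        return len(self.columns)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = sm.add_constant(X[list(self.columns)], has_constant="add")
        return design.to_numpy() @ self.coefficients.to_numpy()


def _as_frame(X, prefix: str = "x") -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])


def fit_linear(y, X) -> LinearFit:
    """Ordinary least squares with intercept.

    Raises on rank-deficient designs, naming the offending columns.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        _, r, piv = _qr_pivot(design.to_numpy())
        bad = sorted(design.columns[piv[rank:]])
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    aic = 2.0 * (k + 2) - 2.0 * loglik
    return LinearFit(
        coefficients=res.params,
        sigma=float(np.sqrt(sigma2)),
        loglik=float(loglik),
        aic=float(aic),
        r_squared=float(res.rsquared),
        n=n,
        rss=rss,
        columns=tuple(X.columns),
    )


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    return qr(a, pivoting=True, mode="economic")


def f_test_nested(full: LinearFit, reduced: LinearFit,
                  n: int | None = None, df_diff: int | None = None) -> tuple[float, float]:
    """Extra-sum-of-squares F-test of a reduced model nested in a full one."""
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("reduced model is not nested in the full model")
    if reduced.n != full.n:
        raise ValueError("fits use different numbers of observations")
    n = full.n if n is None else n
    df_diff = full.k_slopes - reduced.k_slopes if df_diff is None else df_diff
    if df_diff <= 0:
        raise ValueError("full model must have more predictors than the reduced one")
    df_resid = n - full.k_slopes - 1
    num = max(reduced.rss - full.rss, 0.0) / df_diff
    den = full.rss / df_resid
    f_stat = num / den
    p = float(stats.f.sf(f_stat, df_diff, df_resid))
    return float(f_stat), p


@dataclass
class AblationResult:
    """Impact of ablating one predictor, averaged over CV folds.

    Gaussian family: delta_* are full-minus-ablated on held-out folds
    (delta_aic is ablated-minus-full, so positive always means the ablated
    model is worse).  Ordinal family: elpd_diff is ablated-minus-full
    summed held-out log predictive density (negative = ablated worse),
    with fold-wise (default) and pointwise standard errors and the
    |elpd_diff| < 4 negligibility flag.
    """

    ablated: str
    delta_aic: float = 0.0
    delta_loglik: float = 0.0
    delta_r2: float = 0.0
    fold_deltas: pd.DataFrame | None = field(default=None, repr=False)
    f_stat: float | None = None
    p_value: float | None = None
    elpd_diff: float | None = None
    elpd_se: float | None = None
    elpd_se_pointwise: float | None = None
    negligible: bool | None = None


def _heldout_gaussian_metrics(fit: LinearFit, X_test: pd.DataFrame, y_test: np.ndarray):
    mu = fit.predict(X_test)
    ll = float(np.sum(stats.norm.logpdf(y_test, loc=mu, scale=fit.sigma)))
    ss_res = float(np.sum((y_test - mu) ** 2))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    aic = 2.0 * (fit.k_slopes + 2) - 2.0 * ll
    return ll, r2, aic


def ablate_linear(y, X, folds: int = 5, seed: int = 0) -> list[AblationResult]:
    """Ablate each decade column in turn; evaluate deltas out of sample.

    For every fold, the full and each single-column-ablated model are fit
    on the training portion and scored (log-likelihood, R^2, AIC) on the
    held-out portion; the reported deltas average over folds.  The nested
    F-test comparing full and ablated models is run once on all the data.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    fold_metrics: dict[str, list[tuple[float, float, float]]] = {
        col: [] for col in ["__full__", *X.columns]
    }
    for train, test in splits:
        X_tr, X_te = X.iloc[train], X.iloc[test]
        y_tr, y_te = y[train], y[test]
        full = fit_linear(y_tr, X_tr)
        fold_metrics["__full__"].append(_heldout_gaussian_metrics(full, X_te, y_te))
        for col in X.columns:
            abl = fit_linear(y_tr, X_tr.drop(columns=[col]))
            fold_metrics[col].append(_heldout_gaussian_metrics(abl, X_te, y_te))

    full_fit = fit_linear(y, X)
    full_metrics = np.array(fold_metrics["__full__"])  # (folds, 3): ll, r2, aic

    results = [AblationResult(ablated="none", f_stat=0.0, p_value=1.0)]
    for col in X.columns:
        abl_metrics = np.array(fold_metrics[col])
        d_ll = full_metrics[:, 0] - abl_metrics[:, 0]
        d_r2 = full_metrics[:, 1] - abl_metrics[:, 1]
        d_aic = abl_metrics[:, 2] - full_metrics[:, 2]
        reduced_fit = fit_linear(y, X.drop(columns=[col]))
        f_stat, p = f_test_nested(full_fit, reduced_fit)
        results.append(
            AblationResult(
                ablated=str(col),
                delta_aic=float(d_aic.mean()),
                delta_loglik=float(d_ll.mean()),
                delta_r2=float(d_r2.mean()),
                fold_deltas=pd.DataFrame(
                    {"delta_loglik": d_ll, "delta_r2": d_r2, "delta_aic": d_aic}
                ),
                f_stat=f_stat,
                p_value=p,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Ordinal (proportional-odds) family
# ---------------------------------------------------------------------------

@dataclass
class OrdinalFit:
    """Maximum-likelihood cumulative-logit proportional-odds fit.

    ``thresholds`` are the strictly increasing cutpoints separating the
    observed response levels on the latent logistic scale (6 cutpoints for
    a fully observed 0-6 scale); ``betas`` shift the latent mean.
    """

    thresholds: np.ndarray
    betas: pd.Series
    loglik: float
    n: int
    converged: bool
    levels: tuple[int, ...]
    cov_betas: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def latent_mean(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.betas.index)
        return np.asarray(X[cols], dtype=float) @ self.betas.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Category probabilities, one column per observed level."""
        xb = self.latent_mean(X)
        cuts = np.concatenate([[-np.inf], self.thresholds, [np.inf]])
        cdf = stats.logistic.cdf(cuts[None, :] - xb[:, None])
        return np.diff(cdf, axis=1)

    def log_predictive(self, y, X: pd.DataFrame) -> np.ndarray:
        """Pointwise log predictive density of observed ratings.

        Ratings at levels unseen during training are mapped to the nearest
        trained level before scoring.
        """
        probs = self.predict_proba(X)
        levels = np.asarray(self.levels)
        y = np.asarray(y)
        idx = np.abs(y[:, None] - levels[None, :]).argmin(axis=1)
        p = probs[np.arange(len(y)), idx]
        return np.log(np.maximum(p, _LOG_FLOOR))


def fit_ordinal(ratings, X, maxiter: int = 500, gtol: float = 1e-8) -> OrdinalFit:
    """Fit a proportional-odds model to ordinal ratings.

    Three or more observed levels use the cumulative-logit likelihood with
    monotone thresholds enforced by log-difference reparameterization;
    exactly two observed levels reduce to plain logistic regression (one
    cutpoint).  Non-convergence (e.g. complete separation) is flagged, not
    raised — partial estimates are returned.
    """
    X = _as_frame(X, prefix="sim")
    y = np.asarray(ratings)
    levels = tuple(int(v) for v in np.unique(y))
    if len(levels) < 2:
        raise ValueError("all responses identical: need >= 2 distinct levels")
    if len(X) != len(y):
        raise ValueError("ratings and predictors differ in length")

    if len(levels) == 2:
        # cumulative logit with a single cutpoint == logistic regression on
        # the upper level, with threshold = -intercept
        binary = (y == levels[1]).astype(int)
        design = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(binary, design).fit(disp=False, maxiter=maxiter)
        betas = res.params.drop("const")
        cov = res.cov_params().loc[betas.index, betas.index]
        return OrdinalFit(
            thresholds=np.array([-res.params["const"]]),
            betas=betas,
            loglik=float(res.llf),
            n=len(y),
            converged=bool(res.mle_retvals["converged"]),
            levels=levels,
            cov_betas=cov,
        )

    endog = pd.Series(
        pd.Categorical(y, categories=list(levels), ordered=True), index=X.index
    )
    model = OrderedModel(endog, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=maxiter, gtol=gtol, disp=False)
    k = X.shape[1]
    betas = pd.Series(np.asarray(res.params[:k]), index=list(X.columns))
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    cov_all = np.asarray(res.cov_params())
    cov = pd.DataFrame(cov_all[:k, :k], index=betas.index, columns=betas.index)
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    if not converged:
        warnings.warn("ordinal fit did not converge; partial estimates returned")
    return OrdinalFit(
        thresholds=np.asarray(thresholds, dtype=float),
        betas=betas,
        loglik=float(res.llf),
        n=len(y),
        converged=converged,
        levels=levels,
        cov_betas=cov,
    )


def ablate_ordinal(ratings, X, folds: int = 5, seed: int = 0) -> list[AblationResult]:
    """ELPD-based ablation of each predictor of an ordinal rating model.

    Folds are stratified by response level.  For each fold the full and
    ablated models are fit on the training portion; ``elpd_diff`` sums the
    held-out log predictive density of the ablated model minus the full
    model over all folds (negative = ablating hurts).  The default
    standard error treats fold sums as replicates; a pointwise estimate in
    the PSIS-LOO style is also reported.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = _as_frame(X, prefix="sim")
    y = np.asarray(ratings)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    point_diffs: dict[str, list[np.ndarray]] = {col: [] for col in X.columns}
    for train, test in splits:
        X_tr, X_te = X.iloc[train], X.iloc[test]
        y_tr, y_te = y[train], y[test]
        full = fit_ordinal(y_tr, X_tr)
        lp_full = full.log_predictive(y_te, X_te)
        for col in X.columns:
            abl = fit_ordinal(y_tr, X_tr.drop(columns=[col]))
            point_diffs[col].append(abl.log_predictive(y_te, X_te.drop(columns=[col])) - lp_full)

    results = [AblationResult(ablated="none", elpd_diff=0.0, elpd_se=0.0,
                              elpd_se_pointwise=0.0, negligible=True)]
    for col in X.columns:
        per_fold = np.array([d.sum() for d in point_diffs[col]])
        pointwise = np.concatenate(point_diffs[col])
        elpd_diff = float(per_fold.sum())
        se_fold = float(np.sqrt(folds * np.var(per_fold, ddof=1)))
        se_point = float(np.sqrt(len(pointwise) * np.var(pointwise, ddof=1)))
        results.append(
            AblationResult(
                ablated=str(col),
                elpd_diff=elpd_diff,
                elpd_se=se_fold,
                elpd_se_pointwise=se_point,
                negligible=bool(abs(elpd_diff) < 4.0),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Factorial rating model (age x pair type x meaning change)
# ---------------------------------------------------------------------------

_PAIR_LEVELS = ("non_neighbor", "n1950", "n1990")


def factorial_design(
    df: pd.DataFrame,
    age_col: str = "cohort",
    pair_col: str = "pair_type",
    change_col: str = "change_status",
) -> pd.DataFrame:
    """Design matrix for the age x pair-type x change factorial.

    Age (OA vs YA) and meaning change (changed vs unchanged) are effect
    coded at +/- 0.5 (so a main-effect coefficient is the between-level
    difference); pair type is dummy coded against the non-neighbor
    reference.  YA / unchanged / non-neighbor form the reference cell.
    """
    age = df[age_col].map({"OA": 0.5, "YA": -0.5})
    change = df[change_col].map({"changed": 0.5, "unchanged": -0.5})
    if age.isna().any():
        raise ValueError("cohort column must contain only 'YA' / 'OA'")
    if change.isna().any():
        raise ValueError("change column must contain only 'changed' / 'unchanged'")
    if not df[pair_col].isin(_PAIR_LEVELS).all():
        raise ValueError(f"pair type must be one of {_PAIR_LEVELS}")
    d1950 = (df[pair_col] == "n1950").astype(float)
    d1990 = (df[pair_col] == "n1990").astype(float)
    out = pd.DataFrame(
        {
            "age": age.to_numpy(dtype=float),
            "pair_1950": d1950.to_numpy(),
            "pair_1990": d1990.to_numpy(),
            "change": change.to_numpy(dtype=float),
        },
        index=df.index,
    )
    out["age:pair_1950"] = out["age"] * out["pair_1950"]
    out["age:pair_1990"] = out["age"] * out["pair_1990"]
    out["age:change"] = out["age"] * out["change"]
    out["pair_1950:change"] = out["pair_1950"] * out["change"]
    out["pair_1990:change"] = out["pair_1990"] * out["change"]
    out["age:pair_1950:change"] = out["age"] * out["pair_1950"] * out["change"]
    out["age:pair_1990:change"] = out["age"] * out["pair_1990"] * out["change"]
    return out


def cell_design_row(age: str, pair_type: str, change: str) -> pd.Series:
    """Design row for one factorial cell (same coding as factorial_design)."""
    df = pd.DataFrame(
        {"cohort": [age], "pair_type": [pair_type], "change_status": [change]}
    )
    return factorial_design(df).iloc[0]


def fit_factorial_ordinal(
    df: pd.DataFrame,
    rating_col: str = "rating",
    age_col: str = "cohort",
    pair_col: str = "pair_type",
    change_col: str = "change_status",
) -> tuple[OrdinalFit, pd.DataFrame]:
    """Factorial proportional-odds model of ratings plus a contrast table.

    The contrast table reports latent-scale marginal means per
    (change, pair type) cell averaged over age groups, the pairwise
    1950s-vs-1990s and neighbor-vs-non-neighbor differences, and the
    between-age difference of the 1950s-1990s gap (the key test of whether
    older adults weight historical meanings differently), all with Wald
    standard errors and 95% intervals.
    """
    cells = df.groupby([age_col, pair_col, change_col]).size()
    expected = [
        (a, p, c)
        for a in ("YA", "OA")
        for p in _PAIR_LEVELS
        for c in ("changed", "unchanged")
    ]
    missing = [cell for cell in expected if cell not in cells.index]
    if missing:
        raise ValueError(f"missing factorial cells: {missing}")

    X = factorial_design(df, age_col, pair_col, change_col)
    fit = fit_ordinal(df[rating_col], X)
    cov = fit.cov_betas

    def _contrast(vec: pd.Series) -> tuple[float, float]:
        c = vec.reindex(fit.betas.index).to_numpy(dtype=float)
        est = float(c @ fit.betas.to_numpy())
        se = float(np.sqrt(c @ cov.to_numpy() @ c))
        return est, se

    rows = []
    cell_mean: dict[tuple[str, str], pd.Series] = {}
    for change in ("changed", "unchanged"):
        for pair in _PAIR_LEVELS:
            # average over age groups = age coding set to 0
            avg = (
                cell_design_row("YA", pair, change) + cell_design_row("OA", pair, change)
            ) / 2.0
            cell_mean[(change, pair)] = avg
            est, se = _contrast(avg)
            rows.append(("emm", change, pair, est, se))
        for name, a, b in (
            ("1950s - 1990s", "n1950", "n1990"),
            ("1950s - non-neighbor", "n1950", "non_neighbor"),
            ("1990s - non-neighbor", "n1990", "non_neighbor"),
        ):
            diff = cell_mean[(change, a)] - cell_mean[(change, b)]
            est, se = _contrast(diff)
            rows.append(("contrast", change, name, est, se))
        gap = (
            (cell_design_row("OA", "n1950", change) - cell_design_row("OA", "n1990", change))
            - (cell_design_row("YA", "n1950", change) - cell_design_row("YA", "n1990", change))
        )
        est, se = _contrast(gap)
        rows.append(("contrast", change, "(1950s - 1990s): OA - YA", est, se))

    table = pd.DataFrame(rows, columns=["kind", "change", "term", "estimate", "se"])
    z = stats.norm.ppf(0.975)
    table["ci_low"] = table["estimate"] - z * table["se"]
    table["ci_high"] = table["estimate"] + z * table["se"]
    return fit, table
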