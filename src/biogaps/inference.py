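"""Multi-model inference of completeness drivers.

The driver analysis models inventory completeness as a composite binomial
response — per cell, ``S_doc`` successes ("species covered by records")
out of ``S_exp`` trials ("species presumed present") — with a logit link,
so cell richness is the binomial denominator and differences in richness
are automatically accounted for.

The framework:

1. fit all ``2**p`` non-spatial GLMs over subsets of the p standardized
   predictors and rank them by AIC;
2. refit every subset within ``dAIC < 10`` of the best score as a spatial
   model, adding a residuals autocovariate (RAC): per cell, the mean
   working residual of the subset's own non-spatial fit over neighbouring
   cells within a radius chosen by AIC grid search;
3. the minimum adequate model (MAM) is the spatial refit with the lowest
   AIC; model fit is summarized as the deviance explained
   ``D2 = 1 - deviance/null_deviance``;
4. predictor importance is measured two ways: the standardized
   coefficients (beta) of the MAM, and the percentage of the total sum of
   squares attributable to each predictor in a type III ANOVA whose
   response is the AIC of every model in the all-subsets space and whose
   factors code predictor presence/absence. On that balanced, orthogonal
   2**p design, type III and type I sums of squares coincide.

The binomial fits use an in-package iteratively reweighted least squares
(IRLS) solver, vectorized for the thousands of fits an all-subsets sweep
needs; convergence requires max |score| < 1e-8 or a relative deviance
change < 1e-10, and 100 iterations without convergence is reported as
likely separation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import chi2

__all__ = [
    "FitError",
    "ModelFit",
    "SubsetResult",
    "fit_binomial",
    "all_subsets",
    "build_rac",
    "fit_spatial_candidates",
    "importance_beta",
    "importance_anova_ss",
    "density_bivariate",
    "shared_deviance",
    "country_partial_d2",
]

MAX_ITER = 100
SCORE_TOL = 1e-8
DEV_TOL = 1e-10
RAC_NAME = "rac"
DEFAULT_RAC_RADII = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


class FitError(RuntimeError):
    pass


@dataclass
class ModelFit:
    """A fitted binomial GLM (optionally with a RAC term)."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes "(Intercept)" and possibly "rac"
    loglik: float
    aic: float
    deviance: float
    null_deviance: float
    fitted: np.ndarray = field(repr=False)  # fitted probabilities per cell
    working_residuals: np.ndarray = field(repr=False)
    pearson_residuals: np.ndarray = field(repr=False)
    n_obs: int = 0
    n_iter: int = 0
    spatial: bool = False
    rac_radius: float | None = None

    @property
    def d2(self) -> float:
        """Deviance explained, the GLM analogue of r^2."""
        return 1.0 - self.deviance / self.null_deviance if self.null_deviance > 0 else 0.0

    @property
    def k_params(self) -> int:
        return len(self.coefficients)


def _binom_deviance(y: np.ndarray, m: np.ndarray, p: np.ndarray) -> float:
    mu = m * p
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(m - y > 0, (m - y) * np.log((m - y) / (m - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _binom_loglik(y: np.ndarray, m: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    pc = np.clip(p, eps, 1 - eps)
    const = gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)
    return float((const + y * np.log(pc) + (m - y) * np.log(1 - pc)).sum())


def fit_binomial(
    s_doc: np.ndarray,
    s_exp: np.ndarray,
    X: np.ndarray | pd.DataFrame | None = None,
    names: tuple[str, ...] = (),
    *,
    check_rank: bool = True,
) -> ModelFit:
    """Maximum-likelihood logit-link binomial GLM via IRLS.

    ``s_doc`` are successes, ``s_exp`` trials (>= 1 everywhere); ``X`` holds
    the predictor columns (no intercept column — one is added). Raises
    :class:`FitError` on rank deficiency, complete separation (pooled rate
    0 or 1) or non-convergence.
    """
    y = np.asarray(s_doc, dtype=float)
    m = np.asarray(s_exp, dtype=float)
    if (m < 1).any():
        raise ValueError("every analyzed cell needs S_exp >= 1")
    if ((y < 0) | (y > m)).any():
        raise ValueError("S_doc must lie in [0, S_exp]")
    if X is None:
        Xd = np.ones((len(y), 1))
        names = ()
    else:
        if isinstance(X, pd.DataFrame):
            names = tuple(X.columns)
            X = X.to_numpy(float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        Xd = np.column_stack([np.ones(len(y)), X])
    k = Xd.shape[1]
    if check_rank and k > 1 and np.linalg.matrix_rank(Xd) < k:
        raise FitError("design matrix is rank deficient")

    pooled = y.sum() / m.sum()
    if pooled <= 0.0 or pooled >= 1.0:
        raise FitError(
            "complete separation: pooled completeness is 0 or 1, binomial MLE is infinite"
        )
    beta = np.zeros(k)
    beta[0] = math.log(pooled / (1 - pooled))
    dev = _binom_deviance(y, m, expit(Xd @ beta))
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        eta = Xd @ beta
        p = expit(eta)
        mu = m * p
        w = np.maximum(m * p * (1 - p), 1e-12)
        score = Xd.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            break
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        try:
            step = np.linalg.solve(Xd.T @ (Xd * w[:, None]), Xd.T @ (w * z)) - beta
        except np.linalg.LinAlgError:
            # (near-)collinear columns: minimum-norm weighted LS step; fitted
            # values (hence deviance/AIC) remain well defined
            step = np.linalg.lstsq(Xd * sw[:, None], z * sw, rcond=1e-10)[0] - beta
        # step halving keeps the deviance monotone on ill-conditioned designs
        new_dev, cand = np.inf, beta
        for half in range(31):
            cand = beta + step * 0.5**half
            new_dev = _binom_deviance(y, m, expit(Xd @ cand))
            if np.isfinite(new_dev) and new_dev <= dev + 1e-8:
                break
        else:
            raise FitError("IRLS step failed to reduce the deviance; possible separation")
        beta = cand
        if abs(dev - new_dev) < DEV_TOL * (abs(dev) + 1e-12):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise FitError("IRLS did not converge in 100 iterations; possible separation")

    eta = Xd @ beta
    p = expit(eta)
    mu = m * p
    w = np.maximum(m * p * (1 - p), 1e-12)
    dev = _binom_deviance(y, m, p)
    ll = _binom_loglik(y, m, p)
    null_p = np.full_like(p, pooled)
    null_dev = _binom_deviance(y, m, null_p)
    coef = {"(Intercept)": float(beta[0])}
    coef.update({n: float(b) for n, b in zip(names, beta[1:])})
    return ModelFit(
        predictors=tuple(n for n in names if n != RAC_NAME),
        coefficients=coef,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        deviance=dev,
        null_deviance=null_dev,
        fitted=p,
        working_residuals=(y - mu) / w,
        pearson_residuals=(y - mu) / np.sqrt(w),
        n_obs=len(y),
        n_iter=n_iter,
        spatial=RAC_NAME in names,
        rac_radius=None,
    )


@dataclass
class SubsetResult:
    """All-subsets sweep output: ranked fits plus failures."""

    fits: list[ModelFit]  # ascending AIC
    failed: list[tuple[tuple[str, ...], str]]
    predictor_names: tuple[str, ...]

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    def delta_aic_window(self, window: float = 10.0) -> list[ModelFit]:
        best = self.fits[0].aic
        return [f for f in self.fits if f.aic - best < window]

    def ranking_table(self) -> pd.DataFrame:
        name_ix = {n: i for i, n in enumerate(self.predictor_names)}
        rows = []
        best = self.fits[0].aic
        for f in self.fits:
            mask = sum(1 << name_ix[n] for n in f.predictors)
            rows.append(
                {
                    "subset_bitmask": mask,
                    "predictors": "+".join(f.predictors) or "(null)",
                    "k": len(f.predictors),
                    "aic": f.aic,
                    "delta_aic": f.aic - best,
                    "d2": f.d2,
                    "spatial": f.spatial,
                    "rac_radius": f.rac_radius,
                }
            )
        return pd.DataFrame(rows)


def all_subsets(
    s_doc: np.ndarray,
    s_exp: np.ndarray,
    X: pd.DataFrame,
    max_predictors: int = 16,
) -> SubsetResult:
    """Fit every subset of the predictor columns (2^p models, incl. null).

    Ranked ascending by AIC; ties broken by fewer predictors, then
    lexicographic subset order. Subsets whose fit fails are recorded with
    the reason and excluded from the ranking.
    """
    names = tuple(X.columns)
    p = len(names)
    if p > max_predictors:
        raise ValueError(f"{p} predictors exceed the 2^p cap ({max_predictors})")
    Xfull = X.to_numpy(float)
    fits: list[ModelFit] = []
    failed: list[tuple[tuple[str, ...], str]] = []
    for r in range(p + 1):
        for combo in itertools.combinations(range(p), r):
            sub_names = tuple(names[i] for i in combo)
            try:
                fit = fit_binomial(
                    s_doc, s_exp, Xfull[:, combo] if combo else None, sub_names,
                    check_rank=False,
                )
            except (FitError, ValueError) as exc:
                failed.append((sub_names, str(exc)))
                continue
            fits.append(fit)
    fits.sort(key=lambda f: (f.aic, len(f.predictors), f.predictors))
    if not fits:
        raise FitError("every subset fit failed")
    return SubsetResult(fits=fits, failed=failed, predictor_names=names)


def _neighbor_matrix(coords: np.ndarray, radius: float) -> np.ndarray:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    return (d <= radius) & (d > 0)


def build_rac(
    residuals: np.ndarray,
    coords: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Residuals autocovariate: mean neighbour residual within ``radius``.

    The focal cell is excluded; cells with no neighbour inside the radius
    get RAC = 0 (no information about local residual structure).
    """
    nb = _neighbor_matrix(np.asarray(coords, float), radius)
    counts = nb.sum(axis=1)
    rac = np.zeros(len(residuals))
    has = counts > 0
    rac[has] = (nb[has] @ np.asarray(residuals, float)) / counts[has]
    return rac


def _spatial_refit(
    s_doc: np.ndarray,
    s_exp: np.ndarray,
    X: pd.DataFrame,
    fit: ModelFit,
    coords: np.ndarray,
    radii: tuple[float, ...],
) -> ModelFit:
    """Refit one subset with its RAC column, radius chosen by AIC grid search."""
    best: ModelFit | None = None
    for r in radii:
        rac = build_rac(fit.working_residuals, coords, r)
        cols = list(fit.predictors) + [RAC_NAME]
        Xs = np.column_stack([X[list(fit.predictors)].to_numpy(float), rac]) if fit.predictors else rac[:, None]
        try:
            cand = fit_binomial(s_doc, s_exp, Xs, tuple(cols), check_rank=False)
        except (FitError, ValueError):
            continue
        cand.rac_radius = r
        if best is None or cand.aic < best.aic:
            best = cand
    if best is None:
        raise FitError(f"spatial refit failed for subset {fit.predictors}")
    return best


def fit_spatial_candidates(
    s_doc: np.ndarray,
    s_exp: np.ndarray,
    X: pd.DataFrame,
    ranking: SubsetResult,
    coords: np.ndarray,
    window: float = 10.0,
    radii: tuple[float, ...] = DEFAULT_RAC_RADII,
) -> tuple[list[ModelFit], ModelFit]:
    """Spatially refit every subset within ``dAIC < window`` of the best AIC.

    Returns ``(spatial_fits, mam)`` where the MAM (minimum adequate model)
    is the spatial fit with the lowest AIC. The candidate set always
    contains at least the best non-spatial subset.
    """
    candidates = ranking.delta_aic_window(window)
    spatial_fits = [
        _spatial_refit(s_doc, s_exp, X, f, coords, radii) for f in candidates
    ]
    mam = min(spatial_fits, key=lambda f: f.aic)
    return spatial_fits, mam


def importance_beta(mam: ModelFit, predictor_names: tuple[str, ...]) -> pd.Series:
    """Standardized coefficients of the MAM; NaN marks predictors not selected."""
    return pd.Series(
        {n: mam.coefficients.get(n, np.nan) for n in predictor_names}, name="beta"
    )


def importance_anova_ss(
    ranking: SubsetResult,
    include_null: bool = True,
) -> pd.Series:
    """%SS importance: share of each predictor in the AIC-ANOVA total SS.

    Response: the AIC of every model in the all-subsets space; factors:
    sum-to-zero (+1/-1) indicators of predictor presence. The full 2^p
    design is balanced and orthogonal, so each factor's type III sum of
    squares equals its type I value: SS_k = (x_k . y)^2 / n with coded
    x_k. Failed subsets are imputed at the worst observed AIC so the
    design stays complete. Percentages are of the total SS (including the
    residual) and therefore sum to <= 100.
    """
    names = ranking.predictor_names
    p = len(names)
    worst = max(f.aic for f in ranking.fits)
    aic_by_subset = {f.predictors: f.aic for f in ranking.fits}
    for subset, _reason in ranking.failed:
        aic_by_subset[subset] = worst
    rows, y = [], []
    for subset, aic in aic_by_subset.items():
        if not include_null and len(subset) == 0:
            continue
        rows.append([1.0 if n in subset else -1.0 for n in names])
        y.append(aic)
    D = np.asarray(rows)
    y = np.asarray(y)
    n = len(y)
    expected = 2**p if include_null else 2**p - 1
    if n != expected:
        raise FitError(f"incomplete model set: {n} of {expected} subsets")
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    if ss_total == 0:
        return pd.Series(0.0, index=list(names), name="pct_ss")
    # balanced design: columns are orthogonal and mean-zero
    ss = (D.T @ yc) ** 2 / (D**2).sum(axis=0)
    return pd.Series(100.0 * ss / ss_total, index=list(names), name="pct_ss")


def importance_table(
    mam: ModelFit, ranking: SubsetResult, include_null: bool = True
) -> pd.DataFrame:
    """Per-predictor beta (MAM) and %SS (AIC-ANOVA), with effect signs."""
    beta = importance_beta(mam, ranking.predictor_names)
    pct = importance_anova_ss(ranking, include_null)
    out = pd.DataFrame({"beta": beta, "pct_ss": pct})
    out["sign"] = np.sign(out["beta"]).where(out["beta"].notna())
    out.index.name = "predictor"
    return out


def density_bivariate(s_doc: np.ndarray, s_exp: np.ndarray, n_rec: np.ndarray) -> ModelFit:
    """Binomial GLM of completeness on log10(record density + 1).

    Its ``d2`` measures how far record density alone predicts completeness.
    """
    x = np.log10(np.asarray(n_rec, float) + 1.0)
    if np.ptp(x) == 0:
        raise ValueError("record density is constant; zero-variance predictor")
    z = (x - x.mean()) / x.std()
    return fit_binomial(s_doc, s_exp, z[:, None], ("log10_density",))


def shared_deviance(
    s_doc: np.ndarray,
    s_exp: np.ndarray,
    X: pd.DataFrame,
    mam: ModelFit,
    n_rec: np.ndarray,
) -> float:
    """Fraction of the MAM-explained deviance also explained by record density.

    Deviance decomposition over the union model: with explained deviances
    ED_d (density only), ED_m (the MAM's predictor set) and ED_u (their
    union), the shared part is ED_d + ED_m - ED_u and the fraction is
    shared / ED_m, clipped to [0, 1]. All three models are non-spatial
    binomial GLMs on the same cells.
    """
    dens = np.log10(np.asarray(n_rec, float) + 1.0)
    dens = (dens - dens.mean()) / dens.std()
    cols = list(mam.predictors)
    Xm = X[cols].to_numpy(float) if cols else None
    fit_m = fit_binomial(s_doc, s_exp, Xm, tuple(cols), check_rank=False)
    fit_d = fit_binomial(s_doc, s_exp, dens[:, None], ("log10_density",))
    Xu = np.column_stack([X[cols].to_numpy(float), dens]) if cols else dens[:, None]
    fit_u = fit_binomial(s_doc, s_exp, Xu, tuple(cols) + ("log10_density",), check_rank=False)
    ed_m = fit_m.null_deviance - fit_m.deviance
    ed_d = fit_d.null_deviance - fit_d.deviance
    ed_u = fit_u.null_deviance - fit_u.deviance
    if ed_m <= 0:
        raise FitError("MAM explains no deviance; shared fraction undefined")
    return float(np.clip((ed_d + ed_m - ed_u) / ed_m, 0.0, 1.0))


def country_partial_d2(
    s_doc: np.ndarray,
    s_exp: np.ndarray,
    X: pd.DataFrame,
    mam: ModelFit,
    country: np.ndarray,
    rac: np.ndarray | None = None,
) -> tuple[float, float]:
    """Extra deviance explained by country identity on top of the MAM.

    Adds country dummy variables (reference = first country) to the MAM's
    covariates and returns ``(delta_d2, lrt_p)`` from a likelihood-ratio
    chi-square test. Dummies aliased with the existing covariates are
    dropped (country-level predictors already in the model absorb part of
    the country space exactly), and the test runs on the surviving df.
    """
    country = np.asarray(country)
    levels = pd.unique(country)
    if len(levels) < 2:
        raise ValueError("need >= 2 countries among analyzed cells")
    base_cols = [X[c].to_numpy(float) for c in mam.predictors]
    names = list(mam.predictors)
    if rac is not None:
        base_cols.append(np.asarray(rac, float))
        names.append(RAC_NAME)
    X0 = np.column_stack(base_cols) if base_cols else None
    fit0 = fit_binomial(s_doc, s_exp, X0, tuple(names), check_rank=False)
    kept = [np.ones(len(s_doc))] + base_cols
    rank = np.linalg.matrix_rank(np.column_stack(kept))
    dummies, dummy_names = [], []
    for lev in levels[1:]:
        col = (country == lev).astype(float)
        cand_rank = np.linalg.matrix_rank(np.column_stack(kept + [col]))
        if cand_rank > rank:
            kept.append(col)
            rank = cand_rank
            dummies.append(col)
            dummy_names.append(f"country[{lev}]")
    if not dummies:
        return 0.0, 1.0
    X1 = np.column_stack((base_cols or []) + dummies)
    fit1 = fit_binomial(s_doc, s_exp, X1, tuple(names + dummy_names), check_rank=False)
    delta_d2 = fit1.d2 - fit0.d2
    lr = 2.0 * (fit1.loglik - fit0.loglik)
    df = len(dummy_names)
    p = float(chi2.sf(max(lr, 0.0), df))
    return float(delta_d2), p
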