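"""Small self-contained linear-model engine (OLS, ANOVA/ANCOVA, Poisson GLM).

Supports exactly what the inferential stages need: ordinary least squares
with treatment-coded factors and interactions, sequential (Type I) F
tables for nested chains, one-way ANOVA, Poisson log-linear models fitted
by iteratively reweighted least squares, and likelihood-ratio (deviance)
chi-square tests with optional overdispersion rescaling.  Term language:

* ``"x"``            numeric covariate (column of the data frame)
* ``"C(g)"``         categorical factor, treatment coding, first level is
                     the reference (habitat defaults to the ordinal order
                     low < intermediate < high)
* ``"a:b"``          interaction (componentwise product of the coded parts)

An intercept is always included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import HABITAT_LEVELS

__all__ = [
    "ModelFit",
    "build_design",
    "fit_ols",
    "fit_ols_formula",
    "sequential_f_table",
    "fit_poisson",
    "fit_poisson_formula",
    "deviance_chisq_test",
    "one_way_anova",
    "log1p_transform",
]

DEFAULT_FACTOR_LEVELS = {"habitat": list(HABITAT_LEVELS)}


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient (aliased terms)."""


@dataclass
class ModelFit:
    """A fitted linear or Poisson log-linear model."""

    coef_names: list[str]
    params: np.ndarray
    fitted_values: np.ndarray
    residual_df: int
    rss: float | None = None          # OLS
    deviance: float | None = None     # GLM
    dispersion: float = 1.0
    family: str = "gaussian"
    y: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)
    terms: list[str] = field(default_factory=list)
    cov_params: np.ndarray = field(default=None, repr=False)
    n_iter: int = 0

    @property
    def nobs(self) -> int:
        return len(self.y)

    def bse(self) -> np.ndarray:
        """Standard errors of the coefficients."""
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Two-sided confidence intervals, t-based (OLS) or normal (GLM)."""
        se = self.bse()
        if self.family == "gaussian":
            q = stats.t.ppf(1 - alpha / 2, self.residual_df)
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - q * se, self.params + q * se])

    def coef(self, name: str) -> float:
        return float(self.params[self.coef_names.index(name)])


def log1p_transform(x: np.ndarray) -> np.ndarray:
    """The ``log(x + 1)`` normalizing transform applied to body traits."""
    return np.log1p(np.asarray(x, dtype=float))


def _code_component(df: pd.DataFrame, comp: str, factor_levels: dict) -> tuple[np.ndarray, list[str]]:
    comp = comp.strip()
    if comp.startswith("C(") and comp.endswith(")"):
        name = comp[2:-1].strip()
        if name not in df.columns:
            raise KeyError(f"factor column {name!r} not in data")
        levels = factor_levels.get(name)
        if levels is None:
            levels = sorted(df[name].astype(str).unique())
        observed = set(df[name].astype(str))
        levels = [lv for lv in levels if lv in observed]
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"factor {name!r} has unlisted levels {sorted(unknown)}")
        cols = [
            (df[name].astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]
        ]
        names = [f"{name}[{lv}]" for lv in levels[1:]]
        if not cols:
            return np.empty((len(df), 0)), []
        return np.column_stack(cols), names
    if comp not in df.columns:
        raise KeyError(f"covariate column {comp!r} not in data")
    return df[comp].to_numpy(dtype=float)[:, None], [comp]


def _code_term(df: pd.DataFrame, term: str, factor_levels: dict) -> tuple[np.ndarray, list[str]]:
    parts = [p for p in term.split(":")]
    X, names = _code_component(df, parts[0], factor_levels)
    for part in parts[1:]:
        Xp, np_names = _code_component(df, part, factor_levels)
        X = np.concatenate(
            [X[:, [i]] * Xp[:, [j]] for i in range(X.shape[1]) for j in range(Xp.shape[1])],
            axis=1,
        ) if X.shape[1] and Xp.shape[1] else np.empty((len(df), 0))
        names = [f"{a}:{b}" for a in names for b in np_names]
    return X, names


def build_design(
    df: pd.DataFrame, terms: list[str], factor_levels: dict | None = None
) -> tuple[np.ndarray, list[str], list[tuple[str, int]]]:
    """Design matrix with intercept; returns (X, column names, term spans)."""
    levels = dict(DEFAULT_FACTOR_LEVELS)
    if factor_levels:
        levels.update(factor_levels)
    blocks = [np.ones((len(df), 1))]
    names = ["Intercept"]
    spans = [("Intercept", 1)]
    for term in terms:
        Xt, nt = _code_term(df, term, levels)
        blocks.append(Xt)
        names.extend(nt)
        spans.append((term, Xt.shape[1]))
    X = np.concatenate(blocks, axis=1)
    return X, names, spans


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased, cols = [], []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(j)
            else:
                aliased.append(names[j])
        raise RankDeficiencyError(f"design is rank deficient; aliased terms: {aliased}")


def fit_ols(y: np.ndarray, X: np.ndarray, coef_names: list[str] | None = None,
            terms: list[str] | None = None) -> ModelFit:
    """Ordinary least squares with rank checking."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y and X are not conformable")
    names = coef_names or [f"b{j}" for j in range(X.shape[1])]
    if len(y) <= X.shape[1]:
        raise ValueError(f"n = {len(y)} observations for p = {X.shape[1]} parameters")
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = len(y) - X.shape[1]
    sigma2 = rss / df if df > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    return ModelFit(
        coef_names=names,
        params=beta,
        fitted_values=fitted,
        residual_df=df,
        rss=rss,
        dispersion=sigma2,
        family="gaussian",
        y=y,
        X=X,
        terms=terms or [],
        cov_params=xtx_inv * sigma2,
    )


def fit_ols_formula(
    df: pd.DataFrame, response: str, terms: list[str],
    factor_levels: dict | None = None,
) -> ModelFit:
    X, names, _ = build_design(df, terms, factor_levels)
    return fit_ols(df[response].to_numpy(dtype=float), X, names, terms)


def sequential_f_table(
    df: pd.DataFrame, response: str, terms: list[str],
    factor_levels: dict | None = None,
) -> pd.DataFrame:
    """Type-I (sequential) F table: terms added in the order given.

    Each row tests the reduction in residual sum of squares from adding
    one term, against the residual mean square of the full model:
    ``F = (dRSS / ddf) / (RSS_full / df_full)``.
    """
    y = df[response].to_numpy(dtype=float)
    fits = []
    for k in range(len(terms) + 1):
        X, names, _ = build_design(df, terms[:k], factor_levels)
        fits.append(fit_ols(y, X, names, terms[:k]))
    return f_table_from_chain(fits, terms)


def f_table_from_chain(fits: list[ModelFit], term_labels: list[str]) -> pd.DataFrame:
    """Sequential F tests from an explicit nested chain of OLS fits."""
    full = fits[-1]
    if any(f.nobs != full.nobs for f in fits):
        raise ValueError("fits in the chain use different responses")
    scale = max(max(f.rss for f in fits), 1e-30)
    rows = []
    for reduced, larger, label in zip(fits[:-1], fits[1:], term_labels):
        if reduced.rss < larger.rss - 1e-9 * scale:
            raise ValueError(f"chain not nested at term {label!r}: RSS increased")
        ddf = reduced.residual_df - larger.residual_df
        if ddf <= 0:
            raise ValueError(f"term {label!r} adds no degrees of freedom (aliased)")
        drss = max(reduced.rss - larger.rss, 0.0)
        if full.residual_df <= 0:
            raise ValueError("saturated full model: no residual degrees of freedom")
        mse = full.rss / full.residual_df
        if mse <= 1e-14 * scale:
            if drss <= 1e-14 * scale:
                f_stat, p = 0.0, 1.0  # term explains nothing of a perfect fit
            else:
                import warnings

                warnings.warn("perfect fit: F reported as infinity")
                f_stat, p = np.inf, 0.0
        else:
            f_stat = (drss / ddf) / mse
            p = float(stats.f.sf(f_stat, ddf, full.residual_df))
        rows.append(
            {"term": label, "df1": ddf, "df2": full.residual_df,
             "F": float(f_stat), "p": p}
        )
    return pd.DataFrame(rows)


def one_way_anova(y: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Classic one-way ANOVA F test (between/within mean squares)."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if len(y) <= len(labels):
        raise ValueError("not enough observations for the number of groups")
    grand = y.mean()
    ssb = sum(
        len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2 for g in labels
    )
    ssw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in labels)
    df1 = len(labels) - 1
    df2 = len(y) - len(labels)
    msw = ssw / df2
    f_stat = np.inf if msw == 0 else (ssb / df1) / msw
    p = 0.0 if msw == 0 else float(stats.f.sf(f_stat, df1, df2))
    return pd.DataFrame(
        [{"term": "group", "df1": df1, "df2": df2, "F": float(f_stat), "p": p}]
    )


def fit_poisson(
    y: np.ndarray, X: np.ndarray, coef_names: list[str] | None = None,
    terms: list[str] | None = None,
    tol: float = 1e-10, max_iter: int = 100,
) -> ModelFit:
    """Poisson log-linear model by iteratively reweighted least squares.

    Converged when the relative change in deviance drops below ``tol``
    (default 1e-10, at most 100 iterations).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
        raise ValueError("Poisson response must be non-negative integers")
    X = np.asarray(X, dtype=float)
    names = coef_names or [f"b{j}" for j in range(X.shape[1])]
    _check_rank(X, names)
    mu = y + 0.5
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    trace = [dev]
    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        trace.append(new_dev)
        denom = abs(dev) if dev > 0 else 1.0
        if abs(new_dev - dev) / (denom + 0.1) < tol:
            dev = new_dev
            break
        dev = new_dev
    else:
        raise RuntimeError(
            f"Poisson IRLS did not converge in {max_iter} iterations; "
            f"deviance trace: {trace[:5]} ... {trace[-3:]}"
        )
    df = len(y) - X.shape[1]
    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    return ModelFit(
        coef_names=names,
        params=beta,
        fitted_values=mu,
        residual_df=df,
        deviance=float(dev),
        dispersion=float(dev / df) if df > 0 else np.nan,
        family="poisson",
        y=y,
        X=X,
        terms=terms or [],
        cov_params=cov,
        n_iter=it,
    )


def fit_poisson_formula(
    df: pd.DataFrame, response: str, terms: list[str],
    factor_levels: dict | None = None,
) -> ModelFit:
    X, names, _ = build_design(df, terms, factor_levels)
    return fit_poisson(df[response].to_numpy(dtype=float), X, names, terms)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * (term - (y - mu)).sum())


def deviance_chisq_test(
    reduced: ModelFit, full: ModelFit, rescale: bool = True
) -> pd.DataFrame:
    """Likelihood-ratio (deviance) test between nested Poisson fits.

    Without rescaling: chi-square on ``ddf = df_reduced - df_full``.  With
    ``rescale`` and estimated dispersion ``phi = deviance_full/df_full > 1``
    the statistic becomes ``F = (ddeviance/ddf)/phi`` on ``(ddf, df_full)``
    — a quasi-likelihood correction that is strictly more conservative than
    the unscaled chi-square whenever overdispersion is present.
    """
    if reduced.family != "poisson" or full.family != "poisson":
        raise ValueError("deviance test requires Poisson fits")
    if reduced.nobs != full.nobs:
        raise ValueError("fits use different data")
    ddf = reduced.residual_df - full.residual_df
    if ddf <= 0:
        raise ValueError("models are not strictly nested")
    ddev = reduced.deviance - full.deviance
    if ddev < -1e-8 * max(1.0, abs(full.deviance)):
        raise ValueError("deviance increased: models are not nested")
    ddev = max(ddev, 0.0)
    phi = full.deviance / full.residual_df if full.residual_df > 0 else np.nan
    if rescale and np.isfinite(phi) and phi > 1:
        f_stat = (ddev / ddf) / phi
        p = float(stats.f.sf(f_stat, ddf, full.residual_df))
        return pd.DataFrame(
            [{"term": "vs reduced", "statistic": float(f_stat), "kind": "F",
              "df1": ddf, "df2": full.residual_df, "p": p, "dispersion": float(phi),
              "rescaled": True}]
        )
    p = float(stats.chi2.sf(ddev, ddf)) if ddev > 0 else 1.0
    return pd.DataFrame(
        [{"term": "vs reduced", "statistic": float(ddev), "kind": "chi2",
          "df1": ddf, "df2": None, "p": p,
          "dispersion": float(phi) if np.isfinite(phi) else None, "rescaled": False}]
    )
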