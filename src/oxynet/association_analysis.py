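"""Inferential stages: habitat summaries, growth-infestation ANCOVAs and
individual-level network GLMs.

Three questions drive this module.  (1) Do tortoise body traits and
infestation differ among habitat-loss levels (summary table + one-way
tests)?  (2) Is the association between individual growth rate and
oxyurid infestation (species richness or total worm abundance)
habitat-dependent — positive, absent or negative — as judged by the
habitat x covariate interaction of an ANCOVA and by per-habitat
regression slopes with 95% confidence intervals?  (3) At the node level,
do heavier, larger or faster-growing tortoises carry more oxyurid
species (Poisson GLM of species-degree) or more exclusive parasite
spectra (OLS of d')?

Body weight and carapace length enter tests log(x+1)-transformed;
growth-rate scores are used untransformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import HABITAT_LEVELS, StudyDataset
from .linear_models import (
    deviance_chisq_test,
    fit_ols_formula,
    fit_poisson_formula,
    log1p_transform,
    sequential_f_table,
)
from .network_metrics import dprime_hosts, host_degrees

__all__ = [
    "habitat_summaries",
    "growth_infestation_ancova",
    "individual_network_models",
    "host_network_frame",
]

_SUMMARY_VARS = ("weight_g", "carapace_mm", "growth_rate_k", "richness", "abundance")


def _mean_se(x: pd.Series) -> tuple[float, float]:
    x = x.dropna()
    if len(x) == 0:
        return float("nan"), float("nan")
    if len(x) == 1:
        return float(x.iloc[0]), float("nan")  # SE of one observation is NA
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def habitat_summaries(ds: StudyDataset, subset: str = "all") -> pd.DataFrame:
    """Mean +/- SE of traits and infestation per habitat (Table-1 style).

    ``subset`` is ``"all"`` (every life stage) or ``"adults"``.  Richness
    and abundance include uninfected hosts as zeros — means are over all
    sampled hosts in the subset, not just infected ones.
    """
    if subset not in ("all", "adults"):
        raise ValueError("subset must be 'all' or 'adults'")
    df = ds.to_host_frame()
    if subset == "adults":
        df = df[df["stage"] == "adult"]
    rows = []
    for habitat in HABITAT_LEVELS:
        sub = df[df["habitat"] == habitat]
        if len(sub) == 0:
            warnings.warn(f"no hosts in habitat {habitat!r} for subset {subset!r}")
        row: dict = {"habitat": habitat, "subset": subset, "n": len(sub)}
        for var in _SUMMARY_VARS:
            mean, se = _mean_se(sub[var]) if len(sub) else (float("nan"),) * 2
            row[f"{var}_mean"] = mean
            row[f"{var}_se"] = se
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AncovaResult:
    """Sequential F table plus per-habitat slopes and their reading."""

    table: pd.DataFrame
    slopes: pd.DataFrame   # habitat, slope, ci_low, ci_high, sign, n

    def as_dict(self) -> dict:
        return {
            "anova": self.table.to_dict(orient="records"),
            "slopes": self.slopes.to_dict(orient="records"),
        }


def _classify(ci_low: float, ci_high: float) -> str:
    if ci_low > 0:
        return "positive"
    if ci_high < 0:
        return "negative"
    return "neutral"


def growth_infestation_ancova(
    ds: StudyDataset, covariate: str = "richness", subset: str = "all",
    min_hosts: int = 3, sign_alpha: float = 0.01,
) -> AncovaResult:
    """ANCOVA of growth rate on habitat x infestation.

    OLS of the growth-rate score ``k`` on the infestation covariate
    (``richness`` or ``abundance``), habitat and their interaction,
    sequential (Type I) sums of squares with the interaction entered last.
    Per-habitat simple regressions give the slope sign classification
    (positive / neutral / negative) that summarizes the endosymbiont
    interaction type in each landscape; a sign is only declared when the
    ``1 - sign_alpha`` confidence interval excludes zero (default 99%, a
    deliberately strict call so 'neutral' habitats are rarely mislabelled).
    """
    if covariate not in ("richness", "abundance"):
        raise ValueError("covariate must be 'richness' or 'abundance'")
    df = ds.to_host_frame()
    if subset == "adults":
        df = df[df["stage"] == "adult"]
    df = df.dropna(subset=["growth_rate_k"])
    kept = []
    for habitat in HABITAT_LEVELS:
        sub = df[df["habitat"] == habitat]
        if len(sub) < min_hosts:
            warnings.warn(
                f"habitat {habitat!r} has {len(sub)} hosts (< {min_hosts}); dropped"
            )
        else:
            kept.append(habitat)
    df = df[df["habitat"].isin(kept)].reset_index(drop=True)
    table = sequential_f_table(
        df,
        "growth_rate_k",
        [covariate, "C(habitat)", f"{covariate}:C(habitat)"],
        factor_levels={"habitat": kept},
    )
    slope_rows = []
    for habitat in kept:
        sub = df[df["habitat"] == habitat]
        fit = fit_ols_formula(sub, "growth_rate_k", [covariate])
        idx = fit.coef_names.index(covariate)
        lo, hi = fit.conf_int(sign_alpha)[idx]
        slope_rows.append(
            {
                "habitat": habitat,
                "slope": fit.coef(covariate),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "sign": _classify(lo, hi),
                "n": len(sub),
            }
        )
    return AncovaResult(table=table, slopes=pd.DataFrame(slope_rows))


def host_network_frame(ds: StudyDataset, habitat: str) -> pd.DataFrame:
    """Traits joined with node-level network metrics for infected hosts.

    Degree and d' are computed on the habitat matrix restricted to
    infected hosts; trait rows are joined by host id, and missing ids
    raise with the offending list.
    """
    from .data_model import drop_uninfected_hosts

    m = drop_uninfected_hosts(ds.matrices[habitat])
    traits = ds.to_host_frame().set_index("host_id")
    missing = [h for h in m.host_ids if h not in traits.index]
    if missing:
        raise KeyError(f"hosts {missing} in the {habitat} matrix lack trait records")
    df = traits.loc[list(m.host_ids)].reset_index()
    df["degree"] = host_degrees(m)
    df["dprime"] = dprime_hosts(m)
    df["log_weight"] = log1p_transform(df["weight_g"])
    df["log_carapace"] = log1p_transform(df["carapace_mm"])
    return df


def individual_network_models(
    ds: StudyDataset, rescale: bool = True
) -> pd.DataFrame:
    """Per-habitat GLMs of node-level metrics on individual traits.

    For each habitat and each trait (log weight, log carapace length,
    growth rate k): a Poisson log-linear model of species-degree tested by
    the chi-square measure of deviance (rescaled to an F test when
    overdispersed), and a Gaussian OLS of d' tested by its sequential F.
    Each row reports the effect direction.
    """
    traits = {"log_weight": "weight", "log_carapace": "carapace", "growth_rate_k": "k"}
    rows = []
    for habitat in ds.matrices:
        df = host_network_frame(ds, habitat)
        for col, label in traits.items():
            if df[col].nunique() <= 1:
                raise ValueError(
                    f"trait {label!r} is constant in habitat {habitat!r}: zero-df term"
                )
            null_fit = fit_poisson_formula(df, "degree", [])
            full_fit = fit_poisson_formula(df, "degree", [col])
            test = deviance_chisq_test(null_fit, full_fit, rescale=rescale).iloc[0]
            rows.append(
                {
                    "habitat": habitat, "response": "degree", "trait": label,
                    "estimate": full_fit.coef(col),
                    "direction": "positive" if full_fit.coef(col) > 0 else "negative",
                    "statistic": test["statistic"], "kind": test["kind"],
                    "df1": test["df1"], "df2": test["df2"], "p": test["p"],
                    "dispersion": test["dispersion"], "rescaled": test["rescaled"],
                }
            )
            ols_table = sequential_f_table(df, "dprime", [col])
            fit = fit_ols_formula(df, "dprime", [col])
            t = ols_table.iloc[0]
            rows.append(
                {
                    "habitat": habitat, "response": "dprime", "trait": label,
                    "estimate": fit.coef(col),
                    "direction": "positive" if fit.coef(col) > 0 else "negative",
                    "statistic": t["F"], "kind": "F",
                    "df1": t["df1"], "df2": t["df2"], "p": t["p"],
                    "dispersion": fit.dispersion, "rescaled": False,
                }
            )
    return pd.DataFrame(rows)
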