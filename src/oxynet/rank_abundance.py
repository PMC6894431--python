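"""Rank/abundance (dominance) curves and the slope-comparison ANCOVA.

A rank/abundance curve plots log10 relative abundance against descending
abundance rank; its slope measures community evenness (steeper = a few
dominant species, gentler = more even).  Curves from different habitats
are compared by pooling them in one OLS of log relative abundance on
rank, habitat and their interaction: a significant habitat x rank
interaction means the evenness of the parasite community differs across
habitat-loss levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import HABITAT_LEVELS, InteractionMatrix
from .linear_models import fit_ols_formula, sequential_f_table

__all__ = ["RankAbundanceTable", "rank_table", "fit_slope", "compare_slopes"]


@dataclass(frozen=True)
class RankAbundanceTable:
    habitat: str
    species: tuple[str, ...]
    rank: np.ndarray
    rel_abundance: np.ndarray
    log_rel_abundance: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "habitat": self.habitat,
                "species": list(self.species),
                "rank": self.rank,
                "rel_abundance": self.rel_abundance,
                "log_rel_abundance": self.log_rel_abundance,
            }
        )


def rank_table(m: InteractionMatrix) -> RankAbundanceTable:
    """Species ranked by descending total abundance (row sums).

    Relative abundances sum to one over the species present; zero-total
    species are excluded (their log abundance is undefined).  Ties are
    broken by species label so the ranking is deterministic.
    """
    totals = m.species_totals()
    if totals.sum() == 0:
        raise ValueError("all-zero matrix has no rank/abundance curve")
    order = sorted(
        (i for i in range(m.n_species) if totals[i] > 0),
        key=lambda i: (-totals[i], m.species_ids[i]),
    )
    rel = totals[order] / totals.sum()
    return RankAbundanceTable(
        habitat=m.habitat,
        species=tuple(m.species_ids[i] for i in order),
        rank=np.arange(1, len(order) + 1),
        rel_abundance=rel,
        log_rel_abundance=np.log10(rel),
    )


def fit_slope(t: RankAbundanceTable) -> tuple[float, float]:
    """OLS slope and intercept of log10 relative abundance on rank."""
    if len(t.rank) < 3:
        raise ValueError("need at least 3 ranked species to fit a slope")
    df = t.to_dataframe()
    fit = fit_ols_formula(df, "log_rel_abundance", ["rank"])
    return fit.coef("rank"), fit.coef("Intercept")


def compare_slopes(tables: dict[str, RankAbundanceTable]) -> pd.DataFrame:
    """Sequential (Type I) ANCOVA comparing curve slopes across habitats.

    Pools all curves into one OLS of log10 relative abundance on rank,
    habitat and rank x habitat (entered in that order); the interaction
    row tests whether evenness differs among habitats.  Residual df is
    ``N - 2 * n_habitats`` (one intercept and one slope per habitat).
    """
    if len(tables) < 2:
        raise ValueError("need curves from at least 2 habitats")
    for hab, t in tables.items():
        if len(t.rank) < 3:
            raise ValueError(f"habitat {hab!r} has fewer than 3 ranked species")
    df = pd.concat([t.to_dataframe() for t in tables.values()], ignore_index=True)
    order = [h for h in HABITAT_LEVELS if h in tables] + [
        h for h in tables if h not in HABITAT_LEVELS
    ]
    return sequential_f_table(
        df,
        "log_rel_abundance",
        ["rank", "C(habitat)", "rank:C(habitat)"],
        factor_levels={"habitat": order},
    )
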