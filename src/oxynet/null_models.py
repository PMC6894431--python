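"""Degree-proportional null model and Monte-Carlo nestedness significance.

The occurrence probability of each cell under the null is the average of
its row's and column's fill proportions (Bascompte's Null Model II),

    P_ij = (k_i / n_hosts + k_j / n_species) / 2,

which preserves degree heterogeneity probabilistically without fixing
marginals.  Because the observed networks are weighted, filled null cells
receive quantitative values by permuting the observed positive counts
(subsampled without replacement when the null draw has fewer links,
padded by resampling with replacement when it has more).  Significance of
the observed WNODF is the upper-tail Monte-Carlo probability with the
add-one correction, so p is never reported as exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import InteractionMatrix
from .network_metrics import wnodf

__all__ = ["NullEnsemble", "cell_probabilities", "sample_null_matrix", "nestedness_test"]


@dataclass
class NullEnsemble:
    """Monte-Carlo summary of a nestedness significance test."""

    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null distribution is degenerate
    p_value: float
    n_replicates: int
    seed: int | None
    replicates: np.ndarray = field(repr=False)
    weight_scheme: str = "permuted-observed-weights"

    def as_dict(self, full: bool = False) -> dict:
        d = {
            "observed_wnodf": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if np.isnan(self.z) else self.z,
            "p_value": self.p_value,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "weight_scheme": self.weight_scheme,
        }
        if full:
            d["replicates"] = self.replicates.tolist()
        return d


def cell_probabilities(m: InteractionMatrix) -> np.ndarray:
    """Null Model II occurrence probabilities ``P_ij``.

    Average of the row fill (hosts used by species *i* over all hosts) and
    the column fill (species infecting host *j* over all species).  The
    expected fill ``mean(P)`` equals the observed connectance computed over
    the full matrix dimensions.
    """
    binary = m.counts > 0
    row_fill = binary.sum(axis=1) / m.n_hosts
    col_fill = binary.sum(axis=0) / m.n_species
    return (row_fill[:, None] + col_fill[None, :]) / 2.0


def sample_null_matrix(
    m: InteractionMatrix, rng: np.random.Generator, probabilities: np.ndarray | None = None
) -> InteractionMatrix:
    """One weighted null matrix: Bernoulli(P_ij) skeleton + permuted weights.

    Degenerate draws (empty rows/columns) are kept as drawn — resampling
    them away would bias the null distribution upward.
    """
    p = cell_probabilities(m) if probabilities is None else probabilities
    skeleton = rng.random(p.shape) < p
    n_fill = int(skeleton.sum())
    observed = m.counts[m.counts > 0]
    counts = np.zeros_like(m.counts)
    if n_fill > 0 and observed.size > 0:
        if n_fill <= observed.size:
            weights = rng.permutation(observed)[:n_fill]
        else:
            extra = rng.choice(observed, size=n_fill - observed.size, replace=True)
            weights = np.concatenate([rng.permutation(observed), extra])
        counts[skeleton] = weights
    elif n_fill > 0:
        counts[skeleton] = 1
    return InteractionMatrix(
        species_ids=m.species_ids, host_ids=m.host_ids, counts=counts, habitat=m.habitat
    )


def nestedness_test(
    m: InteractionMatrix,
    n_replicates: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullEnsemble:
    """Monte-Carlo WNODF significance against the degree-proportional null.

    ``p = (1 + #{null >= observed}) / (n_replicates + 1)`` (upper tail,
    add-one corrected); ``z = (observed - mean) / sd`` of the null
    replicates, NaN when the null sd is zero.  Null replicates on which
    WNODF is undefined (both axes degenerate after dropping empty margins)
    score 0 — an empty draw carries no nested structure.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = wnodf(m)
    p = cell_probabilities(m)
    reps = np.empty(n_replicates)
    for r in range(n_replicates):
        null = sample_null_matrix(m, rng, probabilities=p)
        try:
            reps[r] = wnodf(null)
        except ValueError:
            reps[r] = 0.0
    null_mean = float(reps.mean())
    null_sd = float(reps.std(ddof=1)) if n_replicates > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p_value = (1.0 + np.count_nonzero(reps >= observed)) / (n_replicates + 1.0)
    return NullEnsemble(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_value=float(p_value),
        n_replicates=n_replicates,
        seed=seed,
        replicates=reps,
    )
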