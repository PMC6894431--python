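"""Weighted bipartite network statistics.

Network-level: connectance ``C``, interaction diversity ``ID`` (Shannon
entropy of link weights), weighted nestedness ``WNODF`` (overlap and
decreasing fill, 0-100) and the network-level specialization index
``H2'`` (0 = opportunistic, 1 = fully specialized).  Node-level, for each
host: species-degree (number of parasite species infecting it) and
Bluethgen's ``d'`` (Kullback-Leibler divergence of the host's partner
spectrum from partner availability, standardized to [0, 1]).

Conventions
-----------
* Rows are parasite species, columns are individual hosts.
* All entropies use natural logarithms by default (``base`` switches).
* Rows or columns with zero totals are ignored (never an error) inside
  the order-sensitive metrics (WNODF, H2', d'); connectance and degree
  use the matrix dimensions as given, so the identity
  ``mean(degree) = connectance * n_species`` is exact on any input.
  Excluding uninfected hosts is an explicit upstream step
  (:func:`oxynet.data_model.drop_uninfected_hosts`), never implicit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import InteractionMatrix

__all__ = [
    "NetworkMetrics",
    "HostMetrics",
    "connectance",
    "host_degrees",
    "interaction_diversity",
    "wnodf",
    "h2prime",
    "dprime_hosts",
    "network_metrics",
    "host_metrics",
    "greedy_min_entropy",
]


@dataclass(frozen=True)
class NetworkMetrics:
    wnodf: float
    connectance: float
    interaction_diversity: float
    h2prime: float
    n_hosts: int
    n_species: int
    n_links: int

    def as_dict(self) -> dict:
        return {
            "wnodf": self.wnodf,
            "connectance": self.connectance,
            "interaction_diversity": self.interaction_diversity,
            "h2prime": self.h2prime,
            "n_hosts": self.n_hosts,
            "n_species": self.n_species,
            "n_links": self.n_links,
        }


@dataclass(frozen=True)
class HostMetrics:
    host_ids: tuple[str, ...]
    degree: np.ndarray
    dprime: np.ndarray

    def as_dict(self) -> dict:
        return {
            "host_ids": list(self.host_ids),
            "degree": self.degree.tolist(),
            "dprime": self.dprime.tolist(),
        }


def connectance(m: InteractionMatrix) -> float:
    """Proportion of realized links among all possible species x host links.

    ``(# cells with a_ij > 0) / (n_species * n_hosts)`` over the matrix as
    given, so ``connectance = mean(host degree) / n_species`` exactly.
    """
    if m.counts.size == 0 or m.counts.sum() == 0:
        raise ValueError("empty matrix: no links")
    return float((m.counts > 0).sum() / m.counts.size)


def host_degrees(m: InteractionMatrix) -> np.ndarray:
    """Number of parasite species infecting each host (per-column)."""
    return (m.counts > 0).sum(axis=0)


def interaction_diversity(m: InteractionMatrix, base: float = math.e) -> float:
    """Shannon entropy of the link-weight distribution across the network.

    0 for a single link, at most ``log(n_links)``.
    """
    total = m.counts.sum()
    if total == 0:
        raise ValueError("zero-total matrix has no interaction diversity")
    p = m.counts[m.counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def _sort_by_totals(counts: np.ndarray) -> np.ndarray:
    """Rows and columns in decreasing marginal-total order, ties by index."""
    r = np.argsort(-counts.sum(axis=1), kind="stable")
    c = np.argsort(-counts.sum(axis=0), kind="stable")
    return counts[np.ix_(r, c)]


def _wnodf_axis(a: np.ndarray) -> float:
    """Sum of pair scores down the rows of an already-sorted matrix.

    A pair (upper u, lower l) scores 0 unless the lower row's total is
    strictly smaller (decreasing fill); otherwise 100 times the fraction of
    the lower row's occupied positions where the weight is positive but
    strictly below the upper row's (weighted overlap).
    """
    totals = a.sum(axis=1)
    npos = (a > 0).sum(axis=1)
    score = 0.0
    for u in range(a.shape[0] - 1):
        for l in range(u + 1, a.shape[0]):
            if totals[l] >= totals[u] or npos[l] == 0:
                continue
            overlap = np.count_nonzero((a[l] > 0) & (a[l] < a[u]))
            score += 100.0 * overlap / npos[l]
    return score


def wnodf(m: InteractionMatrix) -> float:
    """Weighted nestedness based on overlap and decreasing fill (0-100).

    Rows and columns are sorted internally by decreasing totals, so the
    result is invariant to input permutations.  Rows/columns with zero
    totals are dropped; each axis needs at least two non-empty members to
    contribute pairs, and a matrix degenerate on both axes is an error.
    """
    counts = m.counts
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    r, s = counts.shape
    if r < 2 and s < 2:
        raise ValueError("matrix degenerate on both axes: no pairs to score")
    a = _sort_by_totals(counts)
    pairs = r * (r - 1) // 2 + s * (s - 1) // 2
    return (_wnodf_axis(a) + _wnodf_axis(a.T)) / pairs


def greedy_min_entropy(row_totals: np.ndarray, col_totals: np.ndarray) -> float:
    """Entropy (nats) of the maximally concentrated matrix with given marginals.

    Deterministic greedy packing: repeatedly allocate ``min(row, col)`` to
    the cell of the largest remaining row and column totals.
    """
    r = np.asarray(row_totals, dtype=float).copy()
    c = np.asarray(col_totals, dtype=float).copy()
    total = r.sum()
    if not math.isclose(total, c.sum(), rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("row and column totals must agree")
    ent = 0.0
    while True:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        alloc = min(r[i], c[j])
        if alloc <= 0:
            break
        p = alloc / total
        ent -= p * math.log(p)
        r[i] -= alloc
        c[j] -= alloc
    return ent


def h2prime(m: InteractionMatrix, base: float = math.e) -> float:
    """Network-level specialization index ``H2'`` in [0, 1].

    Standardizes the observed interaction entropy ``H2`` between the
    maximum attainable under the observed marginals (the independence
    expectation, outer product of marginal shares) and the minimum
    (greedy maximal concentration):

        H2' = (H2max - H2) / (H2max - H2min)

    0 at independence (opportunistic partner use), 1 at maximal
    concentration given the marginals.
    """
    counts = m.counts
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0:
        raise ValueError("zero-total matrix")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        warnings.warn("H2' undefined for a single row/column; returning 0")
        return 0.0
    total = counts.sum()
    p = counts[counts > 0] / total
    h2 = float(-(p * np.log(p)).sum())
    r = counts.sum(axis=1) / total
    c = counts.sum(axis=0) / total
    # entropy of the outer product r x c separates into H(r) + H(c)
    h2max = float(-(r * np.log(r)).sum() - (c * np.log(c)).sum())
    h2min = greedy_min_entropy(counts.sum(axis=1), counts.sum(axis=0))
    if math.isclose(h2max, h2min, rel_tol=1e-12, abs_tol=1e-12):
        warnings.warn("H2max == H2min: single feasible configuration, H2' set to 0")
        return 0.0
    value = (h2max - h2) / (h2max - h2min)
    return float(min(1.0, max(0.0, value)))


def dprime_hosts(m: InteractionMatrix) -> np.ndarray:
    """Bluethgen's ``d'`` per host: exclusiveness of its parasite spectrum.

    For host *j* with burden ``A_j`` out of the network total ``A``:

        d_j  = sum_i p'_ij * ln(p'_ij / q_i)
        d'_j = d_j / ln(A / A_j)

    where ``p'_ij`` are the host's conditional interaction shares and
    ``q_i`` the species' availabilities (row shares).  ``d_j`` is the KL
    divergence of partner use from availability (0 at proportional use);
    ``ln(A/A_j)`` is its feasible maximum, attained when the host
    monopolizes a partner no commoner than itself.  Hosts with zero burden
    get NaN with a warning.
    """
    counts = m.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("zero-total matrix")
    q = counts.sum(axis=1) / total
    out = np.full(m.n_hosts, np.nan)
    for j in range(m.n_hosts):
        aj = counts[:, j].sum()
        if aj == 0:
            continue
        pj = counts[:, j] / aj
        pos = pj > 0
        d = float((pj[pos] * np.log(pj[pos] / q[pos])).sum())
        dmax = math.log(total / aj)
        out[j] = 0.0 if dmax == 0 else min(1.0, max(0.0, d / dmax))
    if np.isnan(out).any():
        warnings.warn("hosts with zero burden excluded from d' (NaN)")
    return out


def network_metrics(m: InteractionMatrix) -> NetworkMetrics:
    """All network-level statistics of one habitat matrix."""
    return NetworkMetrics(
        wnodf=float(wnodf(m)),
        connectance=connectance(m),
        interaction_diversity=interaction_diversity(m),
        h2prime=h2prime(m),
        n_hosts=m.n_hosts,
        n_species=m.n_species,
        n_links=int((m.counts > 0).sum()),
    )


def host_metrics(m: InteractionMatrix) -> HostMetrics:
    """Node-level statistics (degree, d') for each host column."""
    return HostMetrics(
        host_ids=m.host_ids,
        degree=host_degrees(m),
        dprime=dprime_hosts(m),
    )
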