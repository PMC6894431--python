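"""Study-shaped synthetic data with known ground truth.

Emulates the field design end to end: three habitat-loss levels with
26/20/20 sampled tortoises, a 14-species oxyurid pool of which 13 occur
per habitat, worm counts spanning zero to the low thousands with a
log-series-like abundance decay, a nested infection structure, and a
habitat-dependent association between individual growth rate and
infestation (positive at low habitat loss, absent at intermediate,
negative at high).  All randomness flows through one
``numpy.random.Generator`` seeded from the config, so every artifact is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import HostRecord, InteractionMatrix, StudyDataset
from .growth import params_for_sex, predict_length

__all__ = ["SyntheticConfig", "simulate_network", "simulate_hosts", "simulate_study"]

#: The oxyurid species pool (Pharyngodonidae of Testudo graeca).
SPECIES_POOL = (
    "T_dentata",
    "T_longicollis",
    "T_macrolaimus",
    "T_conica",
    "T_pusilla",
    "T_numidica",
    "T_robusta",
    "T_setosa",
    "T_palearticus",
    "T_seurati",
    "A_numidica",
    "M_stylosa",
    "M_uncinata",
    "M_microstoma",
)

#: Stage/sex composition per habitat: (stage, sex, count), mirroring the
#: sampled panel (adult females/males recorded, younger stages unsexed).
DEFAULT_COMPOSITION = {
    "low": (("adult", "female", 14), ("adult", "male", 7),
            ("subadult", "unknown", 4), ("juvenile", "unknown", 1)),
    "intermediate": (("adult", "female", 3), ("adult", "male", 6),
                     ("subadult", "unknown", 7), ("juvenile", "unknown", 4)),
    "high": (("adult", "female", 9), ("adult", "male", 4),
             ("subadult", "unknown", 5), ("juvenile", "unknown", 2)),
}

#: One species missing per habitat (13 of the 14-species pool occur in each).
DEFAULT_ABSENT = {"low": "T_seurati", "intermediate": "T_seurati",
                  "high": "T_palearticus"}

_AGE_BANDS = {"adult": (9, 25), "subadult": (5, 8), "juvenile": (1, 4)}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_species: int = 14
    target_connectance: float = 0.31
    nestedness_strength: float = 0.7      # nu in [0, 1]
    noise: float = 0.05                   # cell flip / species swap probability
    abundance_decay: float = 0.9          # geometric decay of cell weights
    count_scale: float = 1500.0           # top-of-range cell count
    count_sigma: float = 0.8              # lognormal spread of cell counts
    mean_k: float = 0.12                  # growth-rate score, per year
    sd_k: float = 0.03
    growth_slopes: dict = field(
        default_factory=lambda: {"low": 1.5, "intermediate": 0.0, "high": -1.5}
    )                                     # log-richness per SD of k
    base_log_richness: float = math.log(3.0)
    zero_inflation: float = 0.28          # fraction of hosts free of adult worms
    prevalence_link: float = 1.0          # logit-prevalence change per b_h * SD of k
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    absent_species: dict = field(default_factory=lambda: dict(DEFAULT_ABSENT))
    seed: int = 20100315

    def __post_init__(self) -> None:
        if not 0 < self.target_connectance <= 1:
            raise ValueError("target_connectance must be in (0, 1]")
        if not 0 <= self.nestedness_strength <= 1:
            raise ValueError("nestedness_strength must be in [0, 1]")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def n_hosts(self, habitat: str) -> int:
        return sum(c for _, _, c in self.composition[habitat])


def _weights_along_gradient(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """``n`` positive integer weights, strictly decreasing.

    Heavy-tailed (lognormal around a geometric decay), sorted so the first
    (most 'core') cell is the largest; a strictly decreasing integer ramp
    is added so no two weights tie, which keeps a noiseless nested template
    perfectly nested in the weighted sense.
    """
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    base = cfg.count_scale * cfg.abundance_decay ** np.arange(n, dtype=float)
    vals = base * np.exp(cfg.count_sigma * rng.standard_normal(n))
    vals = np.sort(vals)[::-1]
    return np.maximum(1, vals.astype(np.int64)) + np.arange(n - 1, -1, -1)


def simulate_network(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_species: int | None = None,
    n_hosts: int | None = None,
    habitat: str = "low",
) -> InteractionMatrix:
    """One weighted bipartite matrix with tunable nestedness.

    The binary skeleton interpolates between a uniform random graph
    (``nu = 0``) and a perfectly nested threshold template (``nu = 1``);
    each cell is then flipped with probability ``noise``.  The flip is
    compensated in the base fill so the expected connectance equals the
    target.  Positive cells receive strictly decreasing heavy-tailed
    weights along the nesting gradient, so ``nu = 1, noise = 0`` yields
    WNODF = 100 exactly.
    """
    if rng is None:
        rng = cfg.rng()
    R = n_species if n_species is not None else cfg.n_species
    S = n_hosts if n_hosts is not None else cfg.n_hosts(habitat)
    nu, eps, target = cfg.nestedness_strength, cfg.noise, cfg.target_connectance
    if target >= 1.0 and nu > 0:
        raise ValueError("a nested template cannot realize full fill")
    base = (target - eps) / (1.0 - 2.0 * eps)
    if not 0 < base <= 1:
        raise ValueError(f"target connectance {target} infeasible at noise {eps}")
    # nesting gradient: small = core (generalist x generalist) corner
    grad = (np.arange(R)[:, None] + 0.5) / R + (np.arange(S)[None, :] + 0.5) / S
    order = np.argsort(grad, axis=None, kind="stable")
    n_template = int(round(base * R * S))
    template = np.zeros(R * S)
    template[order[:n_template]] = 1.0
    template = template.reshape(R, S)
    if nu < 1.0:
        p_uniform = (base - nu * n_template / (R * S)) / (1.0 - nu)
        p = nu * template + (1.0 - nu) * np.clip(p_uniform, 0.0, 1.0)
    else:
        p = template
    skeleton = rng.random((R, S)) < p
    if eps > 0:
        skeleton ^= rng.random((R, S)) < eps
    counts = np.zeros((R, S), dtype=np.int64)
    flat_idx = order[np.asarray(skeleton).ravel()[order]]
    weights = _weights_along_gradient(flat_idx.size, cfg, rng)
    # at nu < 1 the weight ordering is only partially tied to the gradient:
    # a (1 - nu) fraction of assignments is shuffled, so nu = 0 carries no
    # weighted structure beyond the skeleton and nu = 1 stays exact
    n_shuffle = int(round((1.0 - nu) * weights.size))
    if n_shuffle > 1:
        pos = rng.choice(weights.size, n_shuffle, replace=False)
        weights[pos] = rng.permutation(weights[pos])
    counts.ravel()[flat_idx] = weights
    species_ids = (
        tuple(SPECIES_POOL[:R]) if R <= len(SPECIES_POOL)
        else tuple(f"sp{i + 1:02d}" for i in range(R))
    )
    return InteractionMatrix(
        species_ids=species_ids,
        host_ids=tuple(f"{habitat[0].upper()}{j + 1:02d}" for j in range(S)),
        counts=counts,
        habitat=habitat,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    while np.any(out <= low):
        bad = out <= low
        out[bad] = rng.normal(mean, sd, bad.sum())
    return out


def simulate_hosts(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[HostRecord]:
    """Host panels per habitat: stages, ages, growth rates, sizes.

    Ages are drawn uniformly within stage bands (adult 9-25 y, subadult
    5-8 y, juvenile 1-4 y), each host gets a growth-rate score ``k`` from
    a truncated normal, carapace length follows the growth curve at that
    age and rate, and weight is allometric in length (cubic) with
    lognormal noise.
    """
    if rng is None:
        rng = cfg.rng()
    hosts: list[HostRecord] = []
    for habitat in cfg.composition:
        idx = 0
        for stage, sex, count in cfg.composition[habitat]:
            lo, hi = _AGE_BANDS[stage]
            for _ in range(count):
                idx += 1
                age = int(rng.integers(lo, hi + 1))
                k = float(_truncated_normal(rng, cfg.mean_k, cfg.sd_k, 0.005, 1)[0])
                params = params_for_sex(sex)
                length = predict_length(age, k, params)
                weight = 2.3e-4 * length**3 * float(np.exp(0.15 * rng.standard_normal()))
                hosts.append(
                    HostRecord(
                        host_id=f"{habitat[0].upper()}{idx:02d}",
                        habitat=habitat,
                        stage=stage,
                        sex=sex,
                        age_years=age,
                        weight_g=weight,
                        carapace_mm=length,
                        growth_rate_k=k,
                    )
                )
    return hosts


def simulate_study(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> StudyDataset:
    """Full synthetic study: hosts, infection burdens, habitat matrices.

    Per-host infestation couples to the growth-rate score ``k`` through
    both prevalence and intensity, with the same habitat-specific sign:
    ``logit P(infected) = logit(1 - zero_inflation) + prevalence_link * b_h * z``
    and ``log E[richness | infected] = base + b_h * z`` for standardized
    ``z = (k - mean_k)/sd_k``, so the configured slope ``b_h`` is the
    ground-truth growth-rate -> infestation association (positive, zero or
    negative by habitat).  Infected hosts receive the top-ranked
    species of their habitat's 13-species pool (occasionally swapped for a
    random rarer one with probability ``noise``), which yields the nested
    structure; cell counts decay geometrically with species rank under
    heavy lognormal noise, spanning the observed dynamic range.

    Ground-truth parameters travel in ``StudyDataset.metadata``.
    """
    if rng is None:
        rng = cfg.rng()
    hosts = simulate_hosts(cfg, rng)
    matrices: dict[str, InteractionMatrix] = {}
    for habitat in cfg.composition:
        pool = [s for s in SPECIES_POOL[: cfg.n_species]
                if s != cfg.absent_species.get(habitat)]
        panel = [h for h in hosts if h.habitat == habitat]
        b = cfg.growth_slopes[habitat]
        counts = np.zeros((len(pool), len(panel)), dtype=np.int64)
        logit_base = math.log((1 - cfg.zero_inflation) / cfg.zero_inflation)
        for j, h in enumerate(panel):
            z = (h.growth_rate_k - cfg.mean_k) / cfg.sd_k
            eta = logit_base + cfg.prevalence_link * b * z
            p_infected = 1.0 / (1.0 + math.exp(-eta))
            if rng.random() >= p_infected:
                continue
            lam = math.exp(cfg.base_log_richness + b * z)
            r = int(rng.poisson(lam))
            r = max(1, min(r, len(pool)))
            chosen = set(range(r))
            for s in list(chosen):
                if rng.random() < cfg.noise:
                    others = [i for i in range(len(pool)) if i not in chosen]
                    if others:
                        chosen.discard(s)
                        chosen.add(int(rng.choice(others)))
            for i in sorted(chosen):
                scale = cfg.count_scale * cfg.abundance_decay ** (3.0 * i)
                c = scale * math.exp(cfg.count_sigma * rng.standard_normal())
                counts[i, j] = max(1, int(c))
        m = InteractionMatrix(
            species_ids=tuple(pool),
            host_ids=tuple(h.host_id for h in panel),
            counts=counts,
            habitat=habitat,
        )
        for j, h in enumerate(panel):
            h.per_species_counts = {
                pool[i]: int(counts[i, j]) for i in range(len(pool)) if counts[i, j] > 0
            }
        matrices[habitat] = m
    meta = {"generator": "oxynet.synthetic_data.simulate_study",
            "config": asdict(cfg)}
    return StudyDataset(hosts=hosts, matrices=matrices, metadata=meta)
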