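"""Domain types and CSV readers/writers for host-parasite interaction data.

The central object is the weighted bipartite adjacency matrix ``A`` with
``a_ij`` = number of adult worms of oxyurid species *i* counted in the
faecal sample of individual tortoise *j*.  Rows are always parasite
species (the "lower" trophic level), columns are always individual hosts
(the "higher" level); every metric in :mod:`oxynet.network_metrics`
documents which axis it aggregates over.

Host trait tables carry one row per sampled tortoise: habitat-loss level,
life stage, sex, ring-estimated age, body weight, carapace length and
(optionally) per-species worm counts.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HABITAT_LEVELS",
    "STAGES",
    "InteractionMatrix",
    "HostRecord",
    "StudyDataset",
    "MatrixParseError",
    "SchemaError",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_host_table",
    "write_host_table",
    "drop_uninfected_hosts",
    "write_metrics_report",
    "read_metrics_report",
]

#: Habitat-loss levels in their natural (ordinal) order.
HABITAT_LEVELS = ("low", "intermediate", "high")

#: Life stages, oldest first.  Age bands: adult > 8 y, subadult 5-8 y,
#: juvenile 1-4 y.
STAGES = ("adult", "subadult", "juvenile")

SEXES = ("female", "male", "unknown")


class MatrixParseError(ValueError):
    """A cell or label in an interaction-matrix CSV failed validation."""


class SchemaError(ValueError):
    """A trait table is missing required columns or uses unknown tokens."""


def _normalize_token(value: object, allowed: Sequence[str], what: str) -> str:
    token = str(value).strip().lower()
    if token not in allowed:
        raise SchemaError(f"unknown {what} {value!r}; expected one of {list(allowed)}")
    return token


@dataclass(frozen=True)
class InteractionMatrix:
    """Weighted bipartite host x parasite-species adjacency matrix.

    Parameters
    ----------
    species_ids :
        Row labels (parasite species), unique, in file/generation order.
    host_ids :
        Column labels (individual hosts), unique.
    counts :
        Non-negative integer array of shape ``(n_species, n_hosts)``.
    habitat :
        Habitat-loss level this matrix belongs to (``low``/``intermediate``/
        ``high``).
    """

    species_ids: tuple[str, ...]
    host_ids: tuple[str, ...]
    counts: np.ndarray
    habitat: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise MatrixParseError("counts must be a 2-D array")
        if counts.shape != (len(self.species_ids), len(self.host_ids)):
            raise MatrixParseError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.host_ids)} hosts"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise MatrixParseError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise MatrixParseError(
                f"negative count at species {self.species_ids[i]!r}, "
                f"host {self.host_ids[j]!r}"
            )
        for axis_name, labels in (("species", self.species_ids), ("host", self.host_ids)):
            if len(set(labels)) != len(labels):
                dupes = sorted({x for x in labels if list(labels).count(x) > 1})
                raise MatrixParseError(f"duplicated {axis_name} labels: {dupes}")
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        object.__setattr__(self, "host_ids", tuple(str(h) for h in self.host_ids))
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(
            self, "habitat", _normalize_token(self.habitat, HABITAT_LEVELS, "habitat")
        )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_hosts(self) -> int:
        return len(self.host_ids)

    def host_totals(self) -> np.ndarray:
        """Per-host worm burden (column sums)."""
        return self.counts.sum(axis=0)

    def species_totals(self) -> np.ndarray:
        """Per-species abundance across hosts (row sums)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.species_ids), columns=list(self.host_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, habitat: str) -> "InteractionMatrix":
        return cls(
            species_ids=tuple(str(i) for i in df.index),
            host_ids=tuple(str(c) for c in df.columns),
            counts=df.to_numpy(),
            habitat=habitat,
        )


@dataclass
class HostRecord:
    """One sampled tortoise: habitat, life stage, traits and infestation."""

    host_id: str
    habitat: str
    stage: str
    sex: str
    age_years: float
    weight_g: float
    carapace_mm: float
    growth_rate_k: float | None = None
    per_species_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.host_id = str(self.host_id)
        self.habitat = _normalize_token(self.habitat, HABITAT_LEVELS, "habitat")
        self.stage = _normalize_token(self.stage, STAGES, "stage")
        self.sex = _normalize_token(self.sex, SEXES, "sex")
        for name in ("age_years", "weight_g", "carapace_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise SchemaError(f"{name} must be positive for host {self.host_id!r}, got {v!r}")
        if not _stage_consistent(self.stage, self.age_years):
            raise SchemaError(
                f"host {self.host_id!r}: stage {self.stage!r} inconsistent with "
                f"age {self.age_years} (adult > 8 y, subadult 5-8 y, juvenile 1-4 y)"
            )
        if self.growth_rate_k is not None and self.growth_rate_k < 0:
            raise SchemaError(
                f"host {self.host_id!r}: growth_rate_k must be non-negative"
            )

    @property
    def richness(self) -> int:
        """Number of oxyurid species with a positive adult count."""
        return sum(1 for v in self.per_species_counts.values() if v > 0)

    @property
    def abundance(self) -> int:
        """Total adult worm burden (eggs/larvae excluded)."""
        return int(sum(self.per_species_counts.values()))


def _stage_consistent(stage: str, age: float) -> bool:
    if stage == "adult":
        return age > 8
    if stage == "subadult":
        return 5 <= age <= 8
    return 1 <= age < 5


@dataclass
class StudyDataset:
    """Full study: trait records plus one interaction matrix per habitat."""

    hosts: list[HostRecord]
    matrices: dict[str, InteractionMatrix]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {h.host_id: h for h in self.hosts}
        for habitat, m in self.matrices.items():
            if m.habitat != habitat:
                raise SchemaError(
                    f"matrix keyed {habitat!r} carries habitat label {m.habitat!r}"
                )
            missing = [hid for hid in m.host_ids if hid not in known]
            if missing:
                raise SchemaError(
                    f"hosts {missing} in {habitat} matrix are absent from the trait table"
                )
            mismatched = [
                hid for hid in m.host_ids if known[hid].habitat != habitat
            ]
            if mismatched:
                raise SchemaError(
                    f"hosts {mismatched} in {habitat} matrix belong to another habitat"
                )

    def hosts_in(self, habitat: str, stage: str | None = None) -> list[HostRecord]:
        sel = [h for h in self.hosts if h.habitat == habitat]
        if stage is not None:
            sel = [h for h in sel if h.stage == stage]
        return sel

    def to_host_frame(self) -> pd.DataFrame:
        """Trait table as a DataFrame, one row per host."""
        rows = []
        for h in self.hosts:
            rows.append(
                {
                    "host_id": h.host_id,
                    "habitat": h.habitat,
                    "stage": h.stage,
                    "sex": h.sex,
                    "age_years": h.age_years,
                    "weight_g": h.weight_g,
                    "carapace_mm": h.carapace_mm,
                    "growth_rate_k": h.growth_rate_k,
                    "richness": h.richness,
                    "abundance": h.abundance,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_interaction_matrix(
    path: str | Path, habitat: str, transposed: bool = False
) -> InteractionMatrix:
    """Read a species x host count matrix from CSV.

    The expected layout has a header row of host ids and a first column of
    species names.  ``transposed=True`` accepts the flipped layout (hosts as
    rows) and transposes it back.  All-zero rows or columns are preserved:
    presence in the file is authoritative, metrics decide what to ignore.
    """
    df = pd.read_csv(path, index_col=0)
    if transposed:
        df = df.T
    arr = np.empty(df.shape, dtype=np.int64)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            v = values[i, j]
            try:
                fv = float(v)
                if not float(fv).is_integer():
                    raise ValueError
                iv = int(fv)
            except (TypeError, ValueError):
                raise MatrixParseError(
                    f"non-integer cell {v!r} at species {df.index[i]!r}, "
                    f"host {df.columns[j]!r} in {path}"
                ) from None
            if iv < 0:
                raise MatrixParseError(
                    f"negative cell {v!r} at species {df.index[i]!r}, "
                    f"host {df.columns[j]!r} in {path}"
                )
            arr[i, j] = iv
    return InteractionMatrix(
        species_ids=tuple(str(s) for s in df.index),
        host_ids=tuple(str(h) for h in df.columns),
        counts=arr,
        habitat=habitat,
    )


def write_interaction_matrix(m: InteractionMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path, index_label="species")


_REQUIRED_HOST_COLUMNS = (
    "host_id",
    "habitat",
    "stage",
    "sex",
    "age_years",
    "weight_g",
    "carapace_mm",
)
_OPTIONAL_HOST_COLUMNS = ("growth_rate_k",)


def read_host_table(path: str | Path) -> list[HostRecord]:
    """Read a tortoise trait table from CSV into typed records.

    Required columns: ``host_id, habitat, stage, sex, age_years, weight_g,
    carapace_mm``.  ``growth_rate_k`` is optional, and any column whose name
    starts with ``count:`` is taken as a per-species worm count (species name
    after the prefix).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_HOST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait table {path} missing required columns {missing}")
    count_cols = [c for c in df.columns if str(c).startswith("count:")]
    records = []
    for _, row in df.iterrows():
        counts = {c[len("count:"):]: int(row[c]) for c in count_cols}
        k = row.get("growth_rate_k")
        records.append(
            HostRecord(
                host_id=row["host_id"],
                habitat=row["habitat"],
                stage=row["stage"],
                sex=row["sex"],
                age_years=float(row["age_years"]),
                weight_g=float(row["weight_g"]),
                carapace_mm=float(row["carapace_mm"]),
                growth_rate_k=None if k is None or pd.isna(k) else float(k),
                per_species_counts=counts,
            )
        )
    return records


def write_host_table(hosts: Iterable[HostRecord], path: str | Path) -> None:
    hosts = list(hosts)
    species = sorted({s for h in hosts for s in h.per_species_counts})
    rows = []
    for h in hosts:
        row = {
            "host_id": h.host_id,
            "habitat": h.habitat,
            "stage": h.stage,
            "sex": h.sex,
            "age_years": h.age_years,
            "weight_g": h.weight_g,
            "carapace_mm": h.carapace_mm,
            "growth_rate_k": h.growth_rate_k,
        }
        for s in species:
            row[f"count:{s}"] = h.per_species_counts.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def drop_uninfected_hosts(m: InteractionMatrix) -> InteractionMatrix:
    """Remove hosts (columns) carrying no adult worms.

    Only infected individuals enter the network analysis; species rows are
    retained even if they become all-zero, and the original ordering is kept.
    Idempotent.  Raises ``ValueError`` if no host is infected.
    """
    keep = m.host_totals() > 0
    if not keep.any():
        raise ValueError("no infected hosts: every column total is zero")
    return InteractionMatrix(
        species_ids=m.species_ids,
        host_ids=tuple(h for h, k in zip(m.host_ids, keep) if k),
        counts=m.counts[:, keep],
        habitat=m.habitat,
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_metrics_report(
    results: Mapping,
    path: str | Path,
    seed: int | None = None,
    n_replicates: int | None = None,
) -> None:
    """Serialize a nested metric mapping to JSON with run metadata."""
    payload = {
        "metadata": {
            "package": "oxynet",
            "seed": seed,
            "n_replicates": n_replicates,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metrics_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())["results"]
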