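"""Record/data-set model and delimited-text I/O for per-plant biomass tables.

A :class:`BiomassRecord` holds the dry masses of the three organ
compartments (leaf, stem, root, in grams) together with taxonomic and
functional-group annotations.  A :class:`DataSet` is an ordered, id-unique
collection of records with free-text provenance.  Reading, validation and
writing all go through a configurable :class:`Dialect` so that differently
laid-out source tables can be adapted without code changes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, RowValidationError

__all__ = [
    "GROUP_VOCABULARY",
    "GROWTH_FORMS",
    "BiomassRecord",
    "DataSet",
    "Dialect",
    "ValidationReport",
    "read_dataset",
    "write_dataset",
    "filter_records",
    "FilterResult",
    "flag_sma_outliers",
]

#: Controlled vocabulary for functional-group labels.
GROUP_VOCABULARY = frozenset(
    {
        "evergreen",
        "deciduous",
        "gymnosperm",
        "angiosperm",
        "monocot",
        "eudicot",
        "graminoid",
        "C3",
        "C4",
        "annual",
        "perennial",
        "palm",
    }
)

GROWTH_FORMS = ("woody", "herbaceous")

# Pairs of labels that cannot co-occur on one record.
_EXCLUSIVE_PAIRS = (
    frozenset({"evergreen", "deciduous"}),
    frozenset({"C3", "C4"}),
    frozenset({"annual", "perennial"}),
)


@dataclass(frozen=True)
class BiomassRecord:
    """One plant (or per-harvest mean): organ dry masses in grams plus labels."""

    record_id: str
    species: str
    leaf_mass: float
    stem_mass: float
    root_mass: float
    family: str = ""
    growth_form: str = ""
    group_labels: frozenset = frozenset()
    source_id: str = ""

    def __post_init__(self):
        for organ in ("leaf_mass", "stem_mass", "root_mass"):
            value = getattr(self, organ)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{organ} must be finite and > 0, got {value!r}")
        if self.growth_form and self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth_form {self.growth_form!r}")
        labels = frozenset(self.group_labels)
        object.__setattr__(self, "group_labels", labels)
        unknown = labels - GROUP_VOCABULARY
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        for pair in _EXCLUSIVE_PAIRS:
            if len(labels & pair) > 1:
                raise ValueError(f"mutually exclusive labels: {sorted(pair)}")

    @property
    def total_mass(self) -> float:
        return self.leaf_mass + self.stem_mass + self.root_mass


class DataSet:
    """Ordered collection of :class:`BiomassRecord` with unique ids."""

    def __init__(self, records: Iterable[BiomassRecord], provenance: str = ""):
        self.records: tuple[BiomassRecord, ...] = tuple(records)
        self.provenance = provenance
        seen = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BiomassRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, DataSet) and self.records == other.records

    # -- array views -----------------------------------------------------

    def organ_mass(self, organ: str) -> np.ndarray:
        """Vector of dry masses (g) for ``organ`` in {'leaf','stem','root','total'}."""
        if organ == "total":
            return np.array([r.total_mass for r in self.records], dtype=float)
        if organ not in ("leaf", "stem", "root"):
            raise ConfigError(f"unknown organ {organ!r}")
        return np.array([getattr(r, f"{organ}_mass") for r in self.records], dtype=float)

    def log10_mass(self, organ: str) -> np.ndarray:
        return np.log10(self.organ_mass(organ))

    @property
    def species(self) -> np.ndarray:
        return np.array([r.species for r in self.records], dtype=object)

    @property
    def families(self) -> np.ndarray:
        return np.array([r.family for r in self.records], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "record_id": r.record_id,
                    "species": r.species,
                    "family": r.family,
                    "growth_form": r.growth_form,
                    "group_labels": ";".join(sorted(r.group_labels)),
                    "leaf_mass_g": r.leaf_mass,
                    "stem_mass_g": r.stem_mass,
                    "root_mass_g": r.root_mass,
                    "source_id": r.source_id,
                }
            )
        return pd.DataFrame(rows, columns=_CANONICAL_COLUMNS)


_CANONICAL_COLUMNS = [
    "record_id",
    "species",
    "family",
    "growth_form",
    "group_labels",
    "leaf_mass_g",
    "stem_mass_g",
    "root_mass_g",
    "source_id",
]

_MANDATORY = ("species", "leaf_mass_g", "stem_mass_g", "root_mass_g")


@dataclass
class Dialect:
    """How to interpret a delimited biomass table.

    ``column_map`` maps canonical column names to the names used in the
    file; ``unit_factor`` converts the file's mass unit to grams; with
    ``strict`` any invalid row is fatal, otherwise it is skipped and
    reported.
    """

    delimiter: str = ","
    column_map: Mapping[str, str] = field(default_factory=dict)
    unit_factor: float = 1.0
    strict: bool = True

    def resolve(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ValidationReport:
    """Machine-readable summary of a read/validate pass."""

    path: str
    n_rows: int = 0
    n_accepted: int = 0
    row_errors: list = field(default_factory=list)  # (row_number, message)

    def to_json(self) -> str:
        return json.dumps(
            {
                "path": self.path,
                "n_rows": self.n_rows,
                "n_accepted": self.n_accepted,
                "n_rejected": len(self.row_errors),
                "row_errors": [{"row": r, "error": m} for r, m in self.row_errors],
            },
            indent=2,
            sort_keys=True,
        )

    def to_text(self) -> str:
        lines = [
            f"file: {self.path}",
            f"rows read: {self.n_rows}",
            f"rows accepted: {self.n_accepted}",
            f"rows rejected: {len(self.row_errors)}",
        ]
        lines += [f"  row {r}: {m}" for r, m in self.row_errors]
        return "\n".join(lines)


def read_dataset(path, dialect: Dialect | None = None) -> DataSet:
    """Read a delimited biomass table into a :class:`DataSet`.

    The returned dataset carries the :class:`ValidationReport` of the read
    as a ``validation`` attribute.  Rows with non-numeric or nonpositive
    masses raise :class:`RowValidationError` in strict mode and are skipped
    (and reported) otherwise.  Row numbers are 1-based data rows (the
    header is row 0).
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for canonical in _MANDATORY:
        if dialect.resolve(canonical) not in df.columns:
            raise FormatError(
                f"missing mandatory column {dialect.resolve(canonical)!r} "
                f"(canonical {canonical!r}) in {path}"
            )
    report = ValidationReport(path=str(path), n_rows=len(df))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            records.append(_row_to_record(row, dialect, default_id=str(i)))
        except (ValueError, RowValidationError) as exc:
            if dialect.strict:
                raise RowValidationError(i, str(exc)) from exc
            report.row_errors.append((i, str(exc)))
    report.n_accepted = len(records)
    ds = DataSet(records, provenance=f"read from {path}")
    ds.validation = report
    return ds


def _row_to_record(row: Mapping[str, str], dialect: Dialect, default_id: str) -> BiomassRecord:
    def get(canonical, default=""):
        return str(row.get(dialect.resolve(canonical), default)).strip()

    masses = {}
    for organ in ("leaf", "stem", "root"):
        raw = get(f"{organ}_mass_g")
        try:
            masses[organ] = float(raw) * dialect.unit_factor
        except ValueError:
            raise ValueError(f"non-numeric {organ} mass {raw!r}")
    labels = frozenset(x for x in get("group_labels").split(";") if x)
    return BiomassRecord(
        record_id=get("record_id") or default_id,
        species=get("species"),
        family=get("family"),
        growth_form=get("growth_form"),
        group_labels=labels,
        leaf_mass=masses["leaf"],
        stem_mass=masses["stem"],
        root_mass=masses["root"],
        source_id=get("source_id"),
    )


def write_dataset(ds: DataSet, path, dialect: Dialect | None = None) -> None:
    """Write ``ds`` in the canonical column layout (round-trip exact)."""
    dialect = dialect or Dialect()
    df = ds.to_frame()
    df.columns = [dialect.resolve(c) for c in df.columns]
    # str() of a float is its shortest round-trip repr, so read->write->read
    # reproduces every mass bit-for-bit.
    df.to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# Declarative filtering


@dataclass
class FilterResult:
    dataset: DataSet
    removed: dict  # atom name -> number of records removed by that atom


_ATOMS = ("min_records_per_species", "min_species_per_family", "mass_range", "group_label")


def filter_records(ds: DataSet, predicate: Sequence[tuple] | Mapping) -> FilterResult:
    """Apply inclusion-rule atoms in order; report per-atom removal counts.

    ``predicate`` is a sequence of ``(atom, value)`` pairs (a mapping is
    accepted and iterated in insertion order).  Supported atoms:

    - ``min_records_per_species``: keep species with at least N records;
    - ``min_species_per_family``: keep families with at least N species
      (evaluated on the current, possibly already filtered, set);
    - ``mass_range``: ``(lo, hi)`` in grams on total mass (inclusive);
    - ``group_label``: keep records carrying the given label.
    """
    if isinstance(predicate, Mapping):
        atoms = list(predicate.items())
    else:
        atoms = [tuple(p) for p in predicate]
    records = list(ds.records)
    removed: dict[str, int] = {}
    for atom, value in atoms:
        if atom not in _ATOMS:
            raise ConfigError(f"unknown filter atom {atom!r}; known: {_ATOMS}")
        before = len(records)
        records = _apply_atom(records, atom, value)
        removed[atom] = removed.get(atom, 0) + before - len(records)
    return FilterResult(DataSet(records, provenance=ds.provenance), removed)


def _apply_atom(records, atom, value):
    if atom == "min_records_per_species":
        counts: dict[str, int] = {}
        for r in records:
            counts[r.species] = counts.get(r.species, 0) + 1
        return [r for r in records if counts[r.species] >= int(value)]
    if atom == "min_species_per_family":
        fam_species: dict[str, set] = {}
        for r in records:
            fam_species.setdefault(r.family, set()).add(r.species)
        return [r for r in records if len(fam_species[r.family]) >= int(value)]
    if atom == "mass_range":
        lo, hi = value
        return [r for r in records if lo <= r.total_mass <= hi]
    if atom == "group_label":
        return [r for r in records if value in r.group_labels]
    raise AssertionError(atom)


def flag_sma_outliers(ds: DataSet, y_organ: str, x_organ: str, threshold: float = 4.0) -> list:
    """Diagnostic only: record ids with |studentized SMA residual| > threshold.

    Flagged records are reported, never removed automatically.
    """
    from .allometry import AllometricPair, fit_sma

    pair = AllometricPair.from_dataset(ds, y_organ, x_organ)
    fit = fit_sma(pair)
    resid = pair.y - (fit.a_log + fit.b * pair.x)
    sd = resid.std(ddof=2)
    if sd == 0:
        return []
    flagged = np.abs(resid / sd) > threshold
    return [ds.records[i].record_id for i in np.flatnonzero(flagged)]
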