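"""Repository of measured subjects: feature tables, bounds, and file I/O.

The repository pairs each laboratory-measured subject (a full ICZ model,
stored as JSON) with its five-feature summary row.  The feature rows are
kept in a CSV index with header ``entry_id,F1_N,F2_N,F3_N,F4_N,D1_cm``;
a repository directory holds this index as ``features.csv`` plus
optional ``models/<entry_id>.json`` full models.

Per-feature minima/maxima over the repository rows (the query user is
never included) define the normalization interval R = max - min used by
the similarity statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .core_model import ICZModel, SimplifiedFeatures, load_icz_model, save_icz_model
from .errors import SchemaError, ValidationError

FEATURE_NAMES: tuple[str, ...] = ("f1", "f2", "f3", "f4", "d1")
CSV_COLUMNS: tuple[str, ...] = ("entry_id", "F1_N", "F2_N", "F3_N", "F4_N", "D1_cm")
INDEX_FILENAME = "features.csv"
MODELS_DIRNAME = "models"


@dataclass(frozen=True)
class FeatureTable:
    """Ordered collection of (entry_id, SimplifiedFeatures) rows."""

    rows: tuple[tuple[str, SimplifiedFeatures], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple((str(i), f) for i, f in self.rows))
        ids = [i for i, _ in self.rows]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate entry_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, SimplifiedFeatures]]:
        return iter(self.rows)

    @property
    def entry_ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.rows)

    def get(self, entry_id: str) -> SimplifiedFeatures:
        for i, f in self.rows:
            if i == entry_id:
                return f
        raise KeyError(entry_id)

    def with_row(self, entry_id: str, features: SimplifiedFeatures) -> "FeatureTable":
        """Return a new table with one row appended."""
        return FeatureTable(self.rows + ((entry_id, features),))


@dataclass(frozen=True)
class FeatureBounds:
    """Per-feature min/max over the repository and the interval R = max - min."""

    minima: Mapping[str, float]
    maxima: Mapping[str, float]

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            if name not in self.minima or name not in self.maxima:
                raise ValidationError(f"bounds missing feature {name!r}")
            if self.maxima[name] < self.minima[name]:
                raise ValidationError(
                    f"feature {name}: max {self.maxima[name]} < min {self.minima[name]}"
                )

    def interval(self, name: str) -> float:
        """The normalization interval R for one feature (>= 0)."""
        return self.maxima[name] - self.minima[name]


def compute_feature_bounds(table: FeatureTable) -> FeatureBounds:
    """Column-wise min/max over the repository rows only.

    The prospective user's features are deliberately excluded: the bounds
    describe the population stored in the repository.
    """
    if len(table) == 0:
        raise ValidationError("cannot compute feature bounds of an empty table")
    minima: dict[str, float] = {}
    maxima: dict[str, float] = {}
    for name in FEATURE_NAMES:
        col = [getattr(f, name) for _, f in table]
        minima[name] = min(col)
        maxima[name] = max(col)
    return FeatureBounds(minima=minima, maxima=maxima)


# ---------------------------------------------------------------------------
# CSV / directory persistence
# ---------------------------------------------------------------------------


def _table_to_frame(table: FeatureTable) -> pd.DataFrame:
    return pd.DataFrame(
        [(i, f.f1, f.f2, f.f3, f.f4, f.d1) for i, f in table],
        columns=list(CSV_COLUMNS),
    )


def _frame_to_table(df: pd.DataFrame, source: str) -> FeatureTable:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        raise SchemaError(f"{source}: unexpected column(s) {extra}")
    ids = df["entry_id"].astype(str).tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise SchemaError(f"{source}: duplicate entry_id(s) {dupes}")
    rows: list[tuple[str, SimplifiedFeatures]] = []
    for pos, rec in enumerate(df.itertuples(index=False)):
        vals = {}
        for name, col in zip(FEATURE_NAMES, CSV_COLUMNS[1:]):
            raw = getattr(rec, col)
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{source}: row {pos + 1} (entry_id={rec.entry_id!r}), column {col}: "
                    f"non-numeric value {raw!r}"
                ) from None
            if pd.isna(v):
                raise SchemaError(
                    f"{source}: row {pos + 1} (entry_id={rec.entry_id!r}), column {col}: missing value"
                )
            vals[name] = v
        try:
            feats = SimplifiedFeatures(**vals)
        except ValidationError as e:
            raise ValidationError(
                f"{source}: row {pos + 1} (entry_id={rec.entry_id!r}): {e}"
            ) from e
        rows.append((str(rec.entry_id), feats))
    return FeatureTable(tuple(rows))


def save_repository(
    table: FeatureTable,
    path: str | Path,
    models: Mapping[str, ICZModel] | None = None,
) -> Path:
    """Write a feature table to CSV, or to a repository directory.

    A path ending in ``.csv`` gets the bare index; any other path is
    treated as a directory receiving ``features.csv`` and, when full
    models are supplied, ``models/<entry_id>.json`` files.
    """
    path = Path(path)
    fmt = lambda v: repr(float(v))  # shortest digits that round-trip exactly
    if path.suffix.lower() == ".csv":
        if models:
            raise ValidationError("full models need a repository directory, not a bare CSV")
        _table_to_frame(table).to_csv(path, index=False, float_format=fmt)
        return path
    path.mkdir(parents=True, exist_ok=True)
    _table_to_frame(table).to_csv(path / INDEX_FILENAME, index=False, float_format=fmt)
    if models:
        unknown = set(models) - set(table.entry_ids)
        if unknown:
            raise ValidationError(f"models supplied for unknown entry_id(s) {sorted(unknown)}")
        mdir = path / MODELS_DIRNAME
        mdir.mkdir(exist_ok=True)
        for entry_id, model in models.items():
            save_icz_model(model, mdir / f"{entry_id}.json")
    return path


def load_repository(
    path: str | Path, with_models: bool = False
) -> FeatureTable | tuple[FeatureTable, dict[str, ICZModel]]:
    """Read a feature table from a CSV file or a repository directory.

    With ``with_models=True`` also loads any linked full-model JSON files
    and returns ``(table, {entry_id: ICZModel})``.
    """
    path = Path(path)
    csv_path = path if path.is_file() else path / INDEX_FILENAME
    if not csv_path.exists():
        raise SchemaError(f"no feature table found at {csv_path}")
    try:
        df = pd.read_csv(csv_path, dtype={"entry_id": str}, float_precision="round_trip")
    except Exception as e:  # pandas raises several parser error types
        raise SchemaError(f"{csv_path}: cannot parse CSV ({e})") from e
    table = _frame_to_table(df, str(csv_path))
    if not with_models:
        return table
    models: dict[str, ICZModel] = {}
    mdir = (path if path.is_dir() else path.parent) / MODELS_DIRNAME
    if mdir.is_dir():
        for entry_id in table.entry_ids:
            f = mdir / f"{entry_id}.json"
            if f.exists():
                models[entry_id] = load_icz_model(f)
    return table, models
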