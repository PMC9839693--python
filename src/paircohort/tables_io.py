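"""Typed tabular containers and TSV readers/writers.

The pipeline moves three kinds of tables around: integer sample-by-OTU count
tables, real sample-by-metabolite concentration tables, and a subject/sample
metadata registry. All files are UTF-8, tab-separated, LF-terminated, with a
header row. Count tables additionally accept the mothur "shared" dialect
(columns ``label``, ``Group``, ``numOtus``, then one column per OTU, one row
per sample).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ConcentrationTable",
    "CohortMetadata",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_concentration_table",
    "write_concentration_table",
    "read_metadata",
    "write_metadata",
]

ROLES = frozenset({"patient", "relative", "fd_mouse", "control_mouse"})

REQUIRED_META_COLUMNS = ("sample_id", "subject_id", "family_id", "role", "collection_date")


class ValidationError(ValueError):
    """A table failed structural validation (duplicate ids, bad cell, ...)."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dup}")


@dataclass
class CountTable:
    """Sample-by-feature integer abundance matrix.

    Canonical orientation is samples as rows. ``counts`` is a dense
    nonnegative integer array of shape (n_samples, n_features).
    """

    samples: list[str]
    features: list[str]
    counts: np.ndarray
    feature_taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.features)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        _check_unique(self.samples, "sample")
        _check_unique(self.features, "feature")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=self.features)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_taxonomy=None) -> "CountTable":
        return cls(
            samples=[str(s) for s in df.index],
            features=[str(f) for f in df.columns],
            counts=df.to_numpy(),
            feature_taxonomy=feature_taxonomy,
        )

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountTable(
            samples=[self.samples[i] for i in idx],
            features=list(self.features),
            counts=self.counts[idx, :],
            feature_taxonomy=self.feature_taxonomy,
        )


@dataclass
class ConcentrationTable:
    """Sample-by-metabolite real concentration matrix with per-metabolite units."""

    samples: list[str]
    metabolites: list[str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.metabolites)):
            raise ValidationError("values shape does not match sample/metabolite ids")
        if (self.values < 0).any():
            raise ValidationError("concentrations must be nonnegative")
        _check_unique(self.samples, "sample")
        _check_unique(self.metabolites, "metabolite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.metabolites)


@dataclass
class CohortMetadata:
    """Per-sample registry: subject, family, role, collection date, covariates.

    ``table`` keeps one row per sample. Unknown covariate columns are preserved
    as opaque strings; missing values stay as empty strings, never imputed.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing required column(s): {missing}")
        _check_unique(self.table["sample_id"], "sample")
        bad_roles = set(self.table["role"]) - ROLES
        if bad_roles:
            raise ValidationError(f"unknown role value(s): {sorted(bad_roles)}")
        # one subject per sample is enforced by the sample-id index; also check
        # each sample's subject is a single value (trivially true in a frame)
        self.table = self.table.reset_index(drop=True)
        try:
            self._dates = pd.to_datetime(self.table["collection_date"], format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"unparseable collection_date: {exc}") from exc

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.table["sample_id"]]

    def date_of(self, sample_id: str) -> _dt.date:
        i = self.table.index[self.table["sample_id"] == sample_id][0]
        return self._dates.iloc[i].date()

    def role_of(self, sample_id: str) -> str:
        i = self.table.index[self.table["sample_id"] == sample_id][0]
        return str(self.table["role"].iloc[i])

    def subset(self, mask) -> "CohortMetadata":
        return CohortMetadata(self.table[mask].copy())


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path, dialect: str = "plain_tsv", orientation: str = "samples_as_rows") -> CountTable:
    """Read a count table.

    dialect ``plain_tsv``: header row of feature (or sample) ids, first column
    holds the other axis's ids; ``orientation`` says which axis is on rows.
    dialect ``mothur_shared``: columns label/Group/numOtus then per-OTU counts.
    """
    if dialect == "mothur_shared":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.empty or df.shape[1] < 3:
            raise ValidationError(f"{path}: not a mothur shared file")
        expected = ["label", "Group", "numOtus"]
        if list(df.columns[:3]) != expected:
            raise ValidationError(
                f"{path}: mothur shared header must start with {expected}, got {list(df.columns[:3])}"
            )
        samples = [str(s) for s in df["Group"]]
        features = [str(c) for c in df.columns[3:]]
        counts = _parse_int_block(df.iloc[:, 3:], samples, features, path)
        return CountTable(samples=samples, features=features, counts=counts)
    if dialect != "plain_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: empty count table")
    if orientation == "features_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    samples = [str(s) for s in df.index]
    features = [str(f) for f in df.columns]
    counts = _parse_int_block(df, samples, features, path)
    return CountTable(samples=samples, features=features, counts=counts)


def _parse_int_block(df: pd.DataFrame, rows, cols, path) -> np.ndarray:
    out = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                out[i, j] = int(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-integer count {cell!r} at row {rows[i]!r}, column {cols[j]!r}"
                ) from None
    return out


def write_count_table(t: CountTable, path, dialect: str = "plain_tsv") -> None:
    """Write a count table; round-trips losslessly with read_count_table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if dialect == "mothur_shared":
            fh.write("label\tGroup\tnumOtus\t" + "\t".join(t.features) + "\n")
            for i, s in enumerate(t.samples):
                row = "\t".join(str(c) for c in t.counts[i])
                fh.write(f"0.03\t{s}\t{t.n_features}\t{row}\n")
        elif dialect == "plain_tsv":
            fh.write("sample_id\t" + "\t".join(t.features) + "\n")
            for i, s in enumerate(t.samples):
                fh.write(s + "\t" + "\t".join(str(c) for c in t.counts[i]) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# concentration tables

_UNIT_PREFIX = "#units:"


def read_concentration_table(path) -> ConcentrationTable:
    """Read a concentration TSV; an optional first comment line carries units.

    Unit line format: ``#units:<tab><unit-for-met-1><tab>...`` aligned with the
    metabolite columns of the header that follows.
    """
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        units_fields = None
        if first.startswith(_UNIT_PREFIX):
            units_fields = first.rstrip("\n").split("\t")[1:]
            rest = fh.read()
        else:
            rest = first + fh.read()
    from io import StringIO

    df = pd.read_csv(StringIO(rest), sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty concentration table")
    metabolites = [str(m) for m in df.columns]
    units = {}
    if units_fields is not None:
        if len(units_fields) != len(metabolites):
            raise ValidationError(f"{path}: units line does not align with metabolite columns")
        units = dict(zip(metabolites, units_fields))
    return ConcentrationTable(
        samples=[str(s) for s in df.index],
        metabolites=metabolites,
        values=df.to_numpy(dtype=float),
        units=units,
    )


def write_concentration_table(c: ConcentrationTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if c.units:
            fh.write(_UNIT_PREFIX + "\t" + "\t".join(c.units.get(m, "") for m in c.metabolites) + "\n")
        fh.write("sample_id\t" + "\t".join(c.metabolites) + "\n")
        for i, s in enumerate(c.samples):
            fh.write(s + "\t" + "\t".join(repr(float(v)) for v in c.values[i]) + "\n")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValidationError(f"{path}: empty metadata table")
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path) -> None:
    df = meta.table
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join("" if pd.isna(v) else str(v) for v in row) + "\n")
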