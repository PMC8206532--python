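"""Domain types and table I/O shared by every analysis stage.

The cohort layout follows a fixed 0-based predictor ID scheme: a block of
baseline scores recorded at 24 months (intervention indicator, anthropometric
z-scores, cognitive/language/motor composites), followed by the gut-microbiota
relative-abundance block at 24 months, followed by the block at 36 months.
With the full study layout (7 + 542 + 621 = 1170 predictors) the blocks occupy
IDs 0-6, 7-548 and 549-1169.  Abundances are stored as fractions in [0, 1];
a reader flag converts percentage inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Timepoint",
    "Aerotolerance",
    "TaxonRank",
    "TableSchema",
    "PredictorMatrix",
    "ResponseVector",
    "ModelRecord",
    "TaxonAnnotation",
    "AbundanceTable",
    "DataFormatError",
    "read_predictor_table",
    "read_taxonomy",
    "write_taxonomy",
    "write_model_list",
    "read_model_list",
]


class DataFormatError(ValueError):
    """A malformed input table (duplicate IDs, non-numeric cells, bad schema)."""


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    MICROBIOTA_24M = "microbiota_24m"
    MICROBIOTA_36M = "microbiota_36m"


class Aerotolerance(str, enum.Enum):
    AEROTOLERANT = "aerotolerant"
    STRICT_ANAEROBE = "strict_anaerobe"
    UNKNOWN = "unknown"


class TaxonRank(str, enum.Enum):
    SPECIES = "species"
    SPECIES_GROUP = "species_group"
    GENUS = "genus"


@dataclass(frozen=True)
class TableSchema:
    """Column-mapping configuration for :func:`read_predictor_table`.

    Parameters
    ----------
    response
        Name of the response column (e.g. the 36-month language composite).
    n_baseline, n_asv_24m, n_asv_36m
        Sizes of the three predictor blocks; IDs are assigned contiguously.
    abundance_scale
        ``"fraction"`` (values already in [0, 1]) or ``"percent"`` (divided
        by 100 on ingestion).
    """

    response: str = "language_36m"
    n_baseline: int = 7
    n_asv_24m: int = 542
    n_asv_36m: int = 621
    abundance_scale: str = "fraction"

    def timepoint_of(self, predictor_id: int) -> Timepoint:
        if predictor_id < self.n_baseline:
            return Timepoint.BASELINE
        if predictor_id < self.n_baseline + self.n_asv_24m:
            return Timepoint.MICROBIOTA_24M
        return Timepoint.MICROBIOTA_36M


@dataclass
class PredictorMatrix:
    """Subjects x predictors numeric matrix with the study ID scheme."""

    values: np.ndarray
    predictor_ids: list[int]
    predictor_labels: list[str]
    timepoint_tags: list[Timepoint]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("predictor values must be a 2-D matrix")
        n, t = self.values.shape
        if n < 2 or t < 1:
            raise DataFormatError(f"need N >= 2 subjects and t >= 1 predictors, got {n} x {t}")
        if len(self.predictor_ids) != t or len(self.timepoint_tags) != t:
            raise DataFormatError("metadata length does not match number of columns")
        if len(set(self.predictor_ids)) != t:
            raise DataFormatError("predictor IDs are not unique")
        if not np.isfinite(self.values).all():
            raise DataFormatError("predictor matrix contains missing or non-finite values")
        frac = [
            j
            for j, tag in enumerate(self.timepoint_tags)
            if tag is not Timepoint.BASELINE
        ]
        if frac:
            block = self.values[:, frac]
            if block.min() < -1e-12 or block.max() > 1 + 1e-9:
                raise DataFormatError("abundance columns must lie in [0, 1] (fractions)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.values.shape[1]

    def tag_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tag in self.timepoint_tags:
            out[tag.value] = out.get(tag.value, 0) + 1
        return out

    def column(self, predictor_id: int) -> np.ndarray:
        return self.values[:, self.predictor_ids.index(predictor_id)]

    def subset(self, ids: list[int]) -> "PredictorMatrix":
        idx = [self.predictor_ids.index(i) for i in ids]
        return PredictorMatrix(
            self.values[:, idx],
            [self.predictor_ids[j] for j in idx],
            [self.predictor_labels[j] for j in idx],
            [self.timepoint_tags[j] for j in idx],
        )

    def abundance_table(self, timepoint: Timepoint) -> "AbundanceTable":
        """Slice out one microbiota block as an :class:`AbundanceTable`."""
        idx = [j for j, tag in enumerate(self.timepoint_tags) if tag is timepoint]
        if not idx:
            raise DataFormatError(f"no columns tagged {timepoint.value}")
        return AbundanceTable(self.values[:, idx], [self.predictor_ids[j] for j in idx], timepoint)


@dataclass
class ResponseVector:
    """Per-subject response (the 36-month BSID-III language composite)."""

    values: np.ndarray
    label: str = "language_36m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise DataFormatError("response contains missing or non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ModelRecord:
    """One selected regression model on the standardized scale.

    ``support`` is the set of predictor IDs with non-zero coefficients,
    ``coefficients_std`` the OLS-polished coefficients restricted to that
    support, and ``rss`` the residual sum of squares of the standardized fit.
    ``certified`` is False when a solver time limit expired before optimality
    was proven.
    """

    support: frozenset[int]
    coefficients_std: dict[int, float]
    rss: float
    n_terms: int
    rank_within_size: int = 1
    certified: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.support) != self.n_terms:
            raise ValueError("|support| must equal n_terms")
        if set(self.coefficients_std) != set(self.support):
            raise ValueError("coefficient keys must equal the support")
        if not np.isfinite(self.rss) or self.rss < -1e-9:
            raise ValueError("rss must be finite and non-negative")

    @property
    def sorted_support(self) -> tuple[int, ...]:
        return tuple(sorted(self.support))


@dataclass(frozen=True)
class TaxonAnnotation:
    """ASV-level taxonomic call with BLAST identity and aerotolerance class."""

    asv_id: int
    taxon_name: str
    rank: TaxonRank = TaxonRank.SPECIES
    identity_pct: float = 100.0
    aerotolerance: Aerotolerance = Aerotolerance.UNKNOWN

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise DataFormatError(
                f"identity_pct must lie in [0, 100], got {self.identity_pct} for ASV {self.asv_id}"
            )


@dataclass
class AbundanceTable:
    """Subjects x taxa relative-abundance fractions at one timepoint.

    ``taxa`` holds ASV IDs for sequence-level tables and taxon labels after
    species-level pooling.
    """

    values: np.ndarray
    taxa: list
    timepoint: Timepoint

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.taxa):
            raise DataFormatError("abundance matrix shape does not match taxa list")
        if self.values.min() < -1e-12:
            raise DataFormatError("abundances must be non-negative")
        if (self.values.sum(axis=1) > 1 + 1e-6).any():
            raise DataFormatError("per-subject abundance fractions must sum to <= 1")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# readers / writers


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_predictor_table(
    path, schema: TableSchema | None = None
) -> tuple[PredictorMatrix, ResponseVector, dict]:
    """Ingest a delimited predictor table.

    The header holds integer predictor IDs plus one response column named by
    the schema.  Rows with missing entries are dropped complete-case and
    listed in the returned report.  Returns ``(matrix, response, report)``
    where ``report`` records tag counts and exclusions.
    """
    schema = schema or TableSchema()
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header_line else ","
    header = header_line.split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DataFormatError(f"duplicate predictor IDs in header: {dupes}")
    df = _read_delimited(path)
    if schema.response not in df.columns:
        raise DataFormatError(f"response column {schema.response!r} not found")
    pred_cols = [c for c in df.columns if c != schema.response]
    try:
        ids = [int(c) for c in pred_cols]
    except ValueError as exc:
        raise DataFormatError(f"predictor column headers must be integer IDs: {exc}") from exc
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataFormatError(f"duplicate predictor IDs: {dupes}")

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataFormatError(
                f"non-numeric cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        df[col] = coerced

    complete = df.notna().all(axis=1)
    excluded = df.index[~complete].tolist()
    df = df.loc[complete]
    if len(df) < 2:
        raise DataFormatError("fewer than 2 complete-case subjects after exclusion")

    values = df[pred_cols].to_numpy(dtype=float)
    tags = [schema.timepoint_of(i) for i in ids]
    if schema.abundance_scale == "percent":
        frac = [j for j, tag in enumerate(tags) if tag is not Timepoint.BASELINE]
        values[:, frac] = values[:, frac] / 100.0
    elif schema.abundance_scale != "fraction":
        raise DataFormatError(f"unknown abundance_scale {schema.abundance_scale!r}")

    matrix = PredictorMatrix(values, ids, [str(i) for i in ids], tags)
    response = ResponseVector(df[schema.response].to_numpy(dtype=float), schema.response)
    report = {
        "n_subjects": matrix.n_subjects,
        "excluded_rows": excluded,
        "tag_counts": matrix.tag_counts(),
    }
    return matrix, response, report


_TAX_COLUMNS = ["asv_id", "taxon_name", "rank", "identity_pct", "aerotolerance"]


def read_taxonomy(path) -> list[TaxonAnnotation]:
    """Read a per-ASV taxonomy table; aerotolerance defaults to unknown."""
    df = _read_delimited(path)
    missing = [c for c in _TAX_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise DataFormatError(f"taxonomy table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        aero = Aerotolerance.UNKNOWN
        if "aerotolerance" in df.columns and isinstance(row["aerotolerance"], str):
            aero = Aerotolerance(row["aerotolerance"])
        out.append(
            TaxonAnnotation(
                asv_id=int(row["asv_id"]),
                taxon_name=str(row["taxon_name"]),
                rank=TaxonRank(row["rank"]),
                identity_pct=float(row["identity_pct"]),
                aerotolerance=aero,
            )
        )
    return out


def write_taxonomy(annotations: list[TaxonAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "asv_id": [a.asv_id for a in annotations],
            "taxon_name": [a.taxon_name for a in annotations],
            "rank": [a.rank.value for a in annotations],
            "identity_pct": [a.identity_pct for a in annotations],
            "aerotolerance": [a.aerotolerance.value for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_model_list(models: list[ModelRecord], path) -> None:
    """Write ranked models as TSV: one row per model, lossless round-trip."""
    if not models:
        raise ValueError("model list is empty")
    rows = []
    for m in models:
        ids = m.sorted_support
        rows.append(
            {
                "n_terms": m.n_terms,
                "rank_within_size": m.rank_within_size,
                "rss": repr(float(m.rss)),
                "support": ",".join(str(i) for i in ids),
                "coefficients": ",".join(repr(float(m.coefficients_std[i])) for i in ids),
                "certified": int(m.certified),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_model_list(path) -> list[ModelRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        if row["n_terms"] == 0 or (isinstance(row["support"], float) and np.isnan(row["support"])):
            ids: list[int] = []
            coefs: list[float] = []
        else:
            ids = [int(s) for s in str(row["support"]).split(",")]
            coefs = [float(s) for s in str(row["coefficients"]).split(",")]
        out.append(
            ModelRecord(
                support=frozenset(ids),
                coefficients_std=dict(zip(ids, coefs)),
                rss=float(row["rss"]),
                n_terms=int(row["n_terms"]),
                rank_within_size=int(row["rank_within_size"]),
                certified=bool(int(row.get("certified", 1))),
            )
        )
    return out
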