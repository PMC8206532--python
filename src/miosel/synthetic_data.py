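"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a longitudinal child-cohort layout: a small block of
baseline scores at 24 months (intervention indicator, anthropometric
z-scores, cognitive/language/motor composites normed to mean 100, SD 15,
with language and cognition correlated at 0.7), followed by two zero-inflated
compositional gut-microbiota blocks (relative-abundance fractions at 24 and
36 months).  Abundances are drawn as zero-inflated log-normal intensities
with block-correlated latent factors and closed to per-subject fractions, so
planted regression coefficients act on the fraction scale.  The response is
a sparse linear signal — by default a 0.44 carry-over of the 24-month
language score plus two microbial terms with coefficients 1929 and 417 on
the fraction scale, intercept 57, Gaussian noise SD 12 — so that the planted
terms' signal-to-noise sits in the same range as the fitted model the
pipeline is meant to recover.

Everything is reproducible bit-exactly from ``(CohortSpec, seed)``.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    AbundanceTable,
    Aerotolerance,
    PredictorMatrix,
    ResponseVector,
    TableSchema,
    TaxonAnnotation,
    TaxonRank,
    Timepoint,
    read_predictor_table,
    read_taxonomy,
    write_taxonomy,
)

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "null_cohort", "planted_truth"]

# fraction-scale targets for the planted microbial predictors; chosen so the
# implied t-ratios of the planted terms land in the 4-7 range of a
# well-determined three-term fit at N = 139
_PLANTED_MEAN_24M = 0.002
_PLANTED_MEAN_36M = 0.006


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; defaults follow the full study layout."""

    n_subjects: int = 139
    n_baseline: int = 7
    n_asv_24m: int = 542
    n_asv_36m: int = 621
    zero_inflation: float = 0.35
    block_correlation: float = 0.3
    block_size: int = 10
    log_abundance_spread: float = 1.5  # SD of per-taxon log-mean intensities
    log_abundance_sigma: float = 1.0  # within-taxon log-normal SD
    planted_support: frozenset = frozenset({5, 281, 563})
    planted_coefficients: tuple = ((5, 0.44), (281, 1929.0), (563, 417.0))
    intercept: float = 57.0
    noise_sd: float = 12.0
    species_fraction: float = 0.73  # share of ASVs resolved to species (identity >= 97)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must lie in [0, 1)")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("block_correlation must lie in [0, 1)")
        t = self.n_baseline + self.n_asv_24m + self.n_asv_36m
        coef_ids = {i for i, _ in self.planted_coefficients}
        if coef_ids != set(self.planted_support):
            raise ValueError("planted coefficients must be keyed by the planted support")
        if any(i < 0 or i >= t for i in self.planted_support):
            raise ValueError(f"planted IDs must lie in [0, {t})")

    @property
    def t(self) -> int:
        return self.n_baseline + self.n_asv_24m + self.n_asv_36m

    @property
    def coefficients(self) -> dict[int, float]:
        return dict(self.planted_coefficients)

    def schema(self) -> TableSchema:
        return TableSchema(
            n_baseline=self.n_baseline,
            n_asv_24m=self.n_asv_24m,
            n_asv_36m=self.n_asv_36m,
        )

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """A 200-predictor pool (7 + 100 + 93) with the same planted signal,
        sized so an exhaustive oracle can be run alongside the solver."""
        defaults = dict(
            n_asv_24m=100,
            n_asv_36m=93,
            planted_support=frozenset({5, 57, 157}),
            planted_coefficients=((5, 0.44), (57, 1929.0), (157, 417.0)),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticCohort:
    """A generated predictor table, response, taxonomy and planted truth."""

    spec: CohortSpec
    predictors: PredictorMatrix
    response: ResponseVector
    taxonomy: list[TaxonAnnotation]
    truth: tuple  # (support, coefficients, noise_sd)

    def abundance_table(self, timepoint: Timepoint) -> AbundanceTable:
        return self.predictors.abundance_table(timepoint)

    def to_dir(self, path) -> None:
        os.makedirs(path, exist_ok=True)
        import pandas as pd

        df = pd.DataFrame(
            self.predictors.values, columns=[str(i) for i in self.predictors.predictor_ids]
        )
        df[self.response.label] = self.response.values
        df.to_csv(os.path.join(path, "predictors.tsv"), sep="\t", index=False)
        write_taxonomy(self.taxonomy, os.path.join(path, "taxonomy.tsv"))
        support, coefs, noise_sd = self.truth
        with open(os.path.join(path, "truth.json"), "w") as fh:
            json.dump(
                {
                    "support": sorted(support),
                    "coefficients": {str(k): v for k, v in coefs.items()},
                    "noise_sd": noise_sd,
                    "seed": self.spec.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_dir(cls, path, spec: CohortSpec) -> "SyntheticCohort":
        matrix, response, _ = read_predictor_table(
            os.path.join(path, "predictors.tsv"), spec.schema()
        )
        taxonomy = read_taxonomy(os.path.join(path, "taxonomy.tsv"))
        with open(os.path.join(path, "truth.json")) as fh:
            raw = json.load(fh)
        truth = (
            frozenset(raw["support"]),
            {int(k): v for k, v in raw["coefficients"].items()},
            raw["noise_sd"],
        )
        return cls(spec=spec, predictors=matrix, response=response, taxonomy=taxonomy, truth=truth)


def _abundance_block(
    rng: np.random.Generator,
    n: int,
    m: int,
    spec: CohortSpec,
    planted_cols: dict[int, float],
) -> np.ndarray:
    """One timepoint's compositional block: zero-inflated log-normal
    intensities with block-correlated latent factors, closed to fractions.

    ``planted_cols`` maps local column index -> target mean fraction; those
    columns' log-mean intensities are set so their post-closure means land on
    target, which pins the planted coefficients' effect scale.
    """
    mu = rng.normal(0.0, spec.log_abundance_spread, size=m)
    sigma = spec.log_abundance_sigma
    keep = rng.random((n, m)) >= spec.zero_inflation
    n_blocks = math.ceil(m / spec.block_size)
    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, m))
    rho = spec.block_correlation
    block_of = np.arange(m) // spec.block_size
    z = math.sqrt(rho) * factors[:, block_of] + math.sqrt(1 - rho) * eps

    # pin planted columns' expected intensity so their closed fraction hits target
    expected = np.exp(mu + sigma**2 / 2) * (1 - spec.zero_inflation)
    rest = expected.sum() - expected[list(planted_cols)].sum()
    for col, target in planted_cols.items():
        share = target / max(1e-12, 1 - sum(planted_cols.values()))
        mu[col] = math.log(share * rest) - sigma**2 / 2 - math.log(1 - spec.zero_inflation)

    intensity = np.exp(mu + sigma * z) * keep
    rowsum = intensity.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return intensity / rowsum


def _baseline_block(rng: np.random.Generator, n: int) -> np.ndarray:
    """Intervention indicator, three anthropometric z-scores, and cognition/
    language/motor composites (mean 100, SD 15; language-cognition r = 0.7)."""
    intervention = rng.integers(0, 2, size=n).astype(float)
    haz = rng.normal(-2.5, 1.0, size=n)
    waz = rng.normal(-1.5, 1.0, size=n)
    whz = rng.normal(-0.5, 1.0, size=n)
    shared = rng.standard_normal(n)
    cog_eps = rng.standard_normal(n)
    lang_eps = rng.standard_normal(n)
    r = 0.7
    cognition = 100 + 15 * (math.sqrt(r) * shared + math.sqrt(1 - r) * cog_eps)
    language = 100 + 15 * (math.sqrt(r) * shared + math.sqrt(1 - r) * lang_eps)
    motor = rng.normal(100, 15, size=n)
    block = np.column_stack(
        [
            intervention,
            haz,
            waz,
            whz,
            np.clip(cognition, 40, 160),
            np.clip(language, 40, 160),
            np.clip(motor, 40, 160),
        ]
    )
    return block


_PLANTED_NAMES_24M = ("Coprococcus eutactus", TaxonRank.SPECIES, 100.0)
_PLANTED_NAMES_36M = ("Bifidobacterium longum group", TaxonRank.SPECIES_GROUP, 100.0)


def _taxonomy_block(
    rng: np.random.Generator,
    asv_ids: list[int],
    spec: CohortSpec,
    planted: set[int],
    planted_meta,
) -> list[TaxonAnnotation]:
    out = []
    n_species_pool = max(2, int(0.6 * len(asv_ids)))
    aero_classes = np.array(
        [Aerotolerance.AEROTOLERANT, Aerotolerance.STRICT_ANAEROBE, Aerotolerance.UNKNOWN],
        dtype=object,
    )
    for asv in asv_ids:
        species_idx = int(rng.integers(0, n_species_pool))
        resolved = rng.random() < spec.species_fraction
        aero = rng.choice(aero_classes, p=[0.15, 0.75, 0.10])
        if asv in planted:
            name, rank, identity = planted_meta
            aero = Aerotolerance.STRICT_ANAEROBE
        elif resolved:
            name = f"species_{species_idx:04d}"
            rank = TaxonRank.SPECIES
            identity = float(np.round(97.0 + 3.0 * rng.random(), 1))
        else:
            name = f"genus_{species_idx % 40:02d}"
            rank = TaxonRank.GENUS
            identity = float(np.round(85.0 + 12.0 * rng.random(), 1))
        out.append(
            TaxonAnnotation(
                asv_id=asv,
                taxon_name=name,
                rank=rank,
                identity_pct=identity,
                aerotolerance=aero,
            )
        )
    return out


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from the spec (bit-exact in (spec, seed))."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    schema = spec.schema()

    baseline = _baseline_block(rng, n)

    planted_by_tp: dict[Timepoint, dict[int, float]] = {
        Timepoint.MICROBIOTA_24M: {},
        Timepoint.MICROBIOTA_36M: {},
    }
    for pid in spec.planted_support:
        tp = schema.timepoint_of(pid)
        if tp is Timepoint.MICROBIOTA_24M:
            planted_by_tp[tp][pid - spec.n_baseline] = _PLANTED_MEAN_24M
        elif tp is Timepoint.MICROBIOTA_36M:
            planted_by_tp[tp][pid - spec.n_baseline - spec.n_asv_24m] = _PLANTED_MEAN_36M

    block24 = _abundance_block(
        rng, n, spec.n_asv_24m, spec, planted_by_tp[Timepoint.MICROBIOTA_24M]
    )
    block36 = _abundance_block(
        rng, n, spec.n_asv_36m, spec, planted_by_tp[Timepoint.MICROBIOTA_36M]
    )
    values = np.column_stack([baseline, block24, block36])
    ids = list(range(spec.t))
    tags = [schema.timepoint_of(i) for i in ids]
    labels = [
        "intervention",
        "HAZ_24m",
        "WAZ_24m",
        "WHZ_24m",
        "cognition_24m",
        "language_24m",
        "motor_24m",
    ][: spec.n_baseline] + [f"asv_{i}" for i in ids[spec.n_baseline :]]
    matrix = PredictorMatrix(values, ids, labels, tags)

    coefs = spec.coefficients
    signal = spec.intercept + sum(
        beta * values[:, pid] for pid, beta in coefs.items()
    )
    y = signal + rng.normal(0.0, spec.noise_sd, size=n)
    response = ResponseVector(y, "language_36m")

    ids24 = ids[spec.n_baseline : spec.n_baseline + spec.n_asv_24m]
    ids36 = ids[spec.n_baseline + spec.n_asv_24m :]
    planted24 = {p for p in spec.planted_support if schema.timepoint_of(p) is Timepoint.MICROBIOTA_24M}
    planted36 = {p for p in spec.planted_support if schema.timepoint_of(p) is Timepoint.MICROBIOTA_36M}
    taxonomy = _taxonomy_block(rng, ids24, spec, planted24, _PLANTED_NAMES_24M)
    taxonomy += _taxonomy_block(rng, ids36, spec, planted36, _PLANTED_NAMES_36M)

    truth = (frozenset(spec.planted_support), coefs, spec.noise_sd)
    return SyntheticCohort(
        spec=spec, predictors=matrix, response=response, taxonomy=taxonomy, truth=truth
    )


def null_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Same marginal structure with all microbiota effects removed: the
    response depends only on the 24-month language score plus noise."""
    schema = spec.schema()
    base_planted = {
        pid: beta
        for pid, beta in spec.coefficients.items()
        if schema.timepoint_of(pid) is Timepoint.BASELINE
    }
    if not base_planted:
        base_planted = {5: 0.44} if spec.n_baseline > 5 else {}
    null_spec = replace(
        spec,
        planted_support=frozenset(base_planted),
        planted_coefficients=tuple(sorted(base_planted.items())),
    )
    return generate_cohort(null_spec)


def planted_truth(cohort: SyntheticCohort) -> tuple:
    """The generating (support, coefficients, noise_sd) for scoring recovery."""
    return cohort.truth
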