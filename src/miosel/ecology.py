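"""Core-microbiota prevalence profiling and the MAPI aerotolerance index.

The *core microbiota* is defined operationally: pool ASV abundances to the
species level (ambiguous calls pool at genus), then rank taxa by prevalence —
the fraction of subjects in which a taxon's relative abundance meets a
detection threshold — at an anchor threshold of 0.1%, and profile the top
taxa across a log-spaced grid of thresholds up to 100%.

The Metagenomic Aerotolerant Predominance Index (MAPI) summarises the
oxygen-tolerance balance of one gut community: MAPI = ln(Ae/Ana), the natural
log of the ratio of summed relative abundance of aerotolerant taxa to that of
strict anaerobes.  MAPI > 0 indicates aerotolerant predominance, MAPI < 0
anaerobic predominance; healthy gut communities sit well below zero.  Taxa
absent from the aerotolerance lookup are excluded from both sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AbundanceTable, Aerotolerance, TaxonAnnotation, TaxonRank
from .group_screen import GroupLabels

__all__ = [
    "CoreProfile",
    "MapiValue",
    "MapiUndefinedError",
    "pool_by_species",
    "prevalence_at",
    "core_profile",
    "render_core_heatmap",
    "mapi",
    "mapi_table",
    "mapi_group_compare",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_PSEUDOCOUNT = 1e-6


class MapiUndefinedError(ValueError):
    """No classified taxon present: the aerotolerance ratio is undefined."""


@dataclass
class CoreProfile:
    """Prevalence of the top taxa over a grid of detection thresholds."""

    species_order: list[str]
    thresholds: np.ndarray
    prevalence: np.ndarray  # species x thresholds, fractions in [0, 1]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.prevalence, axis=1) > 1e-12):
            raise ValueError("prevalence must be nonincreasing along increasing threshold")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.prevalence, index=self.species_order, columns=np.round(self.thresholds, 8)
        )


@dataclass(frozen=True)
class MapiValue:
    """One subject's aerotolerant/anaerobe balance."""

    subject: int
    aerotolerant_fraction: float
    anaerobe_fraction: float
    mapi: float


def pool_by_species(
    table: AbundanceTable, taxonomy: list[TaxonAnnotation]
) -> AbundanceTable:
    """Sum ASV abundances sharing a taxon label into species-level columns.

    ASVs whose call is ambiguous (rank = genus) pool under the genus label.
    Every ASV must be annotated; total abundance per subject is conserved.
    """
    ann = {a.asv_id: a for a in taxonomy}
    missing = [asv for asv in table.taxa if asv not in ann]
    if missing:
        raise ValueError(f"unannotated ASVs: {missing}")
    labels = [ann[asv].taxon_name for asv in table.taxa]
    uniq = sorted(set(labels))
    idx = {name: i for i, name in enumerate(uniq)}
    pooled = np.zeros((table.n_subjects, len(uniq)))
    for j, name in enumerate(labels):
        pooled[:, idx[name]] += table.values[:, j]
    return AbundanceTable(values=pooled, taxa=uniq, timepoint=table.timepoint)


def prevalence_at(table: AbundanceTable, threshold: float) -> np.ndarray:
    """Per-taxon fraction of subjects with abundance >= threshold (closed)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1] as a fraction")
    return (table.values >= threshold).mean(axis=0)


def core_profile(
    table: AbundanceTable,
    anchor_threshold: float = 0.001,
    top_n: int = 50,
    thresholds: np.ndarray | None = None,
) -> CoreProfile:
    """Rank taxa by prevalence at the anchor threshold and profile the top_n.

    The default grid is 30 log-spaced detection thresholds from 0.1% to 100%
    relative abundance.  Fewer taxa than ``top_n`` truncates with a warning.
    """
    if thresholds is None:
        thresholds = np.logspace(math.log10(0.001), 0.0, 30)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    anchor = prevalence_at(table, anchor_threshold)
    if table.n_taxa < top_n:
        import warnings

        warnings.warn(
            f"only {table.n_taxa} taxa available; truncating core to that size",
            stacklevel=2,
        )
        top_n = table.n_taxa
    order = sorted(range(table.n_taxa), key=lambda j: (-anchor[j], str(table.taxa[j])))
    keep = order[:top_n]
    prev = np.stack([ (table.values[:, keep] >= th).mean(axis=0) for th in thresholds ], axis=1)
    return CoreProfile(
        species_order=[table.taxa[j] for j in keep],
        thresholds=thresholds,
        prevalence=prev,
    )


def render_core_heatmap(profile: CoreProfile, path, dpi: int = 150) -> None:
    """Heatmap of the core profile: taxa by prevalence rank on the y-axis,
    log-scaled detection threshold (%) on the x-axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(4, len(profile.species_order) / 6)))
    im = ax.imshow(profile.prevalence, cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(profile.species_order)))
    ax.set_yticklabels(profile.species_order, fontsize=6)
    ticks = range(0, len(profile.thresholds), max(1, len(profile.thresholds) // 8))
    ax.set_xticks(list(ticks))
    ax.set_xticklabels([f"{profile.thresholds[i] * 100:.2g}" for i in ticks], fontsize=7)
    ax.set_xlabel("detection threshold (% relative abundance, log-spaced)")
    fig.colorbar(im, ax=ax, label="prevalence")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def _class_sums(
    row: np.ndarray, taxa: list, aero_of: dict
) -> tuple[float, float, int]:
    ae = ana = 0.0
    classified = 0
    for j, taxon in enumerate(taxa):
        cls = aero_of.get(taxon, Aerotolerance.UNKNOWN)
        if cls is Aerotolerance.AEROTOLERANT:
            ae += row[j]
            classified += 1
        elif cls is Aerotolerance.STRICT_ANAEROBE:
            ana += row[j]
            classified += 1
    return ae, ana, classified


def mapi(
    row: np.ndarray,
    taxa: list,
    taxonomy: list[TaxonAnnotation],
    subject: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MapiValue:
    """MAPI = ln(Ae/Ana) for one sample.

    Ae sums relative abundance over aerotolerant taxa, Ana over strict
    anaerobes; unknown taxa are excluded.  The pseudocount enters only when a
    class sum is exactly zero, keeping non-degenerate values untouched.
    """
    aero_of = {a.taxon_name: a.aerotolerance for a in taxonomy}
    # ASV-keyed tables may be passed directly: fall back to asv_id keys
    if not any(t in aero_of for t in taxa):
        aero_of = {a.asv_id: a.aerotolerance for a in taxonomy}
    ae, ana, classified = _class_sums(np.asarray(row, dtype=float), taxa, aero_of)
    if classified == 0:
        raise MapiUndefinedError("no taxon in this sample has a known aerotolerance class")
    if ae == 0.0 or ana == 0.0:
        value = math.log((ae + pseudocount) / (ana + pseudocount))
    else:
        value = math.log(ae / ana)
    return MapiValue(
        subject=subject, aerotolerant_fraction=ae, anaerobe_fraction=ana, mapi=value
    )


def mapi_table(
    table: AbundanceTable,
    taxonomy: list[TaxonAnnotation],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MapiValue]:
    """MAPI for every subject of an abundance table."""
    return [
        mapi(table.values[i], table.taxa, taxonomy, subject=i, pseudocount=pseudocount)
        for i in range(table.n_subjects)
    ]


def _five_number(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "n": int(values.size),
    }


def mapi_group_compare(
    mapi_values: list[MapiValue], labels: GroupLabels
) -> tuple[dict[str, dict[str, float]], float]:
    """Box-plot summaries per language group and a two-sided rank-sum p-value.

    The comparison uses the Mann-Whitney U test (the implementation's choice
    of rank-sum variant for these group sizes).
    """
    if len(mapi_values) != len(labels.labels):
        raise ValueError("MAPI values do not align with group labels")
    vals = np.array([m.mapi for m in mapi_values])
    below = labels.mask_below()
    if not below.any() or below.all():
        raise ValueError("both groups must be non-empty")
    x, y = vals[~below], vals[below]
    if np.all(np.concatenate([x, y]) == vals[0]):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    summaries = {
        "non_impaired": _five_number(x),
        "below_average": _five_number(y),
    }
    return summaries, p
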