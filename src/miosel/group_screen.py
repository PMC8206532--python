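"""Nonparametric differential-abundance screening between language groups.

Children are dichotomized at the BSID-III population mean (score below 100 =
"below average", 100 or higher = "non-impaired") and every species-resolved
ASV is tested for an abundance difference between the groups with the
two-sided Mann-Whitney U test.  Relative abundances are mixtures of exact
zeros (absence) and positive fractions, which is why a rank test is used:
zeros tie at the lowest ranks and no distributional form is assumed.  Raw
p-values are reported against the expected number of false positives
(n_tests x alpha); an optional Benjamini-Hochberg column is provided as an
extension, clearly separated from the raw screen.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AbundanceTable, Aerotolerance, ResponseVector, TaxonAnnotation

__all__ = [
    "Group",
    "GroupLabels",
    "ScreenResult",
    "dichotomize",
    "mannwhitney_screen",
    "screen_to_frame",
    "expected_false_positives",
]


class Group(str, enum.Enum):
    BELOW_AVERAGE = "below_average"
    NON_IMPAIRED = "non_impaired"


@dataclass
class GroupLabels:
    """Per-subject group membership from thresholding the language score."""

    labels: list[Group]
    cutoff: float

    @property
    def n_below(self) -> int:
        return sum(1 for g in self.labels if g is Group.BELOW_AVERAGE)

    @property
    def n_non_impaired(self) -> int:
        return sum(1 for g in self.labels if g is Group.NON_IMPAIRED)

    def mask_below(self) -> np.ndarray:
        return np.array([g is Group.BELOW_AVERAGE for g in self.labels])

    def swapped(self) -> "GroupLabels":
        flip = {Group.BELOW_AVERAGE: Group.NON_IMPAIRED, Group.NON_IMPAIRED: Group.BELOW_AVERAGE}
        return GroupLabels([flip[g] for g in self.labels], self.cutoff)


@dataclass(frozen=True)
class ScreenResult:
    """One ASV's rank-sum comparison between the two language groups."""

    asv_id: int
    taxon_name: str
    identity_pct: float
    U_statistic: float
    p_value: float
    direction: str  # "higher_in_non_impaired" | "higher_in_impaired"
    obligate_anaerobe: bool
    core_member: bool = False


def dichotomize(scores: ResponseVector, cutoff: float = 100.0) -> GroupLabels:
    """Split subjects at the cutoff: score < cutoff below average, >= cutoff
    non-impaired (the boundary is inclusive on the non-impaired side)."""
    if not np.isfinite(scores.values).all():
        raise ValueError("scores must be finite")
    labels = [
        Group.BELOW_AVERAGE if s < cutoff else Group.NON_IMPAIRED for s in scores.values
    ]
    return GroupLabels(labels=labels, cutoff=cutoff)


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of x vs y, robust to all-tied samples.

    Uses the exact null when both samples are small and tie-free, otherwise
    the normal approximation with tie and continuity corrections (scipy's
    defaults at these sizes).  When every pooled value is identical the test
    carries no information and p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def mannwhitney_screen(
    table: AbundanceTable,
    labels: GroupLabels,
    taxonomy: list[TaxonAnnotation],
    identity_min: float = 97.0,
    core_species: set | None = None,
) -> list[ScreenResult]:
    """Per-ASV two-sided Mann-Whitney screen, species-resolved ASVs only.

    Restricted to ASVs whose taxonomic call has identity >= ``identity_min``.
    Direction compares mean ranks of the two groups.  ``core_species``
    optionally flags taxa that belong to the core-microbiota profile.
    """
    if table.n_subjects != len(labels.labels):
        raise ValueError("abundance rows do not align with group labels")
    if labels.n_below == 0 or labels.n_non_impaired == 0:
        raise ValueError("both language groups must be non-empty")
    ann = {a.asv_id: a for a in taxonomy}
    below = labels.mask_below()
    results: list[ScreenResult] = []
    for j, asv in enumerate(table.taxa):
        a = ann.get(asv)
        if a is None or a.identity_pct < identity_min:
            continue
        col = table.values[:, j]
        x, y = col[~below], col[below]  # non-impaired, below-average
        U, p = _mwu(x, y)
        ranks = stats.rankdata(col)
        direction = (
            "higher_in_non_impaired"
            if ranks[~below].mean() >= ranks[below].mean()
            else "higher_in_impaired"
        )
        results.append(
            ScreenResult(
                asv_id=asv,
                taxon_name=a.taxon_name,
                identity_pct=a.identity_pct,
                U_statistic=U,
                p_value=p,
                direction=direction,
                obligate_anaerobe=a.aerotolerance is Aerotolerance.STRICT_ANAEROBE,
                core_member=bool(core_species and a.taxon_name in core_species),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.asv_id))
    return results


def screen_to_frame(results: list[ScreenResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tabulate the screen with the expected-false-positive context and a
    Benjamini-Hochberg column (extension; the raw screen reports raw p)."""
    df = pd.DataFrame(
        {
            "asv_id": [r.asv_id for r in results],
            "taxon_name": [r.taxon_name for r in results],
            "identity_pct": [r.identity_pct for r in results],
            "U": [r.U_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "core_member": [r.core_member for r in results],
            "obligate_anaerobe": [r.obligate_anaerobe for r in results],
        }
    )
    if len(df):
        df["p_bh"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
    raw, rounded = expected_false_positives(len(df), alpha)
    df.attrs["n_tests"] = len(df)
    df.attrs["alpha"] = alpha
    df.attrs["n_significant"] = int((df["p_value"] < alpha).sum()) if len(df) else 0
    df.attrs["expected_false_positives"] = raw
    df.attrs["expected_false_positives_rounded"] = rounded
    return df


def expected_false_positives(n_tests: int, alpha: float = 0.05) -> tuple[float, int]:
    """Expected count of sub-alpha p-values under a global null: n x alpha,
    returned raw and rounded to the nearest integer."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 0:
        raise ValueError("n_tests must be non-negative")
    raw = n_tests * alpha
    return raw, int(round(raw))
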