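import math

import numpy as np
import pytest

from miosel.data_model import (
    AbundanceTable,
    Aerotolerance,
    TaxonAnnotation,
    TaxonRank,
    Timepoint,
)
from miosel.ecology import (
    MapiUndefinedError,
    core_profile,
    mapi,
    mapi_group_compare,
    mapi_table,
    pool_by_species,
    prevalence_at,
)
from miosel.group_screen import GroupLabels, Group


def _ann(asv, name, rank=TaxonRank.SPECIES, aero=Aerotolerance.UNKNOWN):
    return TaxonAnnotation(asv_id=asv, taxon_name=name, rank=rank,
                           identity_pct=99.0, aerotolerance=aero)


def _table(values, taxa=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa if taxa is not None else list(range(values.shape[1]))
    return AbundanceTable(values, taxa, Timepoint.MICROBIOTA_24M)


class TestPoolBySpecies:
    def test_additivity(self):
        table = _table([[0.01, 0.02], [0.03, 0.04]])
        pooled = pool_by_species(table, [_ann(0, "sp_a"), _ann(1, "sp_a")])
        assert pooled.taxa == ["sp_a"]
        assert np.allclose(pooled.values[:, 0], [0.03, 0.07])

    def test_total_abundance_conserved(self):
        rng = np.random.default_rng(0)
        vals = rng.dirichlet(np.ones(10), size=8) * 0.9
        names = [f"sp_{i % 4}" for i in range(10)]
        pooled = pool_by_species(_table(vals), [_ann(i, names[i]) for i in range(10)])
        assert np.allclose(pooled.values.sum(axis=1), vals.sum(axis=1), atol=1e-12)

    def test_ambiguous_asvs_pool_at_genus(self):
        table = _table([[0.01, 0.02, 0.005], [0.0, 0.01, 0.02]])
        taxonomy = [
            _ann(0, "Bifidobacterium", rank=TaxonRank.GENUS),
            _ann(1, "Bifidobacterium", rank=TaxonRank.GENUS),
            _ann(2, "sp_x"),
        ]
        pooled = pool_by_species(table, taxonomy)
        assert set(pooled.taxa) == {"Bifidobacterium", "sp_x"}
        j = pooled.taxa.index("Bifidobacterium")
        assert np.allclose(pooled.values[:, j], [0.03, 0.01])

    def test_unannotated_asv_listed(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            pool_by_species(_table([[0.01, 0.02]] * 2), [_ann(0, "sp_a")])


class TestPrevalence:
    def test_one_in_five_subjects(self):
        vals = np.zeros((5, 1))
        vals[0, 0] = 0.02
        assert prevalence_at(_table(vals), 0.01)[0] == pytest.approx(0.2)

    def test_threshold_above_maximum(self):
        vals = np.full((4, 2), 0.001)
        assert (prevalence_at(_table(vals), 0.5) == 0).all()

    def test_detection_threshold_is_closed(self):
        vals = np.full((4, 1), 0.001)
        assert prevalence_at(_table(vals), 0.001)[0] == pytest.approx(1.0)


class TestCoreProfile:
    def test_ubiquitous_species_ranks_first(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 0.002, size=(20, 6))
        vals[:, 3] = rng.uniform(0.05, 0.1, size=20)  # present everywhere, abundant
        profile = core_profile(_table(vals, [f"sp_{i}" for i in range(6)]), top_n=6)
        assert profile.species_order[0] == "sp_3"

    def test_prevalence_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(2)
        vals = rng.dirichlet(np.ones(30), size=25)
        profile = core_profile(_table(vals, [f"sp_{i}" for i in range(30)]), top_n=30)
        assert (np.diff(profile.prevalence, axis=1) <= 1e-12).all()

    def test_truncation_warns(self):
        vals = np.random.default_rng(3).dirichlet(np.ones(5), size=10)
        with pytest.warns(UserWarning, match="truncating"):
            profile = core_profile(_table(vals, [f"sp_{i}" for i in range(5)]), top_n=50)
        assert len(profile.species_order) == 5


class TestMapi:
    taxonomy = [
        _ann(0, "aero_sp", aero=Aerotolerance.AEROTOLERANT),
        _ann(1, "ana_sp", aero=Aerotolerance.STRICT_ANAEROBE),
        _ann(2, "unknown_sp"),
    ]

    def test_balanced_classes_give_zero(self):
        v = mapi(np.array([0.2, 0.2, 0.1]), [0, 1, 2], self.taxonomy)
        assert v.mapi == pytest.approx(0.0, abs=1e-12)

    def test_three_to_one_ratio_is_ln3(self):
        v = mapi(np.array([0.3, 0.1, 0.0]), [0, 1, 2], self.taxonomy)
        assert v.mapi == pytest.approx(math.log(3), rel=1e-12)

    def test_label_swap_negates(self):
        swapped = [
            _ann(0, "aero_sp", aero=Aerotolerance.STRICT_ANAEROBE),
            _ann(1, "ana_sp", aero=Aerotolerance.AEROTOLERANT),
            _ann(2, "unknown_sp"),
        ]
        row = np.array([0.25, 0.05, 0.3])
        v = mapi(row, [0, 1, 2], self.taxonomy)
        v_sw = mapi(row, [0, 1, 2], swapped)
        assert v_sw.mapi == pytest.approx(-v.mapi, rel=1e-12)

    def test_all_unknown_is_undefined(self):
        with pytest.raises(MapiUndefinedError):
            mapi(np.array([0.1]), [2], self.taxonomy)

    def test_zero_anaerobes_stays_finite_and_positive(self):
        v = mapi(np.array([0.3, 0.0, 0.0]), [0, 1, 2], self.taxonomy)
        assert v.mapi > 0 and np.isfinite(v.mapi)


class TestMapiGroupCompare:
    @staticmethod
    def _labels(n_below, n_above):
        return GroupLabels(
            [Group.BELOW_AVERAGE] * n_below + [Group.NON_IMPAIRED] * n_above, 100.0
        )

    def test_identical_groups_give_p_one(self):
        taxonomy = TestMapi.taxonomy
        vals = np.tile(np.array([[0.2, 0.1, 0.0]]), (10, 1))
        mv = mapi_table(_table(vals), taxonomy)
        _, p = mapi_group_compare(mv, self._labels(5, 5))
        assert p == pytest.approx(1.0)

    def test_location_shift_detected_with_power(self):
        """A 0.5 ln-scale shift at n=(61,78) is detected in >80% of replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            below = rng.normal(-2.0, 1.0, 61)
            above = rng.normal(-2.5, 1.0, 78)
            from scipy.stats import mannwhitneyu

            p = mannwhitneyu(above, below, alternative="two-sided").pvalue
            hits += p < 0.05
        assert hits / n_rep > 0.8

    def test_summaries_have_five_numbers(self):
        rng = np.random.default_rng(8)
        vals = np.abs(rng.normal(0.1, 0.02, size=(12, 3)))
        vals = vals / vals.sum(axis=1, keepdims=True) * 0.8
        mv = mapi_table(_table(vals), TestMapi.taxonomy)
        summaries, p = mapi_group_compare(mv, self._labels(6, 6))
        for grp in ("below_average", "non_impaired"):
            assert set(summaries[grp]) == {"min", "q1", "median", "q3", "max", "n"}
        assert 0 < p <= 1
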