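import numpy as np
import pandas as pd
import pytest

from miosel.data_model import (
    Aerotolerance,
    DataFormatError,
    ModelRecord,
    TableSchema,
    TaxonRank,
    read_model_list,
    read_predictor_table,
    read_taxonomy,
    write_model_list,
)


def _write_table(tmp_path, df, name="table.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadPredictorTable:
    def test_full_study_layout_tag_counts(self, tmp_path):
        """The 1170-predictor layout splits 7 baseline + 542 + 621 columns."""
        rng = np.random.default_rng(0)
        n, schema = 4, TableSchema()
        cols = {str(i): rng.normal(100, 10, n) for i in range(7)}
        cols.update({str(i): rng.uniform(0, 0.01, n) for i in range(7, 1170)})
        cols[schema.response] = rng.normal(100, 15, n)
        X, y, report = read_predictor_table(_write_table(tmp_path, pd.DataFrame(cols)), schema)
        assert report["tag_counts"] == {
            "baseline": 7,
            "microbiota_24m": 542,
            "microbiota_36m": 621,
        }
        assert X.n_predictors == 1170 and len(y) == n

    def test_toy_table(self, tmp_path):
        df = pd.DataFrame({"0": [1.0, 2, 3], "1": [4.0, 5, 6], "y": [7.0, 8, 9]})
        schema = TableSchema(response="y", n_baseline=2, n_asv_24m=0, n_asv_36m=0)
        X, y, _ = read_predictor_table(_write_table(tmp_path, df), schema)
        assert X.values.shape == (3, 2) and len(y) == 3

    def test_non_numeric_cell_is_named(self, tmp_path):
        df = pd.DataFrame({"0": [1.0, "oops", 3], "y": [1.0, 2, 3]})
        schema = TableSchema(response="y", n_baseline=1, n_asv_24m=0, n_asv_36m=0)
        with pytest.raises(DataFormatError, match="row 1.*'0'"):
            read_predictor_table(_write_table(tmp_path, df), schema)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("0\t0\ty\n1\t2\t3\n4\t5\t6\n")
        schema = TableSchema(response="y", n_baseline=2, n_asv_24m=0, n_asv_36m=0)
        with pytest.raises(DataFormatError, match="duplicate"):
            read_predictor_table(path, schema)

    def test_missing_response_rejected(self, tmp_path):
        df = pd.DataFrame({"0": [1.0, 2], "1": [3.0, 4]})
        with pytest.raises(DataFormatError, match="response"):
            read_predictor_table(
                _write_table(tmp_path, df),
                TableSchema(response="y", n_baseline=2, n_asv_24m=0, n_asv_36m=0),
            )

    def test_incomplete_rows_dropped_and_reported(self, tmp_path):
        df = pd.DataFrame({"0": [1.0, None, 3, 4], "y": [1.0, 2, 3, 4]})
        schema = TableSchema(response="y", n_baseline=1, n_asv_24m=0, n_asv_36m=0)
        X, y, report = read_predictor_table(_write_table(tmp_path, df), schema)
        assert report["excluded_rows"] == [1]
        assert X.n_subjects == 3

    def test_percent_scale_converted_to_fractions(self, tmp_path):
        df = pd.DataFrame({"0": [100.0, 90], "1": [1.5, 4.5], "y": [1.0, 2]})
        schema = TableSchema(response="y", n_baseline=1, n_asv_24m=1, n_asv_36m=0,
                             abundance_scale="percent")
        X, _, _ = read_predictor_table(_write_table(tmp_path, df), schema)
        assert np.allclose(X.column(1), [0.015, 0.045])
        assert np.allclose(X.column(0), [100.0, 90])  # baseline untouched


class TestReadTaxonomy:
    def test_annotated_row(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "asv_id\ttaxon_name\trank\tidentity_pct\taerotolerance\n"
            "281\tCoprococcus eutactus\tspecies\t100.0\tstrict_anaerobe\n"
        )
        (ann,) = read_taxonomy(path)
        assert ann.taxon_name == "Coprococcus eutactus"
        assert ann.aerotolerance is Aerotolerance.STRICT_ANAEROBE
        assert ann.rank is TaxonRank.SPECIES

    def test_missing_aerotolerance_defaults_unknown(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("asv_id\ttaxon_name\trank\tidentity_pct\n7\tspecies_x\tspecies\t99.2\n")
        (ann,) = read_taxonomy(path)
        assert ann.aerotolerance is Aerotolerance.UNKNOWN

    def test_identity_out_of_bounds(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("asv_id\ttaxon_name\trank\tidentity_pct\n7\tspecies_x\tspecies\t105\n")
        with pytest.raises(DataFormatError, match="identity"):
            read_taxonomy(path)


class TestModelList:
    @staticmethod
    def _records():
        out = []
        for size in (4, 3, 2, 1):
            for rank in range(1, 21):
                sup = frozenset(range(100 * size, 100 * size + size))
                out.append(
                    ModelRecord(
                        support=sup,
                        coefficients_std={i: 0.1 * i + rank for i in sup},
                        rss=float(size + rank / 100),
                        n_terms=size,
                        rank_within_size=rank,
                    )
                )
        return out

    def test_eighty_model_grid_roundtrip(self, tmp_path):
        """20 models per size for sizes 1-4 write 80 rows and read back losslessly."""
        models = self._records()
        path = tmp_path / "models.tsv"
        write_model_list(models, path)
        assert len(path.read_text().strip().splitlines()) == 81  # header + 80
        back = read_model_list(path)
        assert len(back) == 80
        for a, b in zip(models, back):
            assert a.support == b.support and a.rss == b.rss
            assert a.coefficients_std == b.coefficients_std

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_model_list([], tmp_path / "m.tsv")

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            ModelRecord(frozenset({1, 2}), {1: 0.5, 2: 0.1}, rss=1.0, n_terms=3)
        with pytest.raises(ValueError):
            ModelRecord(frozenset({1}), {2: 0.5}, rss=1.0, n_terms=1)
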