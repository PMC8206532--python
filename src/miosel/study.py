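"""Conditional reproduction of the original cohort analysis.

The pipeline was built around a published 139-child cohort whose predictor
table (1170 predictors: intervention indicator, six 24-month developmental
scores, 542 ASV abundances at 24 months, 621 at 36 months, response = the
36-month language composite) is distributed as supplementary material and is
not bundled here.  When a copy of that table is supplied, this module re-runs
the headline computations — the three-term refit, cross-validation, the
correlation census, the group split and the differential-abundance screen —
and compares them with the reference values reported for the cohort.
Without the table it refuses cleanly; the package's unconditional validation
lives in the synthetic-cohort test suite instead.
"""

from __future__ import annotations

import os

from . import model_eval
from .data_model import TableSchema, Timepoint, read_predictor_table, read_taxonomy
from .group_screen import dichotomize, mannwhitney_screen

__all__ = ["REFERENCE_RESULTS", "reproduce_study"]

# Reference values reported for the original cohort analysis.  These are
# comparison targets for a supplied data table, never computed outputs.
REFERENCE_RESULTS = {
    "n_subjects": 139,
    "n_predictors": 1170,
    "group_sizes": {"below_average": 61, "non_impaired": 78},
    "best_three_term_support": [5, 281, 563],
    "coefficients": {5: 0.44, 281: 1929.0, 563: 417.0},
    "intercept": 57.0,
    "residual_sd": 12.0,
    "df_resid": 135,
    "F_value": 21.5,
    "adj_R2": 0.31,
    "cv_rmse": 12.1,
    "null_sd": 14.4,
    "high_correlation_pairs": 4164,
    "screen_n_tests": 397,
    "screen_significant": 25,
    "screen_higher_in_non_impaired": 19,
    "mapi_p_value": 0.09,
}


def reproduce_study(
    predictor_table, taxonomy_table=None, seed: int = 0, cutoff: float = 100.0
) -> dict:
    """Recompute the headline cohort quantities from a supplied data table.

    Returns a dict of computed values alongside :data:`REFERENCE_RESULTS`
    for comparison.  Raises ``FileNotFoundError`` when the table is absent.
    """
    if not os.path.exists(str(predictor_table)):
        raise FileNotFoundError(
            f"cohort predictor table not found at {predictor_table!r}; "
            "this reproduction runs only when the supplementary table is supplied"
        )
    schema = TableSchema()
    X, y, report = read_predictor_table(predictor_table, schema)
    out: dict = {"ingest_report": report}

    labels = dichotomize(y, cutoff)
    out["group_sizes"] = {
        "below_average": labels.n_below,
        "non_impaired": labels.n_non_impaired,
    }
    out["null_sd"] = model_eval.null_model_sd(y)

    support = REFERENCE_RESULTS["best_three_term_support"]
    fitted = model_eval.refit_original_scale(X, y, support)
    out["refit"] = {
        "intercept": fitted.intercept,
        "coefficients": fitted.coefficients,
        "residual_sd": fitted.residual_sd,
        "df_resid": fitted.df_resid,
        "F_value": fitted.F_value,
        "adj_R2": fitted.adj_R2,
    }
    n = X.n_subjects
    base, rem = divmod(n, 7)
    folds = [base + (1 if i < rem else 0) for i in range(7)]
    out["cv_rmse"] = model_eval.cross_validate(X, y, support, folds, seed).rmse_mean

    microbiota = [
        pid
        for pid, tag in zip(X.predictor_ids, X.timepoint_tags)
        if tag is not Timepoint.BASELINE
    ]
    out["high_correlation_pairs"] = model_eval.correlation_census(X, 0.5, microbiota)

    if taxonomy_table is not None:
        taxonomy = read_taxonomy(taxonomy_table)
        table24 = X.abundance_table(Timepoint.MICROBIOTA_24M)
        results = mannwhitney_screen(table24, labels, taxonomy, identity_min=97.0)
        out["screen_n_tests"] = len(results)
        out["screen_significant"] = sum(1 for r in results if r.p_value < 0.05)
        out["screen_higher_in_non_impaired"] = sum(
            1
            for r in results
            if r.p_value < 0.05 and r.direction == "higher_in_non_impaired"
        )

    # run the selection itself only on request-sized pools; the full
    # 1170-predictor, size-4 search is a long batch job, not a desk check
    out["reference"] = REFERENCE_RESULTS
    return out
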