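"""Model/Results interface tying the selection stages together.

``BestSubsetSelection`` is constructed from data (arrays, a DataFrame, or a
generated cohort); ``fit`` runs the k-best search over model sizes and
returns a ``BestSubsetResults`` object carrying the ranked ensemble together
with refitting, cross-validation, frequency and plotting methods — the same
shape a statsmodels user expects: build the model from data, fit it, then
interrogate the results object.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model_eval, raster_viz
from .data_model import (
    ModelRecord,
    PredictorMatrix,
    ResponseVector,
    TableSchema,
    Timepoint,
    write_model_list,
)
from .subset_select import SelectionConfig, StandardizedDesign, k_best_subsets, standardize

__all__ = ["BestSubsetSelection", "BestSubsetResults"]


class BestSubsetSelection:
    """k-best all-subsets linear regression of a response on a predictor pool.

    Parameters
    ----------
    endog
        Response values (:class:`ResponseVector` or 1-D array).
    exog
        Predictor pool (:class:`PredictorMatrix` or 2-D array; arrays get
        contiguous integer IDs and baseline tags).

    Examples
    --------
    >>> from miosel.synthetic_data import CohortSpec, generate_cohort
    >>> cohort = generate_cohort(CohortSpec.reduced(seed=7))
    >>> sel = BestSubsetSelection.from_cohort(cohort)
    >>> res = sel.fit(p_max=2, k=3)
    >>> len(res.models)
    6
    """

    def __init__(self, endog, exog):
        if not isinstance(exog, PredictorMatrix):
            exog = np.asarray(exog, dtype=float)
            exog = PredictorMatrix(
                exog,
                list(range(exog.shape[1])),
                [str(j) for j in range(exog.shape[1])],
                [Timepoint.BASELINE] * exog.shape[1],
            )
        if not isinstance(endog, ResponseVector):
            endog = ResponseVector(np.asarray(endog, dtype=float))
        if len(endog) != exog.n_subjects:
            raise ValueError("endog and exog row counts differ")
        self.exog = exog
        self.endog = endog
        self.design: StandardizedDesign = standardize(exog, endog)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str, schema: TableSchema | None = None
    ) -> "BestSubsetSelection":
        """Build from a DataFrame whose predictor columns carry integer IDs."""
        schema = schema or TableSchema(response=response)
        ids = [int(c) for c in df.columns if c != response]
        tags = [schema.timepoint_of(i) for i in ids]
        X = PredictorMatrix(
            df[[c for c in df.columns if c != response]].to_numpy(dtype=float),
            ids,
            [str(i) for i in ids],
            tags,
        )
        y = ResponseVector(df[response].to_numpy(dtype=float), response)
        return cls(y, X)

    @classmethod
    def from_cohort(cls, cohort) -> "BestSubsetSelection":
        return cls(cohort.response, cohort.predictors)

    def fit(
        self,
        p_max: int = 4,
        k: int = 20,
        backend: str = "auto",
        config: SelectionConfig | None = None,
    ) -> "BestSubsetResults":
        """Run the k-best search for sizes 1..p_max."""
        config = config or SelectionConfig(p_max=p_max, k=k, backend=backend)
        models = k_best_subsets(self.design, config)
        return BestSubsetResults(model=self, config=config, models=models)


@dataclass
class BestSubsetResults:
    """Ranked model ensemble plus evaluation and plotting methods."""

    model: BestSubsetSelection
    config: SelectionConfig
    models: list[ModelRecord]

    # -- access -------------------------------------------------------------

    def models_of_size(self, p: int) -> list[ModelRecord]:
        return sorted(
            (m for m in self.models if m.n_terms == p), key=lambda m: m.rank_within_size
        )

    def best(self, p: int) -> ModelRecord:
        ms = self.models_of_size(p)
        if not ms:
            raise KeyError(f"no models of size {p}")
        return ms[0]

    # -- evaluation ---------------------------------------------------------

    def refit(self, support=None, p: int | None = None) -> model_eval.FittedModel:
        """Original-scale OLS refit of a support (default: best of largest size)."""
        if support is None:
            p = p or max(m.n_terms for m in self.models)
            support = self.best(p).support
        return model_eval.refit_original_scale(self.model.exog, self.model.endog, support)

    def cross_validate(
        self, support=None, fold_sizes=None, seed: int = 0
    ) -> model_eval.CVResult:
        if support is None:
            support = self.best(max(m.n_terms for m in self.models)).support
        if fold_sizes is None:
            n = self.model.exog.n_subjects
            base, rem = divmod(n, 7)
            fold_sizes = [base + (1 if i < rem else 0) for i in range(7)]
        return model_eval.cross_validate(
            self.model.exog, self.model.endog, support, fold_sizes, seed
        )

    def null_sd(self) -> float:
        return model_eval.null_model_sd(self.model.endog)

    def predictor_frequency(self, sizes=None, pairs=()):
        return model_eval.predictor_frequency(self.models, sizes, pairs)

    # -- presentation -------------------------------------------------------

    def raster(self, scaling: str = "unit_norm") -> raster_viz.RasterGrid:
        return raster_viz.build_raster(self.models, self.model.design, scaling)

    def plot_raster(self, path, scaling: str = "unit_norm") -> None:
        raster_viz.render_raster(self.raster(scaling), path)

    def rsd_table(self) -> pd.DataFrame:
        return raster_viz.rsd_vs_size(self.models, self.model.design)

    def plot_rsd(self, path) -> None:
        raster_viz.plot_rsd(self.rsd_table(), path)

    def save(self, path) -> None:
        write_model_list(self.models, path)

    def summary(self) -> str:
        """Plain-text summary: ranked supports with RSS and residual SD."""
        design = self.model.design
        buf = io.StringIO()
        buf.write("k-best all-subsets regression\n")
        buf.write(
            f"N = {design.n} subjects, t = {design.t} predictors, "
            f"sizes 1-{self.config.p_max}, k = {self.config.k}\n"
        )
        if design.dropped_ids:
            buf.write(f"dropped zero-variance predictors: {design.dropped_ids}\n")
        rows = []
        ordered = sorted(self.models, key=lambda m: (m.n_terms, m.rank_within_size))
        for m in ordered:
            df_resid = design.n - m.n_terms - 1
            rows.append(
                {
                    "size": m.n_terms,
                    "rank": m.rank_within_size,
                    "rss_std": round(m.rss, 6),
                    "residual_sd": round(
                        float(np.sqrt(m.rss * design.response_scale**2 / df_resid)), 4
                    ),
                    "support": ",".join(str(i) for i in m.sorted_support),
                    "certified": m.certified,
                }
            )
        buf.write(pd.DataFrame(rows).to_string(index=False))
        return buf.getvalue()
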