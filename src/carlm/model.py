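"""Model / Results objects tying the sampler and assessment together.

Usage follows the familiar build-then-fit pattern::

    spec = model_spec("model6")
    m = HierarchicalModel.from_records(records, graph, spec)
    res = m.fit(n_iter=6000, burn_in=2000, n_chains=2, seed=1)
    print(res.summary())
    res.dic, res.p_d
"""

from __future__ import annotations

from functools import cached_property
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    Dataset,
    IndividualRecord,
    ModelSpec,
    WardGraph,
    build_dataset,
)
from .sampler import PosteriorSamples, PriorSpec, run_chain
from . import assess


class HierarchicalModel:
    """Hierarchical normal model for log-DUP with optional ward effects.

    Parameters
    ----------
    dataset : Dataset
        Aligned response / ward index / covariates.
    graph : WardGraph
        Ward contiguity structure (defines the ICAR neighbourhoods).
    spec : ModelSpec
        Which blocks enter the linear predictor.
    priors : PriorSpec, optional
        Minimally informative defaults if omitted.
    """

    def __init__(self, dataset: Dataset, graph: WardGraph, spec: ModelSpec,
                 priors: Optional[PriorSpec] = None,
                 allow_isolated: bool = False):
        if dataset.n_wards != graph.n_wards:
            raise ValueError("dataset and graph disagree on ward count")
        if spec.include_covariates and dataset.covariates is None:
            raise ValueError("model form includes covariates but dataset has none")
        self.dataset = dataset
        self.graph = graph
        self.spec = spec
        self.priors = priors if priors is not None else PriorSpec()
        self.allow_isolated = allow_isolated

    @classmethod
    def from_records(cls, records: Sequence[IndividualRecord],
                     graph: WardGraph, spec: ModelSpec,
                     priors: Optional[PriorSpec] = None,
                     zero_offset: bool = False, center_age: bool = False,
                     allow_isolated: bool = False) -> "HierarchicalModel":
        ds = build_dataset(records, graph, spec, zero_offset=zero_offset,
                           center_age=center_age)
        return cls(ds, graph, spec, priors, allow_isolated=allow_isolated)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, graph: WardGraph,
                       spec: ModelSpec, **kwargs) -> "HierarchicalModel":
        """Build from a raw data frame with columns ward_id, dup_days, age,
        sex, ethnicity and optionally diagnosis."""
        records = [
            IndividualRecord(
                ward_id=str(row["ward_id"]),
                dup_days=float(row["dup_days"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                ethnicity=str(row["ethnicity"]),
                diagnosis=(str(row["diagnosis"])
                           if "diagnosis" in df.columns and pd.notna(row["diagnosis"])
                           and str(row["diagnosis"]) != "" else None),
            )
            for _, row in df.iterrows()
        ]
        return cls.from_records(records, graph, spec, **kwargs)

    def fit(self, n_iter: int = 30_000, burn_in: int = 10_000, thin: int = 1,
            n_chains: int = 2, seed: int = 0,
            fixed_sigma2_e: Optional[float] = None) -> "MCMCResults":
        """Run the Gibbs sampler; returns an :class:`MCMCResults`."""
        samples = run_chain(
            self.dataset, self.graph, self.spec, self.priors,
            n_iter=n_iter, burn_in=burn_in, thin=thin, n_chains=n_chains,
            seed=seed, fixed_sigma2_e=fixed_sigma2_e,
            allow_isolated=self.allow_isolated,
        )
        return MCMCResults(self, samples)


class MCMCResults:
    """Posterior draws plus the derived summaries for one fitted model."""

    def __init__(self, model: HierarchicalModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    # -- fit quality -------------------------------------------------------
    @cached_property
    def _dic_triple(self):
        return assess.compute_dic(self.samples, self.model.dataset)

    @property
    def dic(self) -> float:
        return self._dic_triple[0]

    @property
    def p_d(self) -> float:
        return self._dic_triple[1]

    @property
    def d_bar(self) -> float:
        return self._dic_triple[2]

    # -- summaries ---------------------------------------------------------
    def summary(self, include_effects: bool = False) -> pd.DataFrame:
        return assess.summarize_posterior(self.samples,
                                          include_effects=include_effects)

    def variance_partition(self, mode: str = "per_iteration"):
        return assess.variance_partition(self.samples, mode=mode)

    def rhat(self, warn: bool = True) -> pd.Series:
        return assess.gelman_rubin(self.samples, warn=warn)

    def ward_effects(self) -> pd.DataFrame:
        """Per-ward summary of the unstructured effects R_i, ordered by
        ward label, with a flag for intervals excluding zero."""
        if self.samples.R is None:
            raise ValueError("model form has no unstructured ward effects")
        ids = list(self.samples.ward_ids)
        order = np.argsort(ids)
        rows = []
        for k in order:
            flat = self.samples.R[:, :, k].reshape(-1)
            med, lo, hi = np.percentile(flat, [50.0, 2.5, 97.5])
            rows.append({
                "ward_id": ids[k], "median": med, "q2.5": lo, "q97.5": hi,
                "excludes_zero": bool(lo > 0.0 or hi < 0.0),
            })
        return pd.DataFrame(rows)

    def report(self, rhat: bool = True) -> assess.ModelReport:
        r_hat = None
        if rhat and self.samples.n_chains >= 2:
            r_hat = self.rhat(warn=False)
        return assess.ModelReport(
            label=self.model.spec.label,
            dic=self.dic, p_d=self.p_d, d_bar=self.d_bar,
            parameter_summaries=self.summary(include_effects=False),
            variance_proportion=self.variance_partition(),
            r_hat=r_hat,
            n_obs=self.model.dataset.n_obs,
        )

    def summary_table(self) -> str:
        rep = self.report(rhat=False)
        return assess.format_report_table({rep.label: rep})

    def save_samples(self, path) -> None:
        self.samples.save_csv(path)
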