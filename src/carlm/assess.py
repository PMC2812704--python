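"""Posterior summarisation, DIC, convergence diagnostics and the
area-level variance partition.

DIC follows the classical definition: Dbar (posterior mean deviance) plus
pD, the effective number of parameters, where pD = Dbar - D(theta_hat) and
theta_hat plugs in the posterior means of the parameters "in focus" — here
the fixed effects, the ward effects and the residual variance, i.e. the
deviance is conditional on the random effects.  Lower DIC indicates a
better-fitting model.

The area-level variance share is computed per retained iteration as

    100 * v_area / (v_area + sigma_e^2),
    v_area = sigma_R^2 (if present) + var(S_1..S_K) (if present)

using the empirical variance of the current spatial-effect vector, since
the ICAR sigma_S^2 is a conditional, not a marginal, variance.  The summary
is the median and equal-tailed 95% interval of those per-iteration shares;
a point-estimate mode (ratio at posterior means) is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .data import Dataset
from .sampler import ChainState, PosteriorSamples, deviance

__all__ = [
    "compute_dic",
    "summarize_posterior",
    "variance_partition",
    "VariancePartition",
    "split_rhat",
    "gelman_rubin",
    "ModelReport",
    "comparison_table",
    "format_report_table",
]


def _posterior_mean_state(samples: PosteriorSamples) -> ChainState:
    mean2 = lambda a: float(a.mean())
    return ChainState(
        alpha=mean2(samples.alpha),
        beta=None if samples.beta is None else samples.beta.mean(axis=(0, 1)),
        R=None if samples.R is None else samples.R.mean(axis=(0, 1)),
        S=None if samples.S is None else samples.S.mean(axis=(0, 1)),
        sigma2_e=(samples.fixed_sigma2_e if samples.fixed_sigma2_e is not None
                  else mean2(samples.sigma2_e)),
        sigma2_R=None if samples.sigma2_R is None else mean2(samples.sigma2_R),
        sigma2_S=None if samples.sigma2_S is None else mean2(samples.sigma2_S),
    )


def compute_dic(samples: PosteriorSamples, data: Dataset):
    """Return (dic, p_d, d_bar) from stored per-iteration deviances."""
    if samples.n_retained == 0:
        raise ValueError("empty sample set")
    d_bar = float(samples.deviance.mean())
    d_hat = deviance(_posterior_mean_state(samples), data)
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d, d_bar


def summarize_posterior(samples: PosteriorSamples,
                        include_effects: bool = True) -> pd.DataFrame:
    """Posterior median and equal-tailed 95% interval per parameter,
    pooled across chains."""
    if samples.n_retained == 0:
        raise ValueError("empty sample set")
    rows = {}
    for name, arr in samples.param_arrays(include_effects=include_effects).items():
        flat = arr.reshape(-1)
        med, lo, hi = np.percentile(flat, [50.0, 2.5, 97.5])
        rows[name] = {"median": med, "q2.5": lo, "q97.5": hi}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class VariancePartition:
    """Area-level share of total variance, in percent."""

    median: float
    lower: float
    upper: float
    mode: str = "per_iteration"


def variance_partition(samples: PosteriorSamples,
                       mode: str = "per_iteration") -> Optional[VariancePartition]:
    """Share (%) of total variance attributable to ward-level effects.

    Returns ``None`` for model forms with no area-level block (reported as
    NA in results tables).
    """
    has_R = samples.sigma2_R is not None
    has_S = samples.S is not None
    if not has_R and not has_S:
        return None
    if mode == "per_iteration":
        v_area = np.zeros_like(samples.sigma2_e)
        if has_R:
            v_area = v_area + samples.sigma2_R
        if has_S:
            v_area = v_area + samples.S.var(axis=2, ddof=1)
        prop = 100.0 * v_area / (v_area + samples.sigma2_e)
        med, lo, hi = np.percentile(prop.reshape(-1), [50.0, 2.5, 97.5])
        return VariancePartition(float(med), float(lo), float(hi), mode)
    if mode == "point":
        v_area = 0.0
        if has_R:
            v_area += float(samples.sigma2_R.mean())
        if has_S:
            v_area += float(samples.S.mean(axis=(0, 1)).var(ddof=1))
        s2e = (samples.fixed_sigma2_e if samples.fixed_sigma2_e is not None
               else float(samples.sigma2_e.mean()))
        p = 100.0 * v_area / (v_area + s2e)
        return VariancePartition(p, float("nan"), float("nan"), mode)
    raise ValueError(f"unknown mode {mode!r}")


def split_rhat(draws: np.ndarray) -> float:
    """Classic potential-scale-reduction statistic on split chains.

    ``draws`` has shape (chains, iterations); each chain is split in half
    so within- and between-half variation are compared even within a
    single chain's trajectory.
    """
    draws = np.asarray(draws, dtype=float)
    C, M = draws.shape
    L = M // 2
    if L < 2:
        raise ValueError("need at least 4 iterations per chain")
    halves = np.concatenate([draws[:, :L], draws[:, M - L:]], axis=0)
    within = halves.var(axis=1, ddof=1)
    W = within.mean()
    if W <= 0:
        return 1.0
    B = L * halves.mean(axis=1).var(ddof=1)
    var_plus = (L - 1) / L * W + B / L
    return float(np.sqrt(var_plus / W))


def gelman_rubin(samples: PosteriorSamples, warn: bool = True) -> pd.Series:
    """Split-R-hat per parameter; warns when any exceeds 1.05."""
    if samples.n_chains < 2:
        raise ValueError(
            "convergence diagnostics need n_chains >= 2; rerun with more chains"
        )
    out = {}
    for name, arr in samples.param_arrays().items():
        if np.ptp(arr) == 0:  # constant (e.g. fixed variance): trivially converged
            out[name] = 1.0
        else:
            out[name] = split_rhat(arr)
    res = pd.Series(out, name="r_hat")
    if warn and (res > 1.05).any():
        bad = res[res > 1.05].index.tolist()
        warnings.warn(f"possible non-convergence (split R-hat > 1.05): {bad}",
                      stacklevel=2)
    return res


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Everything a results-table row set needs for one fitted model."""

    label: str
    dic: float
    p_d: float
    d_bar: float
    parameter_summaries: pd.DataFrame
    variance_proportion: Optional[VariancePartition]
    r_hat: Optional[pd.Series]
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        df = self.parameter_summaries.copy()
        df.insert(0, "model", self.label)
        return df

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index_label="parameter")


def comparison_table(reports: Mapping[str, ModelReport]) -> pd.DataFrame:
    """Six-row (or fewer) model comparison ranked by the ladder order,
    with the DIC minimum flagged."""
    rows = []
    for label, rep in reports.items():
        vp = rep.variance_proportion
        rows.append({
            "model": label,
            "dic": rep.dic,
            "p_d": rep.p_d,
            "d_bar": rep.d_bar,
            "area_var_pct": vp.median if vp is not None else np.nan,
        })
    df = pd.DataFrame(rows)
    df["best"] = df["dic"] == df["dic"].min()
    return df


_TABLE_ROWS = (
    ("DIC", None),
    ("sigma_e", "sigma_e"),
    ("sigma_R", "sigma_R"),
    ("sigma_S", "sigma_S"),
    ("Area-level variance (%)", None),
    ("Age (years)", "beta_age"),
    ("Sex (men vs. women)", "beta_sex_male"),
    ("Other white", "beta_other_white"),
    ("Black Caribbean", "beta_black_caribbean"),
    ("Black African", "beta_black_african"),
    ("Asian", "beta_asian"),
    ("Mixed", "beta_mixed"),
    ("Other ethnicity", "beta_other"),
)


def _fmt(med: float, lo: float, hi: float) -> str:
    g = lambda v: f"{v:.3g}"
    return f"{g(med)} ({g(lo)}, {g(hi)})"


def format_report_table(reports: Mapping[str, ModelReport]) -> str:
    """Human-readable comparison in the conventional layout: one column
    per model, rows for DIC, the three SD components, the area-level
    variance share and the covariate effects; NA where a model form
    excludes a block."""
    labels = list(reports)
    cells = {name: [] for name, _ in _TABLE_ROWS}
    for label in labels:
        rep = reports[label]
        ps = rep.parameter_summaries
        for name, param in _TABLE_ROWS:
            if name == "DIC":
                cells[name].append(f"{rep.dic:.2f}")
            elif name == "Area-level variance (%)":
                vp = rep.variance_proportion
                cells[name].append(
                    "NA" if vp is None else _fmt(vp.median, vp.lower, vp.upper)
                )
            elif param in ps.index:
                row = ps.loc[param]
                cells[name].append(_fmt(row["median"], row["q2.5"], row["q97.5"]))
            else:
                cells[name].append("NA")
    width = max(len(n) for n, _ in _TABLE_ROWS)
    colw = max([len(c) for col in cells.values() for c in col] + [len(l) for l in labels]) + 2
    lines = [" " * width + "".join(l.rjust(colw) for l in labels)]
    for name, _ in _TABLE_ROWS:
        lines.append(name.ljust(width) + "".join(c.rjust(colw) for c in cells[name]))
    return "\n".join(lines) + "\n"
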