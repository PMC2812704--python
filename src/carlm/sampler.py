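"""Gibbs sampler for hierarchical normal models with CAR spatial effects.

The model for log-DUP T_ij of individual j in ward i is

    T_ij = mu_ij + e_ij,        e_ij ~ N(0, sigma_e^2)
    mu_ij = alpha + x_ij' beta + R_i + S_i

with any of the three optional blocks (covariates, exchangeable ward
effects R, ICAR spatial ward effects S) switched on or off by the model
form.  R_i ~ N(0, sigma_R^2) iid; S follows the intrinsic conditional
autoregression: S_i given the rest is normal with mean the average of its
neighbours' effects and variance sigma_S^2 / nu_i.

Every full conditional is conjugate, so one sweep performs exact draws of
the fixed-effect vector (jointly), each R_i, each S_i (sequentially), and
the three variance components.  After the spatial scan, S is recentred to
sum to zero per connected component and the removed mean is absorbed into
the intercept, which keeps the intrinsic model identified.

Priors are minimally informative by default: Normal(0, 100^2) on the fixed
effects and Uniform(0, 100) on each standard deviation; a Gamma(0.001,
0.001) prior on the precisions is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaincinv

from .data import COVARIATE_NAMES, Dataset, ModelSpec, WardGraph

_LOG_2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariancePrior:
    """Prior for one variance component.

    ``uniform_sd`` puts Uniform(0, upper) on the standard deviation —
    the default, as vague gamma priors on precisions are known to be
    sensitive exactly when the true variance is near zero.
    ``gamma_precision`` puts Gamma(shape, rate) on the precision.
    """

    kind: str = "uniform_sd"
    upper: float = 100.0
    shape: float = 0.001
    rate: float = 0.001

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_sd", "gamma_precision"):
            raise ValueError(f"unknown variance prior kind {self.kind!r}")
        if self.upper <= 0 or self.shape <= 0 or self.rate <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the fixed effects and the three variance components."""

    fixed_effect_sd: float = 100.0
    sigma_e: VariancePrior = field(default_factory=VariancePrior)
    sigma_R: VariancePrior = field(default_factory=VariancePrior)
    sigma_S: VariancePrior = field(default_factory=VariancePrior)

    def __post_init__(self) -> None:
        if self.fixed_effect_sd <= 0:
            raise ValueError("fixed_effect_sd must be positive")


def sample_variance(ss: float, df: float, prior: VariancePrior,
                    rng: np.random.Generator) -> float:
    """Draw a variance from its full conditional.

    ``ss`` is the sum of squares appearing in the exponent and ``df`` the
    power of the precision in the likelihood (n for the residual variance,
    K for the exchangeable block, K - c for an ICAR block on a graph with
    c connected components).
    """
    ss = max(float(ss), _VAR_FLOOR)
    if prior.kind == "gamma_precision":
        shape = prior.shape + 0.5 * df
        rate = prior.rate + 0.5 * ss
        tau = rng.gamma(shape, 1.0 / rate)
        return 1.0 / max(tau, _VAR_FLOOR)
    # uniform on the SD: p(sigma^2) ~ (sigma^2)^{-1/2} on (0, upper^2),
    # giving a truncated inverse-gamma((df-1)/2, ss/2) full conditional.
    shape = 0.5 * (df - 1.0)
    if shape <= 0:
        raise ValueError(
            "uniform_sd variance update needs df > 1; "
            f"got df={df} (too few units informing this component)"
        )
    rate = 0.5 * ss
    lo_tau = 1.0 / prior.upper ** 2
    cdf_lo = gammainc(shape, rate * lo_tau)
    u = rng.uniform(cdf_lo, 1.0)
    u = min(u, 1.0 - 1e-16)
    tau = gammaincinv(shape, u) / rate
    return 1.0 / max(tau, _VAR_FLOOR)


# ---------------------------------------------------------------------------
# State and samples containers
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """All model parameters at one MCMC iteration.

    Blocks excluded by the model form are ``None`` (absent, not
    zero-filled).
    """

    alpha: float
    beta: Optional[np.ndarray]
    R: Optional[np.ndarray]
    S: Optional[np.ndarray]
    sigma2_e: float
    sigma2_R: Optional[float]
    sigma2_S: Optional[float]

    def copy(self) -> "ChainState":
        return ChainState(
            self.alpha,
            None if self.beta is None else self.beta.copy(),
            None if self.R is None else self.R.copy(),
            None if self.S is None else self.S.copy(),
            self.sigma2_e, self.sigma2_R, self.sigma2_S,
        )


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, (chains x iterations) per parameter."""

    spec: ModelSpec
    priors: PriorSpec
    seed: int
    n_iter: int
    burn_in: int
    thin: int
    ward_ids: tuple
    alpha: np.ndarray                      # (C, M)
    beta: Optional[np.ndarray]             # (C, M, 8)
    R: Optional[np.ndarray]                # (C, M, K)
    S: Optional[np.ndarray]                # (C, M, K)
    sigma2_e: np.ndarray                   # (C, M)
    sigma2_R: Optional[np.ndarray]
    sigma2_S: Optional[np.ndarray]
    deviance: np.ndarray                   # (C, M)
    fixed_sigma2_e: Optional[float] = None

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_retained(self) -> int:
        return self.alpha.shape[1]

    def param_arrays(self, include_effects: bool = True) -> dict:
        """Scalar parameter name -> (chains x iterations) array.

        Variance components are reported as standard deviations (the scale
        on which results tables are written).
        """
        out = {"alpha": self.alpha}
        if self.beta is not None:
            for k, name in enumerate(COVARIATE_NAMES):
                out[f"beta_{name}"] = self.beta[:, :, k]
        if self.fixed_sigma2_e is None:
            out["sigma_e"] = np.sqrt(self.sigma2_e)
        if self.sigma2_R is not None:
            out["sigma_R"] = np.sqrt(self.sigma2_R)
        if self.sigma2_S is not None:
            out["sigma_S"] = np.sqrt(self.sigma2_S)
        if include_effects:
            if self.R is not None:
                for k, w in enumerate(self.ward_ids):
                    out[f"R_{w}"] = self.R[:, :, k]
            if self.S is not None:
                for k, w in enumerate(self.ward_ids):
                    out[f"S_{w}"] = self.S[:, :, k]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """One row per retained iteration with a chain column."""
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_retained)}
        for name, arr in self.param_arrays().items():
            cols[name] = arr.reshape(-1)
        cols["deviance"] = self.deviance.reshape(-1)
        return pd.DataFrame(cols)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Full conditionals
# ---------------------------------------------------------------------------

def icar_full_conditional(i: int, S: np.ndarray, graph: WardGraph,
                          sigma2_S: float):
    """Prior full conditional of S_i: (mean of neighbours, sigma2_S / nu_i)."""
    ns = graph.neighbours[i]
    if len(ns) == 0:
        raise ValueError(f"ward {graph.wards[i]!r} has no neighbours")
    mean = float(np.mean([S[j] for j in ns]))
    return mean, sigma2_S / len(ns)


def log_likelihood(state: ChainState, data: Dataset) -> float:
    """Gaussian log-likelihood of the data at the given state."""
    if state.sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    mu = np.full(data.n_obs, state.alpha)
    if state.beta is not None:
        if data.covariates is None:
            raise ValueError("state has covariate effects but data has no covariates")
        mu += data.covariates @ state.beta
    if state.R is not None:
        mu += state.R[data.ward_index]
    if state.S is not None:
        mu += state.S[data.ward_index]
    resid = data.response - mu
    n = data.n_obs
    return float(-0.5 * (n * (_LOG_2PI + math.log(state.sigma2_e))
                         + resid @ resid / state.sigma2_e))


def deviance(state: ChainState, data: Dataset) -> float:
    return -2.0 * log_likelihood(state, data)


class _Workspace:
    """Precomputed quantities shared across sweeps of one chain."""

    def __init__(self, data: Dataset, graph: WardGraph, spec: ModelSpec,
                 priors: PriorSpec, allow_isolated: bool = False):
        if graph.n_wards != data.n_wards:
            raise ValueError("graph and dataset disagree on the number of wards")
        if spec.include_covariates and data.covariates is None:
            raise ValueError("model form includes covariates but dataset has none")
        self.data = data
        self.graph = graph
        self.spec = spec
        self.priors = priors
        self.y = data.response
        self.w = data.ward_index
        self.n = data.n_obs
        self.K = graph.n_wards
        self.n_i = data.n_per_ward.astype(float)
        if spec.include_covariates:
            self.M = np.column_stack([np.ones(self.n), data.covariates])
        else:
            self.M = np.ones((self.n, 1))
        self.p = self.M.shape[1]
        self.MtM = self.M.T @ self.M
        self.prior_prec_fixed = np.eye(self.p) / priors.fixed_effect_sd ** 2
        if spec.include_spatial:
            deg = graph.degrees
            isolated = np.flatnonzero(deg == 0)
            if isolated.size and not allow_isolated:
                raise ValueError(
                    f"isolated ward(s) {[graph.wards[i] for i in isolated]} "
                    "under a spatial model form; pass allow_isolated=True to "
                    "pin their spatial effect at zero"
                )
            self.isolated = set(int(i) for i in isolated)
            self.nbr = [np.array(ns, dtype=int) for ns in graph.neighbours]
            self.deg = deg.astype(float)
            self.comp = graph.component_labels
            self.comps = [np.flatnonzero(self.comp == c)
                          for c in range(graph.n_components)]
            self.cases_per_comp = np.array(
                [self.n_i[idx].sum() for idx in self.comps]
            )
            self.edges = graph.edges
            # rank of the ICAR quadratic form: K minus one per component
            self.icar_rank = self.K - graph.n_components
        else:
            self.isolated = set()


def _sweep(state: ChainState, ws: _Workspace, rng: np.random.Generator,
           fixed_sigma2_e: Optional[float]) -> ChainState:
    y, w, n_i = ws.y, ws.w, ws.n_i
    spec, priors = ws.spec, ws.priors
    s2e = state.sigma2_e

    # --- fixed effects: joint conjugate multivariate normal draw ----------
    r = y.copy()
    if state.R is not None:
        r -= state.R[w]
    if state.S is not None:
        r -= state.S[w]
    P = ws.MtM / s2e + ws.prior_prec_fixed
    b = ws.M.T @ r / s2e
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
    z = rng.standard_normal(ws.p)
    gamma = mean + np.linalg.solve(L.T, z)
    state.alpha = float(gamma[0])
    if spec.include_covariates:
        state.beta = gamma[1:].copy()

    fitted_fixed = ws.M @ gamma

    # --- unstructured ward effects ----------------------------------------
    if spec.include_unstructured:
        resid = y - fitted_fixed
        if state.S is not None:
            resid -= state.S[w]
        rs = np.bincount(w, weights=resid, minlength=ws.K)
        prec = n_i / s2e + 1.0 / state.sigma2_R
        mean_R = rs / s2e / prec
        state.R = mean_R + rng.standard_normal(ws.K) / np.sqrt(prec)

    # --- spatial ward effects (sequential scan, then recentring) -----------
    if spec.include_spatial:
        resid = y - fitted_fixed
        if state.R is not None:
            resid -= state.R[w]
        rs = np.bincount(w, weights=resid, minlength=ws.K)
        S = state.S
        s2S = state.sigma2_S
        zs = rng.standard_normal(ws.K)
        for i in range(ws.K):
            if i in ws.isolated:
                S[i] = 0.0
                continue
            prior_prec = ws.deg[i] / s2S
            like_prec = n_i[i] / s2e
            prec_i = prior_prec + like_prec
            m_i = (prior_prec * S[ws.nbr[i]].mean() + rs[i] / s2e) / prec_i
            S[i] = m_i + zs[i] / math.sqrt(prec_i)
        # identifiability: sum-to-zero per component, mean into intercept
        shift = 0.0
        for idx, cases in zip(ws.comps, ws.cases_per_comp):
            if len(idx) == 1 and int(idx[0]) in ws.isolated:
                continue
            mc = S[idx].mean()
            S[idx] -= mc
            shift += mc * cases
        state.alpha += shift / ws.n

    # --- variance components ----------------------------------------------
    mu = np.full(ws.n, state.alpha)
    if state.beta is not None:
        mu += ws.data.covariates @ state.beta
    if state.R is not None:
        mu += state.R[w]
    if state.S is not None:
        mu += state.S[w]
    resid = y - mu

    if fixed_sigma2_e is None:
        state.sigma2_e = sample_variance(resid @ resid, ws.n,
                                         priors.sigma_e, rng)
    if spec.include_unstructured:
        state.sigma2_R = sample_variance(state.R @ state.R, ws.K,
                                         priors.sigma_R, rng)
    if spec.include_spatial:
        S = state.S
        ss_pair = 0.0
        for i, j in ws.edges:
            d = S[i] - S[j]
            ss_pair += d * d
        state.sigma2_S = sample_variance(ss_pair, ws.icar_rank,
                                         priors.sigma_S, rng)
    return state


def gibbs_sweep(state: ChainState, data: Dataset, graph: WardGraph,
                spec: ModelSpec, priors: PriorSpec,
                rng: np.random.Generator,
                fixed_sigma2_e: Optional[float] = None,
                allow_isolated: bool = False) -> ChainState:
    """One full Gibbs scan over all blocks the model form includes.

    Updates, in order: the fixed effects (jointly), each R_i, each S_i
    (likelihood-tilted ICAR conditionals, then sum-to-zero recentring per
    component with the mean absorbed into alpha), then sigma_e^2,
    sigma_R^2, sigma_S^2.  Convenience wrapper that rebuilds the internal
    workspace each call; :func:`run_chain` amortises it.
    """
    ws = _Workspace(data, graph, spec, priors, allow_isolated=allow_isolated)
    new = state.copy()
    _sweep(new, ws, rng, fixed_sigma2_e)
    if not np.isfinite(new.alpha) or not np.isfinite(new.sigma2_e):
        raise RuntimeError(f"non-finite state after sweep: {new}")
    return new


def _initial_state(ws: _Workspace, chain: int,
                   rng: np.random.Generator,
                   fixed_sigma2_e: Optional[float]) -> ChainState:
    """Overdispersed start: least-squares fixed effects jittered by the
    chain index, variances at the residual variance times (0.5, 1, 2)."""
    gamma_hat, *_ = np.linalg.lstsq(ws.M, ws.y, rcond=None)
    resid = ws.y - ws.M @ gamma_hat
    dof = max(ws.n - ws.p, 1)
    s2 = float(resid @ resid) / dof
    s2 = max(s2, 1e-6)
    se_scale = math.sqrt(s2 / max(ws.n, 1))
    gamma = gamma_hat + chain * se_scale * rng.standard_normal(ws.p)
    factor = (0.5, 1.0, 2.0)[chain % 3]
    spec = ws.spec
    return ChainState(
        alpha=float(gamma[0]),
        beta=gamma[1:].copy() if spec.include_covariates else None,
        R=np.zeros(ws.K) if spec.include_unstructured else None,
        S=np.zeros(ws.K) if spec.include_spatial else None,
        sigma2_e=fixed_sigma2_e if fixed_sigma2_e is not None else s2 * factor,
        sigma2_R=s2 * factor * 0.1 if spec.include_unstructured else None,
        sigma2_S=s2 * factor * 0.1 if spec.include_spatial else None,
    )


def run_chain(data: Dataset, graph: WardGraph, spec: ModelSpec,
              priors: Optional[PriorSpec] = None,
              n_iter: int = 30_000, burn_in: int = 10_000, thin: int = 1,
              n_chains: int = 2, seed: int = 0,
              fixed_sigma2_e: Optional[float] = None,
              allow_isolated: bool = False) -> PosteriorSamples:
    """Run the Gibbs sampler and return retained posterior draws.

    ``n_iter`` counts total sweeps per chain; the first ``burn_in`` are
    discarded and the remainder thinned by ``thin``, retaining
    ``(n_iter - burn_in) // thin`` iterations per chain.  The per-iteration
    deviance (-2 log-likelihood, conditional on all ward effects) is stored
    alongside.  Identical seed and configuration give identical output.
    """
    if priors is None:
        priors = PriorSpec()
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    if thin < 1 or n_chains < 1:
        raise ValueError("thin and n_chains must be >= 1")
    ws = _Workspace(data, graph, spec, priors, allow_isolated=allow_isolated)
    n_keep = (n_iter - burn_in) // thin
    if n_keep < 1:
        raise ValueError("no retained iterations with this n_iter/burn_in/thin")

    K, C = ws.K, n_chains
    alpha = np.empty((C, n_keep))
    beta = np.empty((C, n_keep, len(COVARIATE_NAMES))) if spec.include_covariates else None
    R = np.empty((C, n_keep, K)) if spec.include_unstructured else None
    S = np.empty((C, n_keep, K)) if spec.include_spatial else None
    s2e = np.empty((C, n_keep))
    s2R = np.empty((C, n_keep)) if spec.include_unstructured else None
    s2S = np.empty((C, n_keep)) if spec.include_spatial else None
    dev = np.empty((C, n_keep))

    streams = np.random.SeedSequence(seed).spawn(n_chains)
    for c in range(C):
        rng = np.random.default_rng(streams[c])
        state = _initial_state(ws, c, rng, fixed_sigma2_e)
        kept = 0
        for it in range(n_iter):
            _sweep(state, ws, rng, fixed_sigma2_e)
            if it < burn_in or (it - burn_in) % thin != 0 or kept >= n_keep:
                continue
            d = deviance(state, data)
            if not np.isfinite(d):
                raise RuntimeError(
                    f"non-finite deviance at chain {c}, iteration {it}; "
                    f"state snapshot: {state}"
                )
            alpha[c, kept] = state.alpha
            if beta is not None:
                beta[c, kept] = state.beta
            if R is not None:
                R[c, kept] = state.R
            if S is not None:
                S[c, kept] = state.S
            s2e[c, kept] = state.sigma2_e
            if s2R is not None:
                s2R[c, kept] = state.sigma2_R
            if s2S is not None:
                s2S[c, kept] = state.sigma2_S
            dev[c, kept] = d
            kept += 1

    return PosteriorSamples(
        spec=spec, priors=priors, seed=seed, n_iter=n_iter, burn_in=burn_in,
        thin=thin, ward_ids=graph.wards,
        alpha=alpha, beta=beta, R=R, S=S,
        sigma2_e=s2e, sigma2_R=s2R, sigma2_S=s2S, deviance=dev,
        fixed_sigma2_e=fixed_sigma2_e,
    )
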