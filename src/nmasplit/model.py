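"""Bayesian random-effects node-splitting on the log odds-ratio scale.

One-stage binomial-logit NMA model.  For study i with arms k (baseline arm
b_i, the lowest-coded treatment in the study):

    r_ik ~ Binomial(p_ik, n_ik)
    logit(p_ik) = mu_i                    (baseline arm)
    logit(p_ik) = mu_i + delta_ik         (other arms)

The study-level contrasts delta_i = (delta_ik) share a common between-study
standard deviation tau; for multi-arm studies they are jointly normal with
Var(delta_ik) = tau^2 and Cov(delta_ik, delta_il) = tau^2/2, the standard
conditional-normal construction under a common tau.

Splitting comparison (x, y): the two-arm x-y studies inform a free *direct*
parameter d_dir (their contrast mean), while every other study keeps the
consistency parameterisation, mean(delta_ik) = d[t_k] - d[t_b], with basic
parameters d relative to a reference treatment.  The *indirect* estimate is
the consistency functional d_ind = d[y] - d[x] and the inconsistency factor
IF = d_dir - d_ind, computed per draw.  Multi-arm studies that contain both
x and y stay intact on the network side: diverting their x-y contrast would
leave the indirect functional without a likelihood path in networks where
such a study is the only extra evidence (see enumerate_split_nodes).

Priors: vague normals N(0, effect_prior_sd^2) on baselines and basic
parameters (and d_dir); an empirical log-normal prior on tau^2, selectable
by outcome / treatment-comparison type (location and scale are
configuration because published empirical values vary by family).

Sampling is Metropolis-within-Gibbs: vectorised random-walk updates for the
baselines and the per-study contrast blocks, an exact multivariate-normal
Gibbs draw for (d, d_dir) (conjugate given the contrasts and tau), and a
random-walk update for log tau.  Proposal scales adapt toward standard
acceptance targets during burn-in only and are frozen afterwards, keeping
the post-burn-in chain Markovian.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .data import NMADataset
from .geometry import SplitNode, build_network, enumerate_split_nodes
from .kld import KLDTriple, interpretation_index

logger = logging.getLogger("nmasplit")

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PosteriorSummary",
    "NodeSplitResult",
    "specify_model",
    "run_node_split",
    "run_all_nodes",
    "gelman_rubin",
    "EMPIRICAL_TAU2_PRIORS",
]

#: published empirical predictive log-normal distributions for tau^2
#: (location, scale on the log scale), keyed by (comparison type, outcome
#: type).  Values are configuration, selectable per analysis.
EMPIRICAL_TAU2_PRIORS: dict[tuple[str, str], tuple[float, float]] = {
    ("pharma_vs_placebo", "semi_objective"): (-2.56, 1.74),
    ("pharma_vs_placebo", "subjective"): (-2.56, 1.74),
    ("pharma_vs_placebo", "objective"): (-3.50, 1.74),
    ("pharma_vs_pharma", "semi_objective"): (-3.02, 1.85),
    ("pharma_vs_pharma", "subjective"): (-3.02, 1.85),
    ("pharma_vs_pharma", "objective"): (-3.95, 1.85),
    ("non_pharma", "semi_objective"): (-2.13, 1.58),
    ("non_pharma", "subjective"): (-2.13, 1.58),
    ("non_pharma", "objective"): (-3.07, 1.58),
}


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the node-splitting model.

    tau2_family:
        ``"lognormal"`` (on tau^2; params = location, scale of log tau^2) or
        ``"halfnormal"`` (on tau; params = (scale,)).
    """

    tau2_family: str = "lognormal"
    tau2_params: tuple[float, ...] = (-2.56, 1.74)
    effect_prior_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.effect_prior_sd <= 0:
            raise ValueError("effect_prior_sd must be positive")
        if self.tau2_family not in ("lognormal", "halfnormal"):
            raise ValueError("tau2_family must be 'lognormal' or 'halfnormal'")
        if self.tau2_family == "lognormal" and len(self.tau2_params) != 2:
            raise ValueError("lognormal tau2 prior needs (location, scale)")
        if self.tau2_family == "halfnormal" and len(self.tau2_params) != 1:
            raise ValueError("halfnormal tau prior needs (scale,)")
        if self.tau2_family == "lognormal" and self.tau2_params[1] <= 0:
            raise ValueError("lognormal scale must be positive")

    @classmethod
    def empirical(
        cls, comparison_type: str, outcome_type: str, effect_prior_sd: float = 100.0
    ) -> "PriorSpec":
        """Empirical tau^2 prior for an outcome / comparison-type family."""
        key = (comparison_type, outcome_type)
        if key not in EMPIRICAL_TAU2_PRIORS:
            raise KeyError(f"no empirical prior recorded for {key}")
        return cls(
            tau2_family="lognormal",
            tau2_params=EMPIRICAL_TAU2_PRIORS[key],
            effect_prior_sd=effect_prior_sd,
        )

    def log_prior_log_tau(self, lam: float | np.ndarray) -> float | np.ndarray:
        """Log prior density of lambda = log(tau), up to a constant."""
        if self.tau2_family == "lognormal":
            loc, scale = self.tau2_params
            # log tau^2 = 2*lambda ~ N(loc, scale^2)
            return -0.5 * ((2.0 * lam - loc) / scale) ** 2
        (s,) = self.tau2_params
        tau = np.exp(lam)
        # half-normal density on tau, times the Jacobian dtau/dlambda = tau
        return -0.5 * (tau / s) ** 2 + lam


@dataclass(frozen=True)
class MCMCSettings:
    """Chain geometry.  Defaults: 3 chains, 20000 iterations, 2000 burn-in,
    thinning at 10 (kept draws are post-burn-in iterations that are
    multiples of ``thin``)."""

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the convergence diagnostic")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class PosteriorSummary:
    """Summary of one monitored scalar."""

    mean: float
    sd: float
    median: float
    q025: float
    q975: float
    rhat: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("posterior sd must be positive")
        if not (self.q025 <= self.median <= self.q975):
            raise ValueError("quantiles must be ordered")


@dataclass(frozen=True)
class NodeSplitResult:
    """Posteriors for one split node, plus the KLD triple."""

    node: SplitNode
    direct: PosteriorSummary
    indirect: PosteriorSummary
    inconsistency_factor: PosteriorSummary
    tau: PosteriorSummary
    kld: KLDTriple | None = None
    converged: bool = True
    draws: dict[str, np.ndarray] | None = field(default=None, compare=False)

    @property
    def max_rhat(self) -> float:
        return max(
            self.direct.rhat,
            self.indirect.rhat,
            self.inconsistency_factor.rhat,
            self.tau.rhat,
        )


# --------------------------------------------------------------------------
# Model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Compiled node-splitting model for one dataset and split node.

    Index arrays and design matrices for the sampler; treatments are coded
    by sorted label, effects are log odds ratios of the higher- versus the
    lower-coded treatment of each contrast.
    """

    node: SplitNode
    treatments: tuple[str, ...]
    reference: str
    n_studies: int
    # per non-baseline arm (aligned with the contrast vector delta)
    nb_events: np.ndarray
    nb_n: np.ndarray
    nb_study: np.ndarray
    # per baseline arm (one per study)
    base_events: np.ndarray
    base_n: np.ndarray
    # contrast design: mean(delta) = X @ theta, theta = (d[1..T-1], d_dir)
    X: np.ndarray
    # per-study contrast-block dimension k_i = arms_i - 1
    k_by_study: np.ndarray
    direct_coord: int
    x_coord: int  # column of d[x] in theta, -1 if x is the reference
    y_coord: int

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def describe(self) -> str:
        d_names = [f"d[{t}]" for t in self.treatments[1:]]
        ind = []
        if self.y_coord >= 0:
            ind.append(f"d[{self.node.comparison[1]}]")
        if self.x_coord >= 0:
            ind.append(f"-d[{self.node.comparison[0]}]")
        return (
            f"node-split {self.node.label}: {self.n_studies} studies, "
            f"basic parameters {{{', '.join(d_names)}}} (reference "
            f"{self.reference}), free d_dir, d_ind = {' '.join(ind) or '0'}"
        )


def specify_model(
    ds: NMADataset, node: SplitNode, prior: PriorSpec | None = None
) -> ModelSpec:
    """Compile the node-splitting model for ``node``.

    Raises ``ValueError`` if the node is not splittable in this dataset.
    """
    net = build_network(ds)
    valid = {n.comparison for n in enumerate_split_nodes(net)}
    if node.comparison not in valid:
        raise ValueError(f"comparison {node.label} is not splittable here")
    treatments = tuple(ds.treatments)
    code = {t: i for i, t in enumerate(treatments)}
    x, y = node.comparison
    designs = ds.study_treatments()
    frame = ds.frame
    arm_of = {
        (r.study, r.treatment): (int(r.events), int(r.sample_size))
        for r in frame.itertuples(index=False)
    }
    P = len(treatments)  # T-1 basic parameters + d_dir
    direct_coord = P - 1

    nb_e, nb_n, nb_study, rows = [], [], [], []
    base_e, base_n, k_by_study = [], [], []
    for si, study in enumerate(sorted(designs)):
        design = designs[study]
        severed = design == (x, y) if x <= y else design == (y, x)
        base = design[0]
        e, n = arm_of[(study, base)]
        base_e.append(e)
        base_n.append(n)
        k_by_study.append(len(design) - 1)
        for t in design[1:]:
            e, n = arm_of[(study, t)]
            nb_e.append(e)
            nb_n.append(n)
            nb_study.append(si)
            row = np.zeros(P)
            if severed:
                row[direct_coord] = 1.0
            else:
                if code[t] > 0:
                    row[code[t] - 1] = 1.0
                if code[base] > 0:
                    row[code[base] - 1] = -1.0
            rows.append(row)
    return ModelSpec(
        node=node,
        treatments=treatments,
        reference=treatments[0],
        n_studies=len(designs),
        nb_events=np.array(nb_e, dtype=float),
        nb_n=np.array(nb_n, dtype=float),
        nb_study=np.array(nb_study, dtype=np.intp),
        base_events=np.array(base_e, dtype=float),
        base_n=np.array(base_n, dtype=float),
        X=np.vstack(rows),
        k_by_study=np.array(k_by_study, dtype=np.intp),
        direct_coord=direct_coord,
        x_coord=code[x] - 1,
        y_coord=code[y] - 1,
    )


# --------------------------------------------------------------------------
# Sampler internals
# --------------------------------------------------------------------------

def _loglik_arms(e: np.ndarray, n: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Binomial-logit log likelihood per arm, up to constants."""
    return e * eta - n * np.logaddexp(0.0, eta)


class _NodeSplitSampler:
    """One-chain Metropolis-within-Gibbs for a compiled model."""

    def __init__(self, spec: ModelSpec, prior: PriorSpec, rng: np.random.Generator):
        self.spec = spec
        self.prior = prior
        self.rng = rng
        S = spec.n_studies
        M = len(spec.nb_events)
        k = spec.k_by_study
        # prior precision structure of the contrast blocks:
        #   Sigma_i = tau^2/2 (I + J)  =>  Sigma_i^{-1} = (1/tau^2) * M_i,
        #   M_i = 2 (I - J/(k_i+1)),  log|Sigma_i| = k_i log(tau^2/2)+log(k_i+1)
        starts = np.concatenate([[0], np.cumsum(k)])
        self.block = [slice(starts[i], starts[i + 1]) for i in range(S)]
        W = np.empty_like(spec.X)
        for i in range(S):
            ki = k[i]
            Mi = 2.0 * (np.eye(ki) - np.ones((ki, ki)) / (ki + 1))
            W[self.block[i]] = Mi @ spec.X[self.block[i]]
        self.W = W
        self.A = spec.X.T @ W  # sum_i X_i' M_i X_i
        self.kvec_per_delta = k[spec.nb_study].astype(float)
        self.k = k.astype(float)
        self.sum_k = float(k.sum())
        # initial values from empirical logits
        mu0 = _logit((spec.base_events + 0.5) / (spec.base_n + 1.0))
        eta0 = _logit((spec.nb_events + 0.5) / (spec.nb_n + 1.0))
        self.mu = mu0 + 0.1 * rng.standard_normal(S)
        self.delta = (eta0 - mu0[spec.nb_study]) + 0.1 * rng.standard_normal(M)
        XtX = spec.X.T @ spec.X + 1e-6 * np.eye(spec.n_params)
        self.theta = np.linalg.solve(XtX, spec.X.T @ self.delta)
        self.theta += 0.1 * rng.standard_normal(spec.n_params)
        self.lam = math.log(0.15) + 0.2 * rng.standard_normal()
        # adaptive proposal scales (frozen after burn-in)
        self.s_mu = np.full(S, 0.3)
        self.s_delta = np.full(S, 0.3)
        self.s_lam = 0.5
        self._acc_mu = np.zeros(S)
        self._acc_delta = np.zeros(S)
        self._acc_lam = 0.0
        self._batch = 0

    # -- updates ------------------------------------------------------------

    def _update_mu(self) -> None:
        sp, rng = self.spec, self.rng
        prop = self.mu + self.s_mu * rng.standard_normal(len(self.mu))
        d_base = _loglik_arms(sp.base_events, sp.base_n, prop) - _loglik_arms(
            sp.base_events, sp.base_n, self.mu
        )
        eta_cur = self.mu[sp.nb_study] + self.delta
        eta_prop = prop[sp.nb_study] + self.delta
        d_nb = _loglik_arms(sp.nb_events, sp.nb_n, eta_prop) - _loglik_arms(
            sp.nb_events, sp.nb_n, eta_cur
        )
        d_ll = d_base + np.bincount(sp.nb_study, d_nb, minlength=len(self.mu))
        v0 = self.prior.effect_prior_sd**2
        d_ll += -(prop**2 - self.mu**2) / (2.0 * v0)
        acc = np.log(rng.random(len(self.mu))) < d_ll
        self.mu = np.where(acc, prop, self.mu)
        self._acc_mu += acc

    def _prior_quad_by_study(self, resid: np.ndarray) -> np.ndarray:
        """q_i = 2 (r_i'r_i - (1'r_i)^2/(k_i+1)); Sigma^-1 = M_i / tau^2."""
        S = self.spec.n_studies
        sr2 = np.bincount(self.spec.nb_study, resid**2, minlength=S)
        sr = np.bincount(self.spec.nb_study, resid, minlength=S)
        return 2.0 * (sr2 - sr**2 / (self.k + 1.0))

    def _update_delta(self, tau2: float) -> None:
        sp, rng = self.spec, self.rng
        prop = self.delta + self.s_delta[sp.nb_study] * rng.standard_normal(
            len(self.delta)
        )
        eta_cur = self.mu[sp.nb_study] + self.delta
        eta_prop = self.mu[sp.nb_study] + prop
        d_nb = _loglik_arms(sp.nb_events, sp.nb_n, eta_prop) - _loglik_arms(
            sp.nb_events, sp.nb_n, eta_cur
        )
        d_ll = np.bincount(sp.nb_study, d_nb, minlength=sp.n_studies)
        m = sp.X @ self.theta
        dq = self._prior_quad_by_study(prop - m) - self._prior_quad_by_study(
            self.delta - m
        )
        d_ll += -dq / (2.0 * tau2)
        acc = np.log(rng.random(sp.n_studies)) < d_ll
        self.delta = np.where(acc[sp.nb_study], prop, self.delta)
        self._acc_delta += acc

    def _update_theta(self, tau2: float) -> None:
        sp = self.spec
        v0 = self.prior.effect_prior_sd**2
        prec = self.A / tau2 + np.eye(sp.n_params) / v0
        b = self.W.T @ self.delta / tau2
        L = np.linalg.cholesky(prec)
        half = solve_triangular(L, b, lower=True)
        mean = solve_triangular(L.T, half, lower=False)
        z = self.rng.standard_normal(sp.n_params)
        self.theta = mean + solve_triangular(L.T, z, lower=False)

    def _update_lam(self) -> None:
        rng = self.rng
        prop = self.lam + self.s_lam * rng.standard_normal()
        resid = self.delta - self.spec.X @ self.theta
        Q = float(self._prior_quad_by_study(resid).sum())
        def logpost(lam: float) -> float:
            tau2 = math.exp(2.0 * lam)
            return (
                -self.sum_k * lam
                - 0.5 * Q / tau2
                + float(self.prior.log_prior_log_tau(lam))
            )
        if math.log(rng.random()) < logpost(prop) - logpost(self.lam):
            self.lam = prop
            self._acc_lam += 1.0

    def _adapt(self, batch_size: int) -> None:
        self._batch += 1
        step = min(0.25, self._batch**-0.5)
        for scales, acc, target in (
            (self.s_mu, self._acc_mu, 0.44),
            (self.s_delta, self._acc_delta, 0.35),
        ):
            rate = acc / batch_size
            scales *= np.exp(np.where(rate > target, step, -step))
            acc[:] = 0.0
        rate = self._acc_lam / batch_size
        self.s_lam *= math.exp(step if rate > 0.44 else -step)
        self._acc_lam = 0.0

    # -- driver -------------------------------------------------------------

    def run(self, mcmc: MCMCSettings) -> dict[str, np.ndarray]:
        sp = self.spec
        n_kept = mcmc.n_kept
        out = {
            name: np.empty(n_kept)
            for name in ("direct", "indirect", "if_", "tau")
        }
        kept = 0
        batch = 50
        for it in range(1, mcmc.n_iter + 1):
            tau2 = math.exp(2.0 * self.lam)
            self._update_mu()
            self._update_delta(tau2)
            self._update_theta(tau2)
            self._update_lam()
            if it <= mcmc.burn_in and it % batch == 0:
                self._adapt(batch)
            if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                direct = self.theta[sp.direct_coord]
                d_y = self.theta[sp.y_coord] if sp.y_coord >= 0 else 0.0
                d_x = self.theta[sp.x_coord] if sp.x_coord >= 0 else 0.0
                indirect = d_y - d_x
                out["direct"][kept] = direct
                out["indirect"][kept] = indirect
                out["if_"][kept] = direct - indirect
                out["tau"][kept] = math.exp(self.lam)
                kept += 1
        for name, arr in out.items():
            if not np.all(np.isfinite(arr)):
                raise RuntimeError(
                    f"sampler produced non-finite draws for {name!r}"
                )
        return out


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


# --------------------------------------------------------------------------
# Diagnostics
# --------------------------------------------------------------------------

def gelman_rubin(chains: Sequence[np.ndarray], method: str = "classic") -> float:
    """Potential scale reduction factor R-hat.

    ``classic``: between/within-chain variance ratio on the chains as given,
    R-hat = sqrt(((n-1)/n * W + B/n) / W).  ``split`` halves every chain
    first (detects within-chain drift).  Requires >= 2 chains of equal
    length >= 10.
    """
    arrs = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(arrs) < 2:
        raise ValueError("R-hat needs at least two chains")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("chains must have equal length")
    if method == "split":
        half = n // 2
        arrs = [a[:half] for a in arrs] + [a[half: 2 * half] for a in arrs]
        n = half
    elif method != "classic":
        raise ValueError("method must be 'classic' or 'split'")
    if n < 10:
        raise ValueError("chains too short for R-hat (need length >= 10)")
    x = np.stack(arrs)  # (m, n)
    m = x.shape[0]
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)  # = B / n
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else math.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(math.sqrt(var_hat / W))


def _summarise(pooled: np.ndarray, per_chain: np.ndarray, rhat_method: str) -> PosteriorSummary:
    q025, med, q975 = np.quantile(pooled, [0.025, 0.5, 0.975])
    return PosteriorSummary(
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        median=float(med),
        q025=float(q025),
        q975=float(q975),
        rhat=gelman_rubin(list(per_chain), method=rhat_method),
    )


# --------------------------------------------------------------------------
# Drivers
# --------------------------------------------------------------------------

def run_node_split(
    ds: NMADataset,
    node: SplitNode,
    prior: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    rhat_method: str = "classic",
    keep_draws: bool = False,
    _seed_key: tuple[int, ...] = (),
) -> NodeSplitResult:
    """Fit the node-splitting model for one split node.

    Chains are seeded deterministically from ``mcmc.seed``; summaries pool
    the post-burn-in, thinned draws of all chains.  A result with any
    monitored R-hat >= 1.1 is returned flagged ``converged=False`` (and
    logged), never silently accepted.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or MCMCSettings()
    spec = specify_model(ds, node, prior)
    names = ("direct", "indirect", "if_", "tau")
    per_chain = {name: [] for name in names}
    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence((mcmc.seed, *_seed_key, chain))
        )
        draws = _NodeSplitSampler(spec, prior, rng).run(mcmc)
        for name in names:
            per_chain[name].append(draws[name])
    pooled = {name: np.concatenate(per_chain[name]) for name in names}
    summaries = {
        name: _summarise(pooled[name], np.stack(per_chain[name]), rhat_method)
        for name in names
    }
    direct, indirect = summaries["direct"], summaries["indirect"]
    result = NodeSplitResult(
        node=node,
        direct=direct,
        indirect=indirect,
        inconsistency_factor=summaries["if_"],
        tau=summaries["tau"],
        kld=interpretation_index(direct, indirect),
        converged=max(s.rhat for s in summaries.values()) < 1.1,
        draws=pooled if keep_draws else None,
    )
    if not result.converged:
        logger.warning(
            "run_node_split %s: max R-hat %.3f >= 1.1 (flagged non-converged)",
            node.label,
            result.max_rhat,
        )
    return result


def run_all_nodes(
    ds: NMADataset,
    prior: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    rhat_method: str = "classic",
    keep_draws: bool = False,
) -> list[NodeSplitResult]:
    """Node-splitting for every split node of the network.

    Per-node chains derive their seeds deterministically from the master
    seed and the node's position in the (sorted, deterministic) node list.
    Returns an empty list (with a warning) when nothing is splittable.
    """
    mcmc = mcmc or MCMCSettings()
    nodes = enumerate_split_nodes(build_network(ds))
    if not nodes:
        logger.warning("run_all_nodes: network has no split nodes")
        return []
    results = []
    for i, node in enumerate(nodes):
        try:
            results.append(
                run_node_split(
                    ds,
                    node,
                    prior,
                    mcmc,
                    rhat_method=rhat_method,
                    keep_draws=keep_draws,
                    _seed_key=(i,),
                )
            )
        except Exception as exc:
            raise RuntimeError(f"node {node.label}: {exc}") from exc
        logger.info(
            "run_all_nodes: %s IF mean %.3f, D^j %.3f, max R-hat %.3f",
            node.label,
            results[-1].inconsistency_factor.mean,
            results[-1].kld.index,
            results[-1].max_rhat,
        )
    return results
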