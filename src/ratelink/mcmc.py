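"""Fixed-topology Bayesian inference of branch rates under relaxed clocks.

Metropolis-within-Gibbs sampling of per-branch rates (lognormal or
exponential uncorrelated clocks, linked or unlinked across the two data
partitions), partition mean-rate scalars, clock hyperparameters, and
(optionally) internal node times under a birth-death prior. Likelihoods
use the pruning engines from :mod:`ratelink.likelihood`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .likelihood import _alignment_engine, _character_engine
from .models import MorphModelParams, NucModelParams
from .synthetic import Alignment, CharacterMatrix, MOL_MEAN_RATE, MORPH_MEAN_RATE
from .trees import Chronogram

__all__ = [
    "ClockModelSpec",
    "McmcSettings",
    "PosteriorSamples",
    "BranchRateSummary",
    "run_mcmc",
    "effective_sample_size",
    "summarize_branch_rates",
]

PARTITIONS = ("mol", "morph")


@dataclass(frozen=True)
class ClockModelSpec:
    """Relaxed-clock configuration for the two data partitions.

    ``linked`` shares one set of branch-rate multipliers between
    partitions (each keeping its own mean-rate scalar); ``unlinked`` gives
    each partition an independent set.
    """

    family: str = "lognormal"
    linkage: str = "unlinked"

    def __post_init__(self):
        if self.family not in ("lognormal", "exponential"):
            raise ValueError(f"unknown clock family {self.family!r}")
        if self.linkage not in ("linked", "unlinked"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass(frozen=True)
class McmcSettings:
    """Chain-control settings (desk-scale defaults)."""

    chain_length: int = 200_000
    n_chains: int = 2
    thin: int = 100
    burnin_fraction: float = 0.10
    ess_threshold: float = 200.0
    seed: int = 0
    estimate_times: bool = False
    adapt: bool = True

    def __post_init__(self):
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.ess_threshold <= 0:
            raise ValueError("ess_threshold must be positive")


@dataclass
class PosteriorSamples:
    """MCMC traces: ``traces[name]`` has shape (n_chains, n_samples)."""

    traces: dict
    settings: McmcSettings
    clock: ClockModelSpec
    durations: np.ndarray  # generating branch durations (fixed-times runs)
    edge_ids: np.ndarray  # child-node ids of sampled branches
    low_ess: list = field(default_factory=list)

    def pooled(self, name: str, burnin_fraction: float = None) -> np.ndarray:
        """Chain-pooled post-burn-in samples of one parameter."""
        bf = self.settings.burnin_fraction if burnin_fraction is None else burnin_fraction
        t = self.traces[name]
        start = int(math.floor(bf * t.shape[1]))
        return t[:, start:].reshape(-1)


@dataclass
class BranchRateSummary:
    """Per-branch posterior mean/median rates plus branch durations (Myr)."""

    edge_ids: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    durations: np.ndarray


# ---------------------------------------------------------------------------
# priors (densities on log-transformed parameters, Jacobian included)


def _logn_logpdf(y, m, s):
    # y = log x, x ~ LogNormal(m, s)  =>  y ~ Normal(m, s)
    return -0.5 * ((y - m) / s) ** 2 - math.log(s) - 0.5 * math.log(2 * math.pi)


def _exp_logpdf_log(y, rate=1.0):
    # y = log x, x ~ Exponential(rate): log density + Jacobian e^y
    return math.log(rate) - rate * math.exp(y) + y


class _ClockState:
    """Mutable sampler state with cached per-partition log-likelihoods."""

    def __init__(self, engines, durations, clock: ClockModelSpec, priors, rng,
                 likelihood_on=True, init=None, fix=None, topology=None, ages=None,
                 estimate_times=False):
        self.engines = engines  # partition -> PruningEngine or None
        self.durations = np.asarray(durations, dtype=float)
        self.clock = clock
        self.priors = priors
        self.rng = rng
        self.likelihood_on = likelihood_on
        self.n_edges = len(durations)
        self.topology = topology
        self.estimate_times = bool(estimate_times)
        self.ages = None if ages is None else np.asarray(ages, dtype=float).copy()
        self.log_bdlam = math.log(priors.get("bd_lambda_init", 0.05))
        fix = fix or {}
        rate_sets = ["shared"] if clock.linkage == "linked" else list(PARTITIONS)
        self.rate_sets = rate_sets
        # log-scale parameters
        self.log_r = {rs: np.zeros(self.n_edges) for rs in rate_sets}
        self.log_c = {p: math.log(priors[f"c_{p}_init"]) for p in PARTITIONS}
        self.log_sigma = {rs: math.log(0.5) for rs in rate_sets}
        if init:
            for key, val in init.items():
                self.set_param(key, val)
        self.fixed = set(fix)
        for key, val in fix.items():
            self.set_param(key, val)
        self.update_order = self._param_names()
        # non-centered sigma moves: propose sigma and rescale the whole rate
        # set jointly (rate-prior and Jacobian terms cancel), which avoids
        # the funnel between sigma and its rates
        self.extra_moves = []
        if clock.family == "lognormal":
            for rs in rate_sets:
                if f"sigma_{rs}" in self.fixed:
                    continue
                if any(f"r_{rs}_{e}" in self.fixed for e in range(self.n_edges)):
                    continue
                self.extra_moves.append(f"sigscale_{rs}")
        # scalars (c, sigma, bdlam) mix slowly under uniform random-scan;
        # give them extra update weight relative to the many branch rates
        scalars = [n for n in self.update_order
                   if n.startswith(("c_", "sigma_")) or n == "bdlam"] + self.extra_moves
        self.update_pool = self.update_order + self.extra_moves + scalars * max(
            1, self.n_edges // 8
        )
        self._lnl = {p: None for p in PARTITIONS}
        all_names = self.update_order + self.extra_moves
        self.scales = {name: 0.5 for name in all_names}
        self.accepts = {name: [0, 0] for name in all_names}

    # -- parameter access ---------------------------------------------------

    def _param_names(self):
        names = []
        for rs in self.rate_sets:
            names += [f"r_{rs}_{e}" for e in range(self.n_edges)]
            if self.clock.family == "lognormal":
                names.append(f"sigma_{rs}")
        names += [f"c_{p}" for p in PARTITIONS]
        if self.estimate_times:
            top = self.topology
            names += [
                f"age_{v}"
                for v in range(top.n_nodes)
                if not top.is_tip(v) and top.parent[v] >= 0
            ]
            names.append("bdlam")
        return [n for n in names if n not in getattr(self, "fixed", set())]

    def get_param(self, name: str) -> float:
        if name == "bdlam":
            return self.log_bdlam
        kind, rest = name.split("_", 1)
        if kind == "r":
            rs, e = rest.rsplit("_", 1)
            return self.log_r[rs][int(e)]
        if kind == "sigma":
            return self.log_sigma[rest]
        if kind == "c":
            return self.log_c[rest]
        if kind == "age":
            return self.ages[int(rest)]
        raise KeyError(name)

    def set_param(self, name: str, value: float):
        if name == "bdlam":
            self.log_bdlam = value
            return
        kind, rest = name.split("_", 1)
        if kind == "r":
            rs, e = rest.rsplit("_", 1)
            self.log_r[rs][int(e)] = value
        elif kind == "sigma":
            self.log_sigma[rest] = value
        elif kind == "c":
            self.log_c[rest] = value
        elif kind == "age":
            self.ages[int(rest)] = value
        else:
            raise KeyError(name)

    def partitions_of(self, name: str):
        if name == "bdlam":
            return ()
        kind, rest = name.split("_", 1)
        if kind == "age":
            return PARTITIONS
        if kind == "c":
            return (rest,)
        rs = rest.rsplit("_", 1)[0] if kind == "r" else rest
        return PARTITIONS if rs == "shared" else (rs,)

    # -- node ages ----------------------------------------------------------

    def _age_bounds(self, v: int):
        top = self.topology
        lo = max(self.ages[c] for c in top.children[v])
        hi = self.ages[top.parent[v]]
        return lo, hi

    def _age_logprior_node(self, t: float) -> float:
        lam = math.exp(self.log_bdlam)
        t_root = self.ages[self.topology.root]
        return math.log(lam) - lam * t - math.log1p(-math.exp(-lam * t_root))

    def _age_logprior_all(self) -> float:
        top = self.topology
        return sum(
            self._age_logprior_node(self.ages[v])
            for v in range(top.n_nodes)
            if not top.is_tip(v) and top.parent[v] >= 0
        )

    def rate_set_for(self, partition: str) -> str:
        return "shared" if self.clock.linkage == "linked" else partition

    # -- densities ----------------------------------------------------------

    def current_durations(self) -> np.ndarray:
        if self.estimate_times:
            par = np.asarray(self.topology.parent)[self.edge_index]
            return self.ages[par] - self.ages[self.edge_index]
        return self.durations

    def edge_lengths(self, partition: str) -> np.ndarray:
        r = np.exp(self.log_r[self.rate_set_for(partition)])
        return self.current_durations() * math.exp(self.log_c[partition]) * r

    def branch_rates(self, partition: str) -> np.ndarray:
        """Rates in natural units (per Myr)."""
        return math.exp(self.log_c[partition]) * np.exp(self.log_r[self.rate_set_for(partition)])

    def loglik(self, partition: str) -> float:
        if not self.likelihood_on or self.engines.get(partition) is None:
            return 0.0
        if self._lnl[partition] is None:
            eng = self.engines[partition]
            self._lnl[partition] = eng.loglik(self._full_edge_vector(partition, eng))
        return self._lnl[partition]

    def _full_edge_vector(self, partition, engine):
        # engines index edges by child node over all nodes; map edge params
        vec = np.zeros(engine.top.n_nodes)
        vec[self.edge_index] = self.edge_lengths(partition)
        return vec

    def invalidate(self, partitions):
        for p in partitions:
            self._lnl[p] = None

    def log_prior_param(self, name: str) -> float:
        y = self.get_param(name)
        kind, rest = name.split("_", 1)
        if kind == "r":
            rs = rest.rsplit("_", 1)[0]
            if self.clock.family == "lognormal":
                s = math.exp(self.log_sigma[rs])
                return _logn_logpdf(y, -0.5 * s * s, s)
            return _exp_logpdf_log(y)
        if kind == "sigma":
            return _exp_logpdf_log(y, rate=self.priors["sigma_rate"])
        if kind == "c":
            return _logn_logpdf(y, self.priors["c_meanlog"], self.priors["c_sdlog"])
        raise KeyError(name)

    def log_prior_rates(self, rs: str) -> float:
        y = self.log_r[rs]
        if self.clock.family == "lognormal":
            s = math.exp(self.log_sigma[rs])
            return float(np.sum(-0.5 * ((y + 0.5 * s * s) / s) ** 2) - len(y) * (math.log(s) + 0.5 * math.log(2 * math.pi)))
        return float(np.sum(y - np.exp(y)))

    def log_posterior_full(self) -> float:
        lp = sum(self.loglik(p) for p in PARTITIONS)
        for rs in self.rate_sets:
            lp += self.log_prior_rates(rs)
            if self.clock.family == "lognormal" and f"sigma_{rs}" not in self.fixed:
                lp += self.log_prior_param(f"sigma_{rs}")
        for p in PARTITIONS:
            if f"c_{p}" not in self.fixed:
                lp += self.log_prior_param(f"c_{p}")
        if self.estimate_times:
            lp += self._age_logprior_all() + _exp_logpdf_log(self.log_bdlam)
        return lp

    # -- single-parameter Metropolis update ---------------------------------

    def step(self, name: str):
        if name.startswith("sigscale_"):
            return self._sigscale_step(name)
        old = self.get_param(name)
        parts = self.partitions_of(name)
        old_lnl = {p: self.loglik(p) for p in parts}
        if name == "bdlam":
            old_target = _exp_logpdf_log(old) + self._age_logprior_all()
            prop = old + self.scales[name] * self.rng.standard_normal()
            self.set_param(name, prop)
            new_target = _exp_logpdf_log(prop) + self._age_logprior_all()
            acc = self.accepts[name]
            acc[1] += 1
            if math.log(self.rng.random() + 1e-300) < new_target - old_target:
                acc[0] += 1
                return True
            self.set_param(name, old)
            return False
        if name.startswith("age_"):
            v = int(name.split("_", 1)[1])
            lo, hi = self._age_bounds(v)
            if hi - lo <= 0:
                return False
            old_target = self._age_logprior_node(old) + sum(old_lnl.values())
            prop = lo + (hi - lo) * self.rng.random()  # symmetric within fixed bounds
            self.set_param(name, prop)
            self.invalidate(parts)
            new_target = self._age_logprior_node(prop) + sum(self.loglik(p) for p in parts)
            acc = self.accepts[name]
            acc[1] += 1
            if math.log(self.rng.random() + 1e-300) < new_target - old_target:
                acc[0] += 1
                return True
            self.set_param(name, old)
            for p in parts:
                self._lnl[p] = old_lnl[p]
            return False
        if name.startswith("sigma"):
            rs = name.split("_", 1)[1]
            old_target = self.log_prior_param(name) + self.log_prior_rates(rs)
        else:
            old_target = self.log_prior_param(name) + sum(old_lnl.values())
        prop = old + self.scales[name] * self.rng.standard_normal()
        self.set_param(name, prop)
        if name.startswith("sigma"):
            rs = name.split("_", 1)[1]
            new_target = self.log_prior_param(name) + self.log_prior_rates(rs)
        else:
            self.invalidate(parts)
            new_target = self.log_prior_param(name) + sum(self.loglik(p) for p in parts)
        acc = self.accepts[name]
        acc[1] += 1
        if math.log(self.rng.random() + 1e-300) < new_target - old_target:
            acc[0] += 1
            return True
        self.set_param(name, old)
        if not name.startswith("sigma"):
            for p in parts:
                self._lnl[p] = old_lnl[p]
        return False

    def _sigscale_step(self, name: str):
        rs = name.split("_", 1)[1]
        parts = PARTITIONS if rs == "shared" else (rs,)
        old_lnl = {p: self.loglik(p) for p in parts}
        s_old = self.log_sigma[rs]
        sig_name = f"sigma_{rs}"
        old_prior = self.log_prior_param(sig_name)
        y_old = self.log_r[rs].copy()
        s_new = s_old + self.scales[name] * self.rng.standard_normal()
        sig_o, sig_n = math.exp(s_old), math.exp(s_new)
        self.log_r[rs] = (sig_n / sig_o) * (y_old + sig_o**2 / 2.0) - sig_n**2 / 2.0
        self.log_sigma[rs] = s_new
        self.invalidate(parts)
        new_prior = self.log_prior_param(sig_name)
        delta = (new_prior - old_prior) + sum(self.loglik(p) for p in parts) - sum(
            old_lnl.values()
        )
        acc = self.accepts[name]
        acc[1] += 1
        if math.log(self.rng.random() + 1e-300) < delta:
            acc[0] += 1
            return True
        self.log_r[rs] = y_old
        self.log_sigma[rs] = s_old
        for p in parts:
            self._lnl[p] = old_lnl[p]
        return False

    def adapt_scales(self, target=0.3):
        for name, (a, t) in self.accepts.items():
            if t >= 20:
                rate = a / t
                self.scales[name] *= math.exp(0.5 * (rate - target))
                self.scales[name] = min(max(self.scales[name], 1e-3), 20.0)
                self.accepts[name] = [0, 0]


def _default_priors():
    return {
        "sigma_rate": 1.0,
        "c_meanlog": 0.0,
        "c_sdlog": 5.0,
        "c_mol_init": MOL_MEAN_RATE,
        "c_morph_init": MORPH_MEAN_RATE,
    }


def run_mcmc(
    chronogram: Chronogram,
    aln: Alignment,
    chars: CharacterMatrix,
    clock: ClockModelSpec = None,
    settings: McmcSettings = None,
    nuc_model: NucModelParams = None,
    morph_model: MorphModelParams = None,
    priors: dict = None,
    likelihood_on: bool = True,
    fix: dict = None,
) -> PosteriorSamples:
    """Sample branch rates and clock hyperparameters on a fixed chronogram.

    Branch lengths for partition p are ``duration * c_p * r_{p,b}`` with
    ``r`` the relaxed-clock multipliers (prior mean 1) and ``c_p`` the
    partition mean-rate scalar. With ``likelihood_on=False`` the sampler
    targets the prior (used for validation). Deterministic given the seed.
    """
    clock = clock or ClockModelSpec()
    settings = settings or McmcSettings()
    pri = _default_priors()
    if priors:
        pri.update(priors)
    top = chronogram.topology
    engines = {"mol": None, "morph": None}
    if aln is not None:
        engines["mol"] = _alignment_engine(top, aln, nuc_model or NucModelParams())
    if chars is not None:
        engines["morph"] = _character_engine(
            top, chars, morph_model or MorphModelParams(k_states=chars.k_states)
        )
    edge_ids = np.asarray([v for v in range(top.n_nodes) if top.parent[v] >= 0], dtype=np.intp)
    durations = chronogram.edge_lengths[edge_ids]

    n_samples = settings.chain_length // settings.thin
    traces = None
    low_ess = []
    for chain in range(settings.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([settings.seed, chain, 0xC1A1]))
        state = _ClockState(
            engines, durations, clock, pri, rng, likelihood_on=likelihood_on, fix=fix,
            topology=top, ages=chronogram.node_ages(), estimate_times=settings.estimate_times,
        )
        state.edge_index = edge_ids
        names = state.update_pool
        burn_steps = int(settings.burnin_fraction * settings.chain_length)
        chain_traces = {}
        for name in _trace_names(state):
            chain_traces[name] = np.empty(n_samples)
        kept = 0
        for it in range(settings.chain_length):
            name = names[int(rng.integers(len(names)))]
            state.step(name)
            if settings.adapt and it < burn_steps and it % 200 == 199:
                state.adapt_scales()
            if (it + 1) % settings.thin == 0:
                _record(state, chain_traces, kept)
                kept += 1
        if traces is None:
            traces = {k: np.empty((settings.n_chains, n_samples)) for k in chain_traces}
        for k, v in chain_traces.items():
            traces[k][chain] = v

    result = PosteriorSamples(traces, settings, clock, durations, edge_ids)
    start = int(settings.burnin_fraction * n_samples)
    for k, t in traces.items():
        pooled = t[:, start:].reshape(-1)
        if effective_sample_size(pooled) < settings.ess_threshold:
            low_ess.append(k)
    result.low_ess = low_ess
    return result


def _trace_names(state: _ClockState):
    names = ["log_posterior"]
    for p in PARTITIONS:
        names += [f"rate_{p}_{e}" for e in range(state.n_edges)]
        names.append(f"c_{p}")
    for rs in state.rate_sets:
        if state.clock.family == "lognormal":
            names.append(f"sigma_{rs}")
    if state.estimate_times:
        names += [f"dur_{e}" for e in range(state.n_edges)]
    return names


def _record(state: _ClockState, chain_traces, i):
    chain_traces["log_posterior"][i] = state.log_posterior_full()
    for p in PARTITIONS:
        rates = state.branch_rates(p)
        for e in range(state.n_edges):
            chain_traces[f"rate_{p}_{e}"][i] = rates[e]
        chain_traces[f"c_{p}"][i] = math.exp(state.log_c[p])
    for rs in state.rate_sets:
        if state.clock.family == "lognormal":
            chain_traces[f"sigma_{rs}"][i] = math.exp(state.log_sigma[rs])
    if state.estimate_times:
        dur = state.current_durations()
        for e in range(state.n_edges):
            chain_traces[f"dur_{e}"][i] = dur[e]


# ---------------------------------------------------------------------------
# diagnostics and summaries


def effective_sample_size(trace) -> float:
    """Initial-monotone-positive-sequence ESS estimate (Geyer).

    Constant traces report an ESS of 1.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("trace too short for an ESS estimate")
    if np.ptp(x) == 0:
        return 1.0
    xc = x - x.mean()
    # autocovariances via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sums of adjacent pairs, truncated at first non-positive,
    # enforced non-increasing
    gammas = []
    k = 0
    while 2 * k + 1 < n:
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        gammas.append(g)
        k += 1
    if not gammas:
        return 1.0
    gammas = np.minimum.accumulate(gammas)
    tau = max(2.0 * float(np.sum(gammas)) - 1.0, 1.0 / n)
    return max(min(n / tau, float(n)), 1.0)


def summarize_branch_rates(samples: PosteriorSamples, burnin_fraction: float = None,
                           partition: str = "mol") -> BranchRateSummary:
    """Posterior mean and median branch rates, pooled across chains."""
    n_edges = len(samples.edge_ids)
    mean = np.empty(n_edges)
    median = np.empty(n_edges)
    durations = samples.durations.copy()
    for e in range(n_edges):
        pooled = samples.pooled(f"rate_{partition}_{e}", burnin_fraction)
        if pooled.size < 2:
            raise ValueError("no samples left after burn-in")
        mean[e] = pooled.mean()
        median[e] = np.median(pooled)
        if f"dur_{e}" in samples.traces:  # times were estimated
            durations[e] = np.median(samples.pooled(f"dur_{e}", burnin_fraction))
    return BranchRateSummary(samples.edge_ids, mean, median, durations)
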