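"""Fixed-topology likelihood computation and ML branch-length estimation.

The pruning engine computes log-likelihoods and analytic branch-length
gradients for discrete-state data under GTR+G+I or Mk+G, over site
patterns compressed with weights. Branch lengths are optimized in the
unrooted parameterization (the two root-adjacent edges are merged, since
only their sum is identifiable under a reversible model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .models import MorphModelParams, NucModelParams
from .synthetic import MISSING, Alignment, CharacterMatrix
from .trees import Topology, TreeError

__all__ = [
    "PruningEngine",
    "FitResult",
    "ModelSelectionResult",
    "nucleotide_loglik",
    "morphology_loglik",
    "optimize_branch_lengths",
    "fit_unlinked",
    "fit_linked",
    "information_criteria",
    "compress_patterns",
    "BRANCH_UPPER_BOUND",
    "AICC_BIC_THRESHOLD",
]

BRANCH_UPPER_BOUND = 10.0
BRANCH_LOWER_BOUND = 1e-9
AICC_BIC_THRESHOLD = 2.5
_LOGL_TOL = 1e-6


def compress_patterns(states: np.ndarray, k: int):
    """Collapse identical data columns into unique patterns with counts.

    Returns (tip_partials, weights, const_freq_index): tip partials are
    one-hot rows with all-ones for MISSING cells; ``const_freq_index[p]``
    is the state shared by all non-missing cells of pattern ``p``
    (invariant-compatible), or -1 otherwise.
    """
    cols = np.ascontiguousarray(states.T)
    uniq, inverse = np.unique(cols, axis=0, return_inverse=True)
    weights = np.bincount(inverse, minlength=len(uniq)).astype(float)
    n_taxa, n_pat = states.shape[0], len(uniq)
    partials = np.ones((n_taxa, n_pat, k))
    const_state = np.full(n_pat, -1, dtype=int)
    for p in range(n_pat):
        col = uniq[p]
        obs = col[col != MISSING]
        for t in range(n_taxa):
            s = col[t]
            if s != MISSING:
                partials[t, p, :] = 0.0
                partials[t, p, s] = 1.0
        if obs.size == 0 or np.all(obs == obs[0]):
            const_state[p] = obs[0] if obs.size else 0
    return partials, weights, const_state


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Parameters
    ----------
    topology : Topology
    tip_partials : ndarray, (n_tips, n_patterns, k)
    weights : ndarray, pattern multiplicities
    model : NucModelParams or MorphModelParams
    """

    def __init__(self, topology: Topology, tip_partials, weights, model, const_state=None,
                 use_numba: bool = True):
        self.top = topology
        self.use_numba = bool(use_numba and _kernels.HAVE_NUMBA)
        self.model = model
        self.k = tip_partials.shape[2]
        self.ncat = model.n_categories
        self.cat_rates = model.category_rates()
        self.freqs = model.freqs
        self.p_inv = getattr(model, "p_inv", 0.0)
        self.q = model.rate_matrix()
        self.weights = np.asarray(weights, dtype=float)
        self.n_patterns = tip_partials.shape[1]
        self.n_columns = int(round(self.weights.sum()))
        # tip partials broadcast over categories: (n_tips, ncat, pat, k)
        self.tipL = np.broadcast_to(
            tip_partials[:, None, :, :], (topology.n_tips, self.ncat, self.n_patterns, self.k)
        )
        if const_state is None:
            const_state = np.full(self.n_patterns, -1, dtype=int)
        self.const_pi = np.where(const_state >= 0, self.freqs[np.clip(const_state, 0, None)], 0.0)
        # (n_tips, ncat, k, n_patterns) layout for batched matmuls
        self.tipLk = np.ascontiguousarray(np.swapaxes(self.tipL, 2, 3))
        if isinstance(model, NucModelParams):
            self._eig = model.eigensystem()
        else:
            self._eig = None
        self._build_levels()
        # flat child/parent/sibling arrays for the compiled kernels
        top = self.top
        self._post_internal = np.asarray(
            [v for v in top.postorder if not top.is_tip(v)], dtype=np.intp
        )
        self._child1 = np.full(top.n_nodes, -1, dtype=np.intp)
        self._child2 = np.full(top.n_nodes, -1, dtype=np.intp)
        self._sibling = np.full(top.n_nodes, -1, dtype=np.intp)
        for v in range(top.n_nodes):
            if not top.is_tip(v):
                c1, c2 = top.children[v]
                self._child1[v], self._child2[v] = c1, c2
                self._sibling[c1], self._sibling[c2] = c2, c1
        self._edge_order = np.asarray(
            [v for v in top.preorder if top.parent[v] >= 0], dtype=np.intp
        )
        self._parent = np.asarray(top.parent, dtype=np.intp)

    def _build_levels(self):
        """Group nodes by height (postorder) and edges by depth (preorder)
        so each level is one batched matmul instead of a Python loop."""
        top = self.top
        height = np.zeros(top.n_nodes, dtype=int)
        for v in top.postorder:
            if not top.is_tip(v):
                height[v] = 1 + max(height[c] for c in top.children[v])
        groups = {}
        for v in range(top.n_nodes):
            if not top.is_tip(v):
                groups.setdefault(height[v], []).append(v)
        self._up_levels = []
        for h in sorted(groups):
            nodes = np.asarray(groups[h], dtype=np.intp)
            c1 = np.asarray([top.children[v][0] for v in nodes], dtype=np.intp)
            c2 = np.asarray([top.children[v][1] for v in nodes], dtype=np.intp)
            self._up_levels.append((nodes, c1, c2))
        depth = np.zeros(top.n_nodes, dtype=int)
        for v in top.preorder:
            p = top.parent[v]
            if p >= 0:
                depth[v] = depth[p] + 1
        egroups = {}
        for v in range(top.n_nodes):
            p = top.parent[v]
            if p >= 0:
                egroups.setdefault(depth[p], []).append(v)
        self._down_levels = []
        for d in sorted(egroups):
            vs = np.asarray(egroups[d], dtype=np.intp)
            us = top.parent[vs]
            sibs = np.asarray(
                [
                    top.children[u][1] if top.children[u][0] == v else top.children[u][0]
                    for u, v in zip(us, vs)
                ],
                dtype=np.intp,
            )
            self._down_levels.append((vs, us, sibs))

    # -- internal passes ----------------------------------------------------

    def _trans(self, edge_lengths):
        """Transition matrices, shape (n_nodes, ncat, k, k)."""
        t = np.multiply.outer(np.maximum(edge_lengths, 0.0), self.cat_rates)
        if self._eig is not None:
            w, u, uinv = self._eig
            e = np.exp(t[..., None] * w)  # (nodes, C, k)
            p = (u[None, None] * e[:, :, None, :]) @ uinv
            return np.clip(p, 0.0, None)
        return self.model.transition_probs(t)

    def _postorder(self, P):
        top = self.top
        nn, C, npat, k = top.n_nodes, self.ncat, self.n_patterns, self.k
        nt = top.n_tips
        if self.use_numba:
            below = np.empty((nn, C, k, npat))
            T = np.empty((nn, C, k, npat))
            clog = np.zeros((nn, npat))
            _kernels.postorder_pass(
                P, self.tipLk, self._post_internal, self._child1, self._child2,
                nt, below, T, clog,
            )
            return below, T, clog
        below = np.empty((nn, C, k, npat))
        T = np.empty((nn, C, k, npat))  # T[v] = P[v] @ below[v]
        clog = np.zeros((nn, npat))
        below[:nt] = self.tipLk
        np.matmul(P[:nt], below[:nt], out=T[:nt])
        for nodes, c1, c2 in self._up_levels:
            prod = T[c1] * T[c2]
            f = np.maximum(prod.max(axis=(1, 2)), 1e-300)  # per-(node,pattern) scale
            below[nodes] = prod / f[:, None, None, :]
            clog[nodes] = np.log(f) + clog[c1] + clog[c2]
            T[nodes] = np.matmul(P[nodes], below[nodes])
        return below, T, clog

    def _root_logliks(self, below, clog):
        root = self.top.root
        site = np.tensordot(self.freqs, below[root], axes=(0, 1)).mean(axis=0)
        site = np.maximum(site, 1e-300)
        s = clog[root]
        if self.p_inv > 0:
            with np.errstate(divide="ignore"):
                t1 = np.log((1.0 - self.p_inv) * site) + s
                t2 = np.where(self.const_pi > 0, np.log(self.p_inv * self.const_pi), -np.inf)
            return np.logaddexp(t1, t2)
        return np.log(site) + s

    def pattern_logliks(self, edge_lengths) -> np.ndarray:
        P = self._trans(edge_lengths)
        below, _, clog = self._postorder(P)
        return self._root_logliks(below, clog)

    def loglik(self, edge_lengths) -> float:
        return float(self.weights @ self.pattern_logliks(edge_lengths))

    def loglik_grad(self, edge_lengths):
        """(log-likelihood, gradient w.r.t. every edge length, by child node)."""
        top = self.top
        P = self._trans(edge_lengths)
        below, T, clog = self._postorder(P)
        lnl_pat = self._root_logliks(below, clog)
        lnl = float(self.weights @ lnl_pat)

        if self.use_numba:
            QP = self.q @ P
            grad = np.zeros(top.n_nodes)
            _kernels.gradient_pass(
                P, QP, self.cat_rates, below, T, clog, self._edge_order,
                self._parent, self._sibling, top.n_tips, float(self.p_inv),
                self.const_pi, self.weights, self.freqs, grad,
            )
            return lnl, grad

        C = self.ncat
        # D[v] = r_cat * Q @ P[v] @ below[v]: derivative counterpart of T[v]
        D = (self.q @ P * self.cat_rates[:, None, None]) @ below
        Pt = np.swapaxes(P, 2, 3)
        grad = np.zeros(top.n_nodes)
        # A[v]: outside-subtree partial as function of node v's state, scaled
        A = np.empty_like(below)
        alog = np.zeros((top.n_nodes, self.n_patterns))
        A[top.root] = self.freqs[None, :, None]
        w1 = 1.0 - self.p_inv
        for vs, us, sibs in self._down_levels:
            flank = A[us] * T[sibs]  # (edges, C, k, pat)
            flog = alog[us] + clog[sibs]
            val = np.einsum("eckp,eckp->ep", flank, T[vs]) / C
            dv = np.einsum("eckp,eckp->ep", flank, D[vs]) / C
            if self.p_inv > 0:
                sv = flog + clog[vs]
                den = w1 * val + self.p_inv * self.const_pi * np.exp(np.clip(-sv, None, 700.0))
                num = w1 * dv
            else:
                den = val
                num = dv
            grad[vs] = (num / np.maximum(den, 1e-300)) @ self.weights
            internal = ~(vs < top.n_tips)
            if internal.any():
                vi = vs[internal]
                av = Pt[vi] @ flank[internal]
                f = np.maximum(av.max(axis=(1, 2)), 1e-300)
                A[vi] = av / f[:, None, None, :]
                alog[vi] = flog[internal] + np.log(f)
        return lnl, grad


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Branch-length fit for one or two data partitions."""

    branch_lengths: dict  # partition name -> edge-length array (by child node)
    log_likelihood: float
    n_free_params: int
    n_columns: int
    proportionality_constant: float = None
    converged: bool = True
    n_iterations: int = 0


@dataclass
class ModelSelectionResult:
    """Linked vs unlinked branch-length model comparison."""

    aicc_linked: float
    aicc_unlinked: float
    bic_linked: float
    bic_unlinked: float
    delta_aicc: float = field(init=False)
    delta_bic: float = field(init=False)
    decision_aicc: str = field(init=False)
    decision_bic: str = field(init=False)
    threshold: float = AICC_BIC_THRESHOLD
    aicc_defined: bool = True

    def __post_init__(self):
        self.delta_aicc = self.aicc_unlinked - self.aicc_linked
        self.delta_bic = self.bic_unlinked - self.bic_linked
        self.decision_aicc = self._decide(self.delta_aicc) if self.aicc_defined else "indeterminate"
        self.decision_bic = self._decide(self.delta_bic)

    def _decide(self, delta: float) -> str:
        if delta > self.threshold:
            return "linked"
        if delta < -self.threshold:
            return "unlinked"
        return "indeterminate"


# ---------------------------------------------------------------------------
# engine construction and plain log-likelihood entry points


def _check_labels(topology: Topology, taxa):
    if tuple(taxa) != tuple(topology.labels):
        if set(taxa) != set(topology.labels):
            raise TreeError("tip labels of data and topology do not match")
        # reorder data rows to tree tip order
        order = [list(taxa).index(l) for l in topology.labels]
        return np.asarray(order)
    return None


def _alignment_engine(topology: Topology, aln: Alignment, model: NucModelParams) -> PruningEngine:
    states = aln.states
    order = _check_labels(topology, aln.taxa)
    if order is not None:
        states = states[order]
    partials, weights, const = compress_patterns(states, 4)
    return PruningEngine(topology, partials, weights, model, const)


def _character_engine(
    topology: Topology, chars: CharacterMatrix, model: MorphModelParams
) -> PruningEngine:
    if chars.k_states > model.k_states or np.any(chars.states >= model.k_states):
        raise ValueError("character states exceed model state count")
    states = chars.states
    order = _check_labels(topology, chars.taxa)
    if order is not None:
        states = states[order]
    partials, weights, const = compress_patterns(states, model.k_states)
    return PruningEngine(topology, partials, weights, model, const)


def nucleotide_loglik(
    topology: Topology, branch_lengths, aln: Alignment, model: NucModelParams = None
) -> float:
    """GTR+G+I log-likelihood of an alignment on a fixed tree by pruning."""
    if model is None:
        model = NucModelParams()
    return _alignment_engine(topology, aln, model).loglik(np.asarray(branch_lengths, dtype=float))


def morphology_loglik(
    topology: Topology,
    branch_lengths,
    chars: CharacterMatrix,
    model: MorphModelParams = None,
    ascertainment: str = "none",
) -> float:
    """Mk+G log-likelihood; optional conditioning on characters being variable."""
    if model is None:
        model = MorphModelParams(k_states=chars.k_states)
    engine = _character_engine(topology, chars, model)
    edge = np.asarray(branch_lengths, dtype=float)
    lnl = engine.loglik(edge)
    if ascertainment == "variable_only":
        lnl -= engine.n_columns * _log_one_minus_pconst(topology, edge, model)
    elif ascertainment != "none":
        raise ValueError(f"unknown ascertainment option {ascertainment!r}")
    return lnl


def _log_one_minus_pconst(topology: Topology, edge_lengths, model: MorphModelParams) -> float:
    k = model.k_states
    const = np.tile(np.arange(k), (topology.n_tips, 1))
    partials, weights, cs = compress_patterns(const, k)
    eng = PruningEngine(topology, partials, weights, model, cs)
    p_const = np.exp(eng.pattern_logliks(edge_lengths)).sum()
    return float(np.log1p(-min(p_const, 1.0 - 1e-12)))


# ---------------------------------------------------------------------------
# ML optimization


def _free_edge_map(topology: Topology):
    """Unrooted parameterization: merge the two root-adjacent edges.

    Returns (free_nodes, zero_node): the edge above ``zero_node`` is pinned
    at 0 and its length is absorbed into its sibling's parameter.
    """
    root = topology.root
    c0, c1 = topology.children[root]
    free = [v for v in range(topology.n_nodes) if v not in (root, c0)]
    return np.asarray(free, dtype=np.intp), c0


def _expand(topology, free_nodes, zero_node, x):
    edge = np.zeros(topology.n_nodes)
    edge[free_nodes] = x
    edge[zero_node] = 0.0
    return edge


def _ml_single(engine: PruningEngine, x0=None):
    top = engine.top
    free, zero = _free_edge_map(top)
    if x0 is None:
        x0 = np.full(len(free), 0.05)
    x0 = np.clip(x0, BRANCH_LOWER_BOUND, BRANCH_UPPER_BOUND)

    def nll(x):
        lnl, g = engine.loglik_grad(_expand(top, free, zero, x))
        return -lnl, -g[free]

    res = minimize(
        nll,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(BRANCH_LOWER_BOUND, BRANCH_UPPER_BOUND)] * len(free),
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    edge = _expand(top, free, zero, res.x)
    return edge, -res.fun, bool(res.success), int(res.nit)


def optimize_branch_lengths(topology: Topology, data, model=None, x0=None) -> FitResult:
    """ML branch lengths for one data set (alignment or character matrix)."""
    if isinstance(data, Alignment):
        engine = _alignment_engine(topology, data, model or NucModelParams())
        name = "mol"
    elif isinstance(data, CharacterMatrix):
        engine = _character_engine(
            topology, data, model or MorphModelParams(k_states=data.k_states)
        )
        name = "morph"
    else:
        raise TypeError("data must be an Alignment or CharacterMatrix")
    edge, lnl, ok, nit = _ml_single(engine, x0)
    if not ok:
        warnings.warn("branch-length optimization did not report convergence")
    return FitResult(
        branch_lengths={name: edge},
        log_likelihood=lnl,
        n_free_params=2 * topology.n_tips - 3,
        n_columns=engine.n_columns,
        converged=ok,
        n_iterations=nit,
    )


def fit_unlinked(
    topology: Topology,
    aln: Alignment,
    chars: CharacterMatrix,
    nuc_model: NucModelParams = None,
    morph_model: MorphModelParams = None,
) -> FitResult:
    """Independent branch-length sets for the two data types."""
    fm = optimize_branch_lengths(topology, aln, nuc_model)
    fc = optimize_branch_lengths(topology, chars, morph_model)
    return FitResult(
        branch_lengths={"mol": fm.branch_lengths["mol"], "morph": fc.branch_lengths["morph"]},
        log_likelihood=fm.log_likelihood + fc.log_likelihood,
        n_free_params=2 * (2 * topology.n_tips - 3),
        n_columns=fm.n_columns + fc.n_columns,
        converged=fm.converged and fc.converged,
        n_iterations=fm.n_iterations + fc.n_iterations,
    )


def fit_linked(
    topology: Topology,
    aln: Alignment,
    chars: CharacterMatrix,
    nuc_model: NucModelParams = None,
    morph_model: MorphModelParams = None,
    init: FitResult = None,
) -> FitResult:
    """Shared branch lengths with a morphological proportionality constant c.

    Molecular branch lengths are the shared set b; morphological lengths
    are c*b. Jointly optimized by L-BFGS with analytic gradients.
    """
    eng_m = _alignment_engine(topology, aln, nuc_model or NucModelParams())
    eng_c = _character_engine(
        topology, chars, morph_model or MorphModelParams(k_states=chars.k_states)
    )
    free, zero = _free_edge_map(topology)
    nb = len(free)
    if init is not None and "mol" in init.branch_lengths and "morph" in init.branch_lengths:
        b0 = np.clip(init.branch_lengths["mol"][free], BRANCH_LOWER_BOUND, BRANCH_UPPER_BOUND)
        tm = init.branch_lengths["mol"].sum()
        tc = init.branch_lengths["morph"].sum()
        c0 = np.clip(tc / tm if tm > 0 else 1.0, 1e-4, 1e4)
    else:
        b0 = np.full(nb, 0.05)
        c0 = 1.0

    def nll(x):
        b, logc = x[:nb], x[nb]
        c = np.exp(logc)
        edge_m = _expand(topology, free, zero, b)
        edge_c = edge_m * c
        lm, gm = eng_m.loglik_grad(edge_m)
        lc, gc = eng_c.loglik_grad(edge_c)
        g = np.empty(nb + 1)
        g[:nb] = gm[free] + c * gc[free]
        g[nb] = c * float(edge_m[free] @ gc[free])  # d/d log c
        return -(lm + lc), -g

    x0 = np.concatenate([b0, [np.log(c0)]])
    bounds = [(BRANCH_LOWER_BOUND, BRANCH_UPPER_BOUND)] * nb + [(np.log(1e-6), np.log(1e4))]
    res = minimize(
        nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 1500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        warnings.warn("linked-model optimization did not report convergence")
    b, c = res.x[:nb], float(np.exp(res.x[nb]))
    edge_m = _expand(topology, free, zero, b)
    return FitResult(
        branch_lengths={"mol": edge_m, "morph": edge_m * c},
        log_likelihood=-res.fun,
        n_free_params=(2 * topology.n_tips - 3) + 1,
        n_columns=eng_m.n_columns + eng_c.n_columns,
        proportionality_constant=c,
        converged=bool(res.success),
        n_iterations=int(res.nit),
    )


# ---------------------------------------------------------------------------
# information criteria


def _aic(lnl: float, k: int) -> float:
    return 2.0 * k - 2.0 * lnl


def _aicc(lnl: float, k: int, n: int) -> float:
    if n <= k + 1:
        return np.nan
    return _aic(lnl, k) + 2.0 * k * (k + 1) / (n - k - 1)


def _bic(lnl: float, k: int, n: int) -> float:
    return k * np.log(n) - 2.0 * lnl


def information_criteria(linked: FitResult, unlinked: FitResult) -> ModelSelectionResult:
    """AICc/BIC comparison of linked vs unlinked fits on the same data.

    The effective sample size n is the total number of data columns
    (alignment sites plus characters).
    """
    if linked.n_columns != unlinked.n_columns:
        raise ValueError("fits compare different data")
    n = linked.n_columns
    aicc_l = _aicc(linked.log_likelihood, linked.n_free_params, n)
    aicc_u = _aicc(unlinked.log_likelihood, unlinked.n_free_params, n)
    defined = np.isfinite(aicc_l) and np.isfinite(aicc_u)
    return ModelSelectionResult(
        aicc_linked=aicc_l if defined else np.nan,
        aicc_unlinked=aicc_u if defined else np.nan,
        bic_linked=_bic(linked.log_likelihood, linked.n_free_params, n),
        bic_unlinked=_bic(unlinked.log_likelihood, unlinked.n_free_params, n),
        aicc_defined=bool(defined),
    )
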