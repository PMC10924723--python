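"""Detection tests for correlated molecular/morphological evolutionary rates.

Five procedures: root-to-tip distance correlation (permutation test),
independent sister-pairs contrasts, likelihood model selection (AICc/BIC),
correlation of Bayesian posterior branch rates, and Bayes-factor model
selection. Each returns a :class:`TestResult` with a boolean detection call.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .likelihood import AICC_BIC_THRESHOLD, ModelSelectionResult
from .trees import Chronogram, Phylogram, Topology

__all__ = [
    "TestResult",
    "spearman",
    "root_to_tip_test",
    "extract_sister_pairs",
    "sister_pairs_test",
    "ml_modelsel_test",
    "bayes_branchrate_test",
    "bayes_modelsel_test",
    "DEFAULT_N_PERM",
    "LOG_BF_THRESHOLD",
]

DEFAULT_N_PERM = 20_000
DEFAULT_ALPHA = 0.05
LOG_BF_THRESHOLD = 1.0
SISTER_EPS = 1e-9  # pseudocount guarding log of zero-length branches
EXACT_SPEARMAN_MAX_N = 10


class InsufficientDataError(ValueError):
    """Raised when a test has too few data points to be meaningful."""


@dataclass
class TestResult:
    """Outcome of one detection method on one data-set pair."""

    method: str
    statistic: float
    detected: bool
    p_value: float = None
    n_points: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# Spearman rank correlation with exact small-sample null


_exact_null_cache: dict = {}


def _rankdata(x):
    return stats.rankdata(x, method="average")


def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted null distribution of rho over all n! rank permutations."""
    if n not in _exact_null_cache:
        base = np.arange(1, n + 1, dtype=float)
        perms = np.array(list(itertools.permutations(base)))
        c = base - base.mean()
        denom = (c**2).sum()
        rho = ((perms - base.mean()) @ c) / denom
        _exact_null_cache[n] = np.sort(rho)
    return _exact_null_cache[n]


def spearman(x, y) -> dict:
    """Spearman rho with two- and one-sided (rho > 0) p-values.

    Exact permutation null for n <= 10 when ranks are untied; the
    t-distribution approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 points for a rank correlation")
    rx, ry = _rankdata(x), _rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return {"rho": np.nan, "p_two_sided": np.nan, "p_one_sided": np.nan, "defined": False}
    rho = float(np.corrcoef(rx, ry)[0, 1])
    untied = len(set(rx)) == n and len(set(ry)) == n
    if n <= EXACT_SPEARMAN_MAX_N and untied:
        null = _exact_rho_null(n)
        m = len(null)
        tol = 1e-12
        ge = m - np.searchsorted(null, rho - tol, side="left")
        le = np.searchsorted(null, rho + tol, side="right")
        p1 = ge / m
        p2 = min(1.0, 2.0 * min(ge, le) / m)
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p2 = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p1 = float(stats.t.sf(t, df=n - 2))
    return {"rho": rho, "p_two_sided": p2, "p_one_sided": p1, "defined": True}


# ---------------------------------------------------------------------------
# (i) root-to-tip distance correlations


def _iqr_outliers(v: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


def root_to_tip_test(
    mol: Phylogram,
    morph: Phylogram,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    remove_outliers: bool = False,
    seed: int = 0,
    exhaustive: bool = False,
) -> TestResult:
    """Permutation test of the Pearson correlation of root-to-tip distances.

    One-sided (positive-correlation) p-value computed by shuffling the
    assignment of one distance vector to tips; MC p is (1 + #{r* >= r}) /
    (n_perm + 1), or the exact enumeration fraction when ``exhaustive``.
    """
    if tuple(mol.labels) != tuple(morph.labels):
        order = [list(morph.labels).index(l) for l in mol.labels]
        y_full = morph.root_to_tip_distances()[order]
    else:
        y_full = morph.root_to_tip_distances()
    x = mol.root_to_tip_distances()
    y = y_full
    removed = 0
    if remove_outliers:
        keep = ~(_iqr_outliers(x) | _iqr_outliers(y))
        removed = int((~keep).sum())
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"only {n} tips left after outlier removal")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    xc = (x - x.mean()) / max(x.std(), 1e-300)
    yc = (y - y.mean()) / max(y.std(), 1e-300)
    r_obs = float(xc @ yc) / n
    tol = 1e-12
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = (yc[perms] @ xc) / n
        p = float(np.mean(r_perm >= r_obs - tol))
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        block = 2000
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            idx = np.argsort(rng.random((b, n)), axis=1)
            r_perm = (yc[idx] @ xc) / n
            count += int(np.sum(r_perm >= r_obs - tol))
            done += b
        p = (1.0 + count) / (n_perm + 1.0)
        n_used = n_perm
    return TestResult(
        method="root_to_tip",
        statistic=r_obs,
        p_value=p,
        detected=bool(p < alpha),
        n_points=n,
        options={"n_perm": n_used, "remove_outliers": remove_outliers,
                 "n_outliers_removed": removed, "exhaustive": exhaustive},
    )


# ---------------------------------------------------------------------------
# (ii) independent sister-pairs contrasts


def extract_sister_pairs(topology: Topology):
    """All cherries: internal nodes whose two children are both tips.

    Returns a list of (tip_a, tip_b, cherry_node) with tips ordered
    lexicographically by label within each pair.
    """
    pairs = []
    for v in range(topology.n_nodes):
        ch = topology.children[v]
        if len(ch) == 2 and topology.is_tip(ch[0]) and topology.is_tip(ch[1]):
            a, b = ch
            if topology.labels[a] > topology.labels[b]:
                a, b = b, a
            pairs.append((a, b, v))
    pairs.sort(key=lambda p: topology.labels[p[0]])
    return pairs


def _contrasts(phy: Phylogram, pairs, ages):
    c = np.empty(len(pairs))
    for i, (a, b, v) in enumerate(pairs):
        t = ages[v]
        c[i] = (np.log(phy.edge_lengths[a] + SISTER_EPS) - np.log(phy.edge_lengths[b] + SISTER_EPS)) / np.sqrt(t)
    return c


def sister_pairs_test(
    chrono: Chronogram, mol: Phylogram, morph: Phylogram, alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Spearman correlation of standardized log sister-pair contrasts.

    Each cherry contributes (log b1 - log b2) / sqrt(divergence time) per
    data type, with a fixed label ordering; detection requires a positive
    rho with two-sided p < alpha.
    """
    top = chrono.topology
    if tuple(mol.labels) != tuple(top.labels) or tuple(morph.labels) != tuple(top.labels):
        raise ValueError("phylograms must share the chronogram's topology and labels")
    pairs = extract_sister_pairs(top)
    if len(pairs) < 3:
        raise InsufficientDataError(f"only {len(pairs)} sister pairs; need at least 3")
    ages = chrono.node_ages()
    cx = _contrasts(mol, pairs, ages)
    cy = _contrasts(morph, pairs, ages)
    s = spearman(cx, cy)
    detected = bool(s["defined"] and s["p_two_sided"] < alpha and s["rho"] > 0)
    return TestResult(
        method="sister_pairs",
        statistic=s["rho"],
        p_value=s["p_two_sided"] if s["defined"] else None,
        detected=detected,
        n_points=len(pairs),
    )


# ---------------------------------------------------------------------------
# (iii) likelihood model selection


def ml_modelsel_test(
    msr: ModelSelectionResult, criterion: str = "aicc", threshold: float = AICC_BIC_THRESHOLD
) -> TestResult:
    """Detected iff the unlinked-minus-linked criterion difference > threshold."""
    if criterion == "aicc":
        delta = msr.delta_aicc
        defined = msr.aicc_defined
    elif criterion == "bic":
        delta = msr.delta_bic
        defined = True
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    detected = bool(defined and delta > threshold)
    return TestResult(
        method=f"ml_modelsel_{criterion}",
        statistic=float(delta) if defined else np.nan,
        detected=detected,
        options={"criterion": criterion, "threshold": threshold, "defined": defined},
    )


# ---------------------------------------------------------------------------
# (iv) correlations of Bayesian branch rates


def bayes_branchrate_test(
    mol_summary,
    morph_summary,
    statistic: str = "mean",
    drop_shortest_fraction: float = 0.0,
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Spearman correlation of per-branch posterior rates (one-sided).

    Optionally drops the chronologically shortest fraction of branches
    (smallest duration in Myr) before correlating.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if not 0 <= drop_shortest_fraction < 1:
        raise ValueError("drop_shortest_fraction must be in [0, 1)")
    x = np.asarray(getattr(mol_summary, statistic))
    y = np.asarray(getattr(morph_summary, statistic))
    dur = np.asarray(mol_summary.durations)
    if x.shape != y.shape:
        raise ValueError("summaries cover different branch sets")
    n = len(x)
    if drop_shortest_fraction > 0:
        k = int(round(drop_shortest_fraction * n))
        keep = np.argsort(dur, kind="stable")[k:]
        x, y = x[keep], y[keep]
    if len(x) < 4:
        raise InsufficientDataError(f"only {len(x)} branches after dropping; need at least 4")
    s = spearman(x, y)
    detected = bool(s["defined"] and s["p_one_sided"] < alpha)
    return TestResult(
        method=f"bayes_branch_rates_{statistic}",
        statistic=s["rho"],
        p_value=s["p_one_sided"] if s["defined"] else None,
        detected=detected,
        n_points=len(x),
        options={"drop_shortest_fraction": drop_shortest_fraction},
    )


# ---------------------------------------------------------------------------
# (v) Bayesian model selection


def bayes_modelsel_test(log_bf: float, threshold: float = LOG_BF_THRESHOLD) -> TestResult:
    """Detected iff log BF (linked minus unlinked, natural log) > threshold."""
    if not np.isfinite(log_bf):
        raise ValueError("log Bayes factor must be finite")
    return TestResult(
        method="bayes_modelsel",
        statistic=float(log_bf),
        detected=bool(log_bf > threshold),
        options={"threshold": threshold},
    )
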