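"""Synthetic data engine: relaxed-clock rates, alignments, character matrices.

Generates matched molecular/morphological data-set pairs on a shared
chronogram, with branch rates either coupled (morphological branch
lengths a fixed multiple of molecular ones) or drawn independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .models import MorphModelParams, NucModelParams, NUC_STATES
from .trees import Chronogram, Phylogram, simulate_chronogram

__all__ = [
    "ClockSpec",
    "RateAssignment",
    "ScenarioSpec",
    "Alignment",
    "CharacterMatrix",
    "MISSING",
    "draw_branch_rates",
    "build_phylogram",
    "couple_morph_phylogram",
    "generate_scenario_pair",
    "simulate_alignment",
    "simulate_characters",
    "mask_missing",
    "derive_rng",
    "MOL_MEAN_RATE",
    "MORPH_MEAN_RATE",
    "DEFAULT_SCALE_FACTOR",
    "DEFAULT_ROOT_AGE",
]

#: mean molecular rate, substitutions/site/Myr
MOL_MEAN_RATE = 9.65e-4
#: mean morphological rate, changes/character/Myr
MORPH_MEAN_RATE = 1.83e-3
#: default morphological/molecular branch-length coupling factor
DEFAULT_SCALE_FACTOR = 1.90
#: default chronogram root age, Myr
DEFAULT_ROOT_AGE = 139.40

MISSING = -1  # missing-state token in character matrices


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    """Deterministic per-stage RNG from a master seed and hashable tokens.

    String tokens are CRC32-hashed so every (stage, scenario, replicate)
    combination gets an independent, reproducible stream.
    """
    ints = [int(master_seed) & 0xFFFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            ints.append(zlib.crc32(t.encode()))
        elif isinstance(t, bool):
            ints.append(int(t))
        elif isinstance(t, (int, np.integer)):
            ints.append(int(t) & 0xFFFFFFFF)
        else:  # floats: hash their repr to avoid platform float-hash drift
            ints.append(zlib.crc32(repr(float(t)).encode()))
    return np.random.default_rng(np.random.SeedSequence(ints))


def _derive_int_seed(master_seed: int, *tokens) -> int:
    return int(derive_rng(master_seed, *tokens).integers(0, 2**31 - 1))


@dataclass(frozen=True)
class ClockSpec:
    """Uncorrelated relaxed-clock specification.

    ``sigma`` is the standard deviation of log branch rates; the log-scale
    mean is ``ln(mean_rate) - sigma**2 / 2`` so that ``E[rate] = mean_rate``.
    The exponential family ignores ``sigma`` (its CV is fixed at 1).
    """

    family: str = "lognormal"
    mean_rate: float = MOL_MEAN_RATE
    sigma: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("lognormal", "exponential"):
            raise ValueError(f"unknown clock family {self.family!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class RateAssignment:
    """Per-branch rates (indexed by child node; root entry unused)."""

    rates: np.ndarray
    clock_spec: ClockSpec

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", r)


def draw_branch_rates(tree: Chronogram, clock: ClockSpec, rng=None) -> RateAssignment:
    """Draw i.i.d. branch rates for every branch of ``tree``."""
    if rng is None:
        rng = np.random.default_rng(clock.seed)
    n = tree.topology.n_nodes
    if clock.family == "lognormal":
        if clock.sigma == 0:
            rates = np.full(n, clock.mean_rate)
        else:
            meanlog = np.log(clock.mean_rate) - clock.sigma**2 / 2.0
            rates = rng.lognormal(meanlog, clock.sigma, size=n)
    else:  # exponential: CV = 1
        rates = rng.exponential(clock.mean_rate, size=n)
        rates = np.maximum(rates, 1e-300)
    rates[tree.topology.root] = 0.0
    return RateAssignment(rates, clock)


def build_phylogram(tree: Chronogram, rates: RateAssignment) -> Phylogram:
    """Rescale chronogram durations by per-branch rates."""
    r = rates.rates
    if r.shape != tree.edge_lengths.shape:
        raise ValueError("rate assignment does not cover this tree's branches")
    return Phylogram(tree.topology, tree.edge_lengths * r)


def couple_morph_phylogram(mol: Phylogram, scale_factor: float = DEFAULT_SCALE_FACTOR) -> Phylogram:
    """Morphological phylogram with perfectly coupled branch rates."""
    return mol.scaled(scale_factor)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid plus a replicate index."""

    n_taxa: int = 18
    n_chars: int = 100
    k_states: int = 2
    sigma: float = 0.75
    coupled: bool = True
    seq_length: int = 1000
    scale_factor: float = DEFAULT_SCALE_FACTOR
    replicate_id: int = 0
    master_seed: int = 0
    mol_mean_rate: float = MOL_MEAN_RATE
    morph_mean_rate: float = MORPH_MEAN_RATE
    root_age: float = DEFAULT_ROOT_AGE

    def __post_init__(self):
        if self.n_taxa < 2 or self.n_chars < 1 or self.k_states < 2:
            raise ValueError("invalid scenario dimensions")
        if self.sigma < 0 or self.scale_factor <= 0 or self.seq_length < 1:
            raise ValueError("invalid scenario parameters")

    def with_replicate(self, replicate_id: int) -> "ScenarioSpec":
        return replace(self, replicate_id=replicate_id)

    def _key(self) -> tuple:
        return (self.n_taxa, self.n_chars, self.k_states, self.sigma, self.coupled,
                self.replicate_id)

    def _rate_key(self) -> tuple:
        # branch-rate draws depend only on the tree and rate-variation level,
        # so scenarios differing in the morphological data dimensions share
        # phylograms (mirrors the study's fixed per-size trees and lets the
        # evaluation layer cache molecular inference)
        return (self.n_taxa, self.sigma, self.replicate_id)


def scenario_chronogram(spec: ScenarioSpec) -> Chronogram:
    """Chronogram shared by all scenarios of a given tree size.

    Mirrors the fixed per-size trees of the original design: the tree
    depends only on (master_seed, n_taxa, root_age).
    """
    seed = _derive_int_seed(spec.master_seed, "tree", spec.n_taxa)
    return simulate_chronogram(spec.n_taxa, root_age=spec.root_age, seed=seed)


def generate_scenario_pair(spec: ScenarioSpec) -> dict:
    """Generate one matched molecular/morphological phylogram pair.

    Returns a dict with the chronogram, both phylograms, and the true
    per-branch rate assignments. Deterministic in (spec, master_seed).
    """
    chrono = scenario_chronogram(spec)
    mol_clock = ClockSpec("lognormal", spec.mol_mean_rate, spec.sigma)
    mol_rng = derive_rng(spec.master_seed, "mol_rates", *spec._rate_key())
    true_mol = draw_branch_rates(chrono, mol_clock, rng=mol_rng)
    mol_phy = build_phylogram(chrono, true_mol)
    if spec.coupled:
        morph_phy = couple_morph_phylogram(mol_phy, spec.scale_factor)
        morph_rates = true_mol.rates * spec.scale_factor
        morph_rates[chrono.topology.root] = 0.0
        true_morph = RateAssignment(
            morph_rates, replace(mol_clock, mean_rate=spec.mol_mean_rate * spec.scale_factor)
        )
    else:
        morph_clock = ClockSpec("lognormal", spec.morph_mean_rate, spec.sigma)
        morph_rng = derive_rng(spec.master_seed, "morph_rates", *spec._rate_key())
        true_morph = draw_branch_rates(chrono, morph_clock, rng=morph_rng)
        morph_phy = build_phylogram(chrono, true_morph)
    return {
        "chronogram": chrono,
        "mol_phylogram": mol_phy,
        "morph_phylogram": morph_phy,
        "true_rates_mol": true_mol,
        "true_rates_morph": true_morph,
    }


# ---------------------------------------------------------------------------
# Sequence and character simulation


@dataclass(frozen=True)
class Alignment:
    """Nucleotide alignment; ``states`` holds 0..3 codes (row per taxon)."""

    taxa: tuple
    states: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.states)
        if s.ndim != 2 or s.shape[0] != len(self.taxa):
            raise ValueError("states must be (n_taxa, L) with a row per taxon")
        object.__setattr__(self, "states", s)

    @property
    def length(self) -> int:
        return self.states.shape[1]

    def sequence_strings(self):
        lut = np.array(list(NUC_STATES))
        return ["".join(lut[row]) for row in self.states]


@dataclass(frozen=True)
class CharacterMatrix:
    """Discrete character matrix; states in [0, k-1] with MISSING for gaps."""

    taxa: tuple
    states: np.ndarray
    k_states: int

    def __post_init__(self):
        s = np.asarray(self.states)
        if s.ndim != 2 or s.shape[0] != len(self.taxa):
            raise ValueError("states must be (n_taxa, n_chars) with a row per taxon")
        ok = (s == MISSING) | ((s >= 0) & (s < self.k_states))
        if not np.all(ok):
            raise ValueError("character states out of range")
        object.__setattr__(self, "states", s)

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.states == MISSING))


def _evolve_states(topology, edge_lengths, site_rates, root_probs, trans_fn, rng):
    """Drop states down the tree with per-site rate multipliers."""
    n_sites = site_rates.shape[0]
    k = root_probs.shape[0]
    states = np.empty((topology.n_nodes, n_sites), dtype=np.int8)
    root = topology.root
    states[root] = rng.choice(k, size=n_sites, p=root_probs)
    u = rng.random((topology.n_nodes, n_sites))
    for v in topology.preorder:
        p = topology.parent[v]
        if p < 0:
            continue
        pm = trans_fn(edge_lengths[v] * site_rates)  # (n_sites, k, k)
        rows = pm[np.arange(n_sites), states[p], :]
        cum = np.cumsum(rows, axis=1)
        cum[:, -1] = 1.0
        states[v] = (u[v][:, None] > cum).sum(axis=1)
    return states[: topology.n_tips]


def simulate_alignment(
    phy: Phylogram, model: NucModelParams = None, L: int = 1000, seed: int = 0
) -> Alignment:
    """Simulate a nucleotide alignment on a phylogram under GTR+G+I.

    Per-site rate multipliers are 0 with probability ``p_inv`` and
    otherwise drawn from a continuous Gamma(shape, mean 1).
    """
    if L < 1:
        raise ValueError("alignment length must be at least 1")
    if model is None:
        model = NucModelParams()
    rng = np.random.default_rng(seed)
    rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=L)
    if model.p_inv > 0:
        rates[rng.random(L) < model.p_inv] = 0.0
    tip_states = _evolve_states(
        phy.topology, phy.edge_lengths, rates, model.freqs, model.transition_probs, rng
    )
    return Alignment(phy.labels, tip_states)


def simulate_characters(
    phy: Phylogram, model: MorphModelParams = None, n_chars: int = 100, seed: int = 0
) -> CharacterMatrix:
    """Simulate discrete characters under the Mk model with gamma rate variation.

    Root states are uniform over the k states; invariant characters are
    retained (no ascertainment filtering).
    """
    if n_chars < 1:
        raise ValueError("need at least one character")
    if model is None:
        model = MorphModelParams()
    rng = np.random.default_rng(seed)
    rates = rng.gamma(model.char_rate_shape, 1.0 / model.char_rate_shape, size=n_chars)
    tip_states = _evolve_states(
        phy.topology, phy.edge_lengths, rates, model.freqs, model.transition_probs, rng
    )
    return CharacterMatrix(phy.labels, tip_states, model.k_states)


def mask_missing(m: CharacterMatrix, fraction: float, seed: int = 0) -> CharacterMatrix:
    """Replace a uniformly random ``round(fraction * cells)`` cells with MISSING."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return m
    rng = np.random.default_rng(seed)
    cells = m.states.size
    n_mask = int(round(fraction * cells))
    flat = m.states.copy().reshape(-1)
    idx = rng.choice(cells, size=n_mask, replace=False)
    flat[idx] = MISSING
    return CharacterMatrix(m.taxa, flat.reshape(m.states.shape), m.k_states)
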