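"""Factorial simulation grid orchestration and power / false-positive tables.

Enumerates the scenario grid, runs the requested detection methods on each
replicate data-set pair, and aggregates detection rates per scenario cell
(power on coupled data, false-positive rate on uncoupled data).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import detect
from .detect import TestResult
from .gss import bayes_factor, gss_logml
from .likelihood import fit_linked, information_criteria
from .mcmc import ClockModelSpec, McmcSettings, run_mcmc, summarize_branch_rates
from .models import MorphModelParams, NucModelParams
from .synthetic import (
    ScenarioSpec,
    derive_rng,
    generate_scenario_pair,
    simulate_alignment,
    simulate_characters,
)
from .trees import Phylogram

__all__ = [
    "GridConfig",
    "ALL_METHODS",
    "enumerate_grid",
    "run_replicate",
    "compute_rates",
    "export_tables",
    "run_grid",
]

ALL_METHODS = (
    "rtt",
    "sisters",
    "ml_aicc",
    "ml_bic",
    "bayes_rates_mean",
    "bayes_rates_median",
    "bayes_bf",
)
_ML_METHODS = {"rtt", "sisters", "ml_aicc", "ml_bic"}
_BAYES_METHODS = {"bayes_rates_mean", "bayes_rates_median", "bayes_bf"}


@dataclass(frozen=True)
class GridConfig:
    """Factorial grid specification (defaults reproduce the study preset)."""

    tree_sizes: tuple = (18, 45, 111)
    char_counts: tuple = (10, 100, 1000)
    state_counts: tuple = (2, 4)
    sigmas: tuple = (0.25, 0.75, 1.25)
    n_replicates: int = 20
    coupled: bool = True
    methods: tuple = ("rtt", "sisters", "ml_aicc", "ml_bic")
    inference_scale: str = "desk"
    master_seed: int = 0
    seq_length: int = 1000

    def __post_init__(self):
        if not all((self.tree_sizes, self.char_counts, self.state_counts, self.sigmas)):
            raise ValueError("grid value lists must be non-empty")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def enumerate_grid(cfg: GridConfig):
    """Scenario specs for the Cartesian product, in deterministic order."""
    specs = []
    for n_taxa in cfg.tree_sizes:
        for n_chars in cfg.char_counts:
            for k in cfg.state_counts:
                for sigma in cfg.sigmas:
                    specs.append(
                        ScenarioSpec(
                            n_taxa=n_taxa,
                            n_chars=n_chars,
                            k_states=k,
                            sigma=sigma,
                            coupled=cfg.coupled,
                            seq_length=cfg.seq_length,
                            master_seed=cfg.master_seed,
                        )
                    )
    return specs


def _mcmc_settings(scale: str, seed: int) -> McmcSettings:
    if scale == "paper":
        return McmcSettings(chain_length=10_000_000, thin=1000, n_chains=2, seed=seed)
    if scale == "desk":
        return McmcSettings(chain_length=200_000, thin=100, n_chains=2, seed=seed)
    if scale == "fast":  # reduced settings for grid sweeps
        return McmcSettings(chain_length=30_000, thin=60, n_chains=1, seed=seed)
    raise ValueError(f"unknown inference scale {scale!r}")


def simulate_replicate_data(spec: ScenarioSpec, nuc_model: NucModelParams = None,
                            morph_model: MorphModelParams = None):
    """Data pair for one replicate; molecular data shared across morphology cells."""
    pair = generate_scenario_pair(spec)
    nuc_model = nuc_model or NucModelParams()
    morph_model = morph_model or MorphModelParams(k_states=spec.k_states)
    aln_seed = derive_rng(spec.master_seed, "aln", *spec._rate_key()).integers(2**31)
    aln = simulate_alignment(pair["mol_phylogram"], nuc_model, spec.seq_length, seed=aln_seed)
    chars_seed = derive_rng(spec.master_seed, "chars", *spec._key()).integers(2**31)
    chars = simulate_characters(pair["morph_phylogram"], morph_model, spec.n_chars,
                                seed=chars_seed)
    return pair, aln, chars, nuc_model, morph_model


def _indeterminate(method: str, err: Exception) -> TestResult:
    return TestResult(method=method, statistic=float("nan"), detected=False,
                      options={"error": f"{type(err).__name__}: {err}"})


def run_replicate(
    spec: ScenarioSpec,
    methods=ALL_METHODS,
    inference_scale: str = "desk",
    mol_fit_cache: dict = None,
    use_true_phylograms: bool = False,
    alpha: float = 0.05,
    n_perm: int = detect.DEFAULT_N_PERM,
) -> list:
    """Generate one data pair, run inference, and apply the requested tests.

    ``mol_fit_cache`` (optional dict) reuses molecular ML fits across
    scenarios that share the molecular data. ``use_true_phylograms``
    bypasses ML inference and applies the distance-based tests to the
    generating phylograms (used for calibration checks).
    """
    methods = list(methods)
    pair, aln, chars, nuc_model, morph_model = simulate_replicate_data(spec)
    chrono = pair["chronogram"]
    top = chrono.topology
    results = []

    needs_ml = _ML_METHODS & set(methods)
    mol_phy = morph_phy = None
    fit_u = fit_l = None
    if needs_ml:
        if use_true_phylograms:
            mol_phy = pair["mol_phylogram"]
            morph_phy = pair["morph_phylogram"]
        else:
            from .likelihood import optimize_branch_lengths

            key = ("molfit", spec._rate_key())
            if mol_fit_cache is not None and key in mol_fit_cache:
                fit_mol = mol_fit_cache[key]
            else:
                x0 = _duration_init(chrono, spec.mol_mean_rate)
                fit_mol = optimize_branch_lengths(top, aln, nuc_model, x0=x0)
                if mol_fit_cache is not None:
                    mol_fit_cache[key] = fit_mol
            x0 = _duration_init(chrono, spec.morph_mean_rate)
            fit_morph = optimize_branch_lengths(top, chars, morph_model, x0=x0)
            from .likelihood import FitResult

            fit_u = FitResult(
                branch_lengths={
                    "mol": fit_mol.branch_lengths["mol"],
                    "morph": fit_morph.branch_lengths["morph"],
                },
                log_likelihood=fit_mol.log_likelihood + fit_morph.log_likelihood,
                n_free_params=2 * (2 * top.n_tips - 3),
                n_columns=fit_mol.n_columns + fit_morph.n_columns,
                converged=fit_mol.converged and fit_morph.converged,
            )
            mol_phy = Phylogram(top, fit_mol.branch_lengths["mol"])
            morph_phy = Phylogram(top, fit_morph.branch_lengths["morph"])
        if {"ml_aicc", "ml_bic"} & set(methods) and not use_true_phylograms:
            fit_l = fit_linked(top, aln, chars, nuc_model, morph_model, init=fit_u)

    for method in methods:
        try:
            if method == "rtt":
                seed = int(derive_rng(spec.master_seed, "perm", *spec._key()).integers(2**31))
                results.append(
                    detect.root_to_tip_test(mol_phy, morph_phy, n_perm=n_perm,
                                            alpha=alpha, seed=seed)
                )
            elif method == "sisters":
                results.append(detect.sister_pairs_test(chrono, mol_phy, morph_phy, alpha=alpha))
            elif method in ("ml_aicc", "ml_bic"):
                if fit_l is None:
                    raise ValueError("model selection requires ML fits")
                msr = information_criteria(fit_l, fit_u)
                results.append(detect.ml_modelsel_test(msr, criterion=method.split("_")[1]))
            elif method in ("bayes_rates_mean", "bayes_rates_median"):
                samples = _bayes_samples(spec, chrono, aln, chars, nuc_model, morph_model,
                                         inference_scale)
                mol_s = summarize_branch_rates(samples, partition="mol")
                morph_s = summarize_branch_rates(samples, partition="morph")
                results.append(
                    detect.bayes_branchrate_test(mol_s, morph_s,
                                                 statistic=method.rsplit("_", 1)[1],
                                                 alpha=alpha)
                )
            elif method == "bayes_bf":
                seed = int(derive_rng(spec.master_seed, "gss", *spec._key()).integers(2**31))
                steps, length = (25, 400_000) if inference_scale == "paper" else (8, 8_000)
                mls = {}
                for linkage in ("linked", "unlinked"):
                    mls[linkage] = gss_logml(
                        chrono, aln, chars, ClockModelSpec("lognormal", linkage),
                        n_steps=steps, chain_length=length, seed=seed,
                        nuc_model=nuc_model, morph_model=morph_model,
                    )
                bf = bayes_factor(mls["linked"].log_ml, mls["unlinked"].log_ml)
                results.append(detect.bayes_modelsel_test(bf["log_bf"]))
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as err:  # record, never drop silently
            warnings.warn(f"{method} failed on {spec}: {err}")
            results.append(_indeterminate(method, err))
    return results


_bayes_cache: dict = {}


def _bayes_samples(spec, chrono, aln, chars, nuc_model, morph_model, scale):
    key = (spec._key(), scale, spec.master_seed)
    if key not in _bayes_cache:
        seed = int(derive_rng(spec.master_seed, "mcmc", *spec._key()).integers(2**31))
        settings = _mcmc_settings(scale, seed)
        _bayes_cache.clear()  # keep at most one (they are large)
        _bayes_cache[key] = run_mcmc(
            chrono, aln, chars, ClockModelSpec("lognormal", "unlinked"), settings,
            nuc_model=nuc_model, morph_model=morph_model,
        )
    return _bayes_cache[key]


def _duration_init(chrono, mean_rate):
    from .likelihood import _free_edge_map

    free, _ = _free_edge_map(chrono.topology)
    return np.clip(chrono.edge_lengths[free] * mean_rate, 1e-8, 10.0)


# ---------------------------------------------------------------------------
# aggregation


_SCENARIO_COLS = ["n_taxa", "n_chars", "k_states", "sigma"]


def run_grid(cfg: GridConfig, verbose: bool = False) -> pd.DataFrame:
    """Run every (scenario, replicate, method) and return one row per test."""
    rows = []
    cache: dict = {}
    for spec in enumerate_grid(cfg):
        for rep in range(cfg.n_replicates):
            s = spec.with_replicate(rep)
            t0 = time.time()
            for res in run_replicate(
                s, cfg.methods, inference_scale=cfg.inference_scale, mol_fit_cache=cache
            ):
                rows.append(
                    {
                        "n_taxa": s.n_taxa,
                        "n_chars": s.n_chars,
                        "k_states": s.k_states,
                        "sigma": s.sigma,
                        "coupled": s.coupled,
                        "replicate": rep,
                        "method": res.method,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "detected": bool(res.detected),
                    }
                )
            if verbose:
                print(
                    f"scenario n={s.n_taxa} chars={s.n_chars} k={s.k_states} "
                    f"sigma={s.sigma} rep={rep}: {time.time() - t0:.1f}s",
                    flush=True,
                )
    return pd.DataFrame(rows)


def compute_rates(results: pd.DataFrame) -> pd.DataFrame:
    """Detection-rate table per (scenario, method, coupling).

    ``detection_rate`` is power for coupled rows and the false-positive
    rate for uncoupled rows; indeterminate results count as not detected.
    """
    grouped = (
        results.groupby(_SCENARIO_COLS + ["method", "coupled"], as_index=False)
        .agg(n_replicates=("detected", "size"), n_detected=("detected", "sum"))
    )
    grouped["detection_rate"] = grouped["n_detected"] / grouped["n_replicates"]
    return grouped


def pooled_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-weighted pooled detection rate per (method, coupling)."""
    pooled = (
        table.groupby(["method", "coupled"], as_index=False)
        .agg(n_replicates=("n_replicates", "sum"), n_detected=("n_detected", "sum"))
    )
    pooled["detection_rate"] = pooled["n_detected"] / pooled["n_replicates"]
    return pooled


def export_tables(table: pd.DataFrame, outdir) -> list:
    """Long-format CSV plus one heatmap-shaped wide CSV per method.

    Wide layout: rows are sigma x state-count, columns char-count x
    tree-size, mirroring the figure grids.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if table.empty:
        warnings.warn("empty evaluation table; nothing exported")
        return written
    long_path = outdir / "results_long.csv"
    table.to_csv(long_path, index=False)
    written.append(long_path)
    for method, sub in table.groupby("method"):
        wide = sub.pivot_table(
            index=["sigma", "k_states"],
            columns=["n_chars", "n_taxa"],
            values="detection_rate",
        )
        p = outdir / f"heatmap_{method}.csv"
        wide.to_csv(p)
        written.append(p)
    pooled = pooled_rates(table)
    p = outdir / "summary_pooled.csv"
    pooled.to_csv(p, index=False)
    written.append(p)
    return written
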