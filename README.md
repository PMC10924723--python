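# ratelink

Simulation and detection of correlated rates of molecular and morphological
evolution on fixed phylogenies.

`ratelink` implements a complete simulation-study pipeline:

- **Synthetic data** (`ratelink.synthetic`, `ratelink.trees`): birth–death
  chronograms (or user Newick trees), uncorrelated lognormal relaxed-clock
  branch rates, coupled (×1.90) or independent morphological phylograms,
  GTR+Γ+I nucleotide alignments, Mk+Γ discrete character matrices, optional
  missing-data masking.
- **Maximum likelihood** (`ratelink.likelihood`): fixed-topology pruning
  likelihoods (GTR+Γ+I, Mk+Γ, ascertainment correction), branch-length
  optimization with analytic gradients, linked ("proportionate") vs unlinked
  branch-length models, AICc/BIC model selection.
- **Bayesian inference** (`ratelink.mcmc`, `ratelink.gss`): fixed-topology
  relaxed-clock MCMC (lognormal/exponential, linked/unlinked clocks,
  optional node-time estimation), ESS diagnostics, posterior branch-rate
  summaries, generalized stepping-stone marginal likelihoods and Bayes
  factors.
- **Detection tests** (`ratelink.detect`): root-to-tip distance permutation
  correlation, independent sister-pairs contrasts, likelihood model
  selection (ΔAICc/ΔBIC > 2.5), Spearman correlation of posterior branch
  rates (mean/median, optional shortest-branch removal), Bayes-factor model
  selection (log BF > 1).
- **Evaluation harness** (`ratelink.evaluation`): the 54-scenario factorial
  grid (3 tree sizes × 3 character counts × 2 state counts × 3 rate-variation
  levels), power and false-positive-rate tables, heatmap-shaped CSV export.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (structural checks,
closed-form and enumeration oracles, calibration and recovery checks at
reduced scale).

## CLI

```sh
# simulate one scenario (config mirrors ScenarioSpec fields)
ratelink simulate --config cfg.yaml --outdir sim/ --seed 1

# fixed-topology ML fits + linked/unlinked model selection
ratelink infer-ml --topology sim/chronogram.nwk --aln sim/alignment.fasta \
    --chars sim/characters.nex --mode both --out fit

# relaxed-clock MCMC (traces + branch-rate summaries)
ratelink infer-bayes --topology sim/chronogram.nwk --aln sim/alignment.fasta \
    --chars sim/characters.nex --clock lognormal --linkage unlinked \
    --steps 200000 --seed 1 --out mc

# stepping-stone marginal likelihoods and the log Bayes factor
ratelink marginal-likelihood --topology sim/chronogram.nwk \
    --aln sim/alignment.fasta --chars sim/characters.nex --seed 1

# one detection test on phylograms
ratelink test --method rtt --mol mol.nwk --morph morph.nwk --n-perm 20000

# run a simulation grid and export power / false-positive tables
ratelink evaluate --config grid.yaml --outdir results/ --seed 1
```

Example `grid.yaml`:

```yaml
tree_sizes: [18, 45, 111]
char_counts: [10, 100, 1000]
state_counts: [2, 4]
sigmas: [0.25, 0.75, 1.25]
n_replicates: 20
coupled: true
methods: [rtt, sisters, ml_aicc, ml_bic]
```

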