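# energyscape

Energy-landscape analysis of multi-network brain activity, built around the
pairwise maximum-entropy (Ising) model.  The package is aimed at
resting-state fMRI studies that reduce each scan to the time courses of a
small set of networks (e.g. nine ICA components) and ask how a cohort's
*brain-state dynamics* — which joint activation patterns act as attractors,
how long the brain dwells in each, and how often it transitions between
them — differ between two groups and relate to behavior.

## The model

Each time point is reduced to a binary activity vector
`σ = (σ₁, …, σ_N) ∈ {−1, +1}^N` (network *i* above or below its group-mean
activity).  The maximum-entropy distribution consistent with the empirical
first and second moments is the Boltzmann distribution

    P(V_k) = exp(−E(V_k)) / Σ_j exp(−E(V_j))
    E(V_k) = − Σ_i h_i σ_i(V_k) − ½ Σ_{i≠j} J_ij σ_i(V_k) σ_j(V_k)

where `h_i` is the activation tendency of network *i* and `J_ij` the
pairwise interaction.  `h` and `J` are fitted by gradient ascent on the
log-likelihood, with model moments recomputed exactly by enumerating all
`2^N` patterns each step, so at the fixed point `⟨σ_i⟩_model = ⟨σ_i⟩_data`
and `⟨σ_i σ_j⟩_model = ⟨σ_i σ_j⟩_data`.  Fit quality is summarised by
`R = (D₁ − D₂)/D₁`, the fraction of the independent model's
Kullback–Leibler shortfall (base-2) removed by the couplings.

On the resulting energy landscape (patterns = nodes of the N-hypercube,
single-flip adjacency):

- **local minima** are patterns with energy strictly below all N neighbours;
- **basins** assign every pattern to a minimum by steepest descent;
- the **disconnectivity tree** records, for each pair of minima, the energy
  threshold (minimax saddle) at which their wells separate;
- minima are grouped into **brain states** (explicit mapping or a k-cut of
  the tree), each time point is labelled with a state, and seven
  per-subject measures are computed: appearance frequency, mean duration,
  mean energy, and total / direct / indirect / in-out transition
  frequencies;
- a **Metropolis–Hastings walk** (uniform neighbour proposal, acceptance
  `min[1, e^{E_i − E_j}]`) simulates the same dynamics from the fitted
  landscape;
- groups are compared with pooled-variance t tests (Bonferroni-corrected
  within declared measure families) and chi-square tests with post-hoc
  adjusted standardized residuals; behavior scores are correlated with the
  measures that show significant group differences.

Because the cohort data such studies use are access-restricted, the package
ships a first-class synthetic-data module: ground-truth models (random, or
a structured three-well model with planted group differences in specific
couplings), Boltzmann/Markov pattern sampling with realistic dwell times,
continuous signals whose mean-threshold binarization recovers the patterns,
and behavior scores linearly coupled to a planted dynamics measure.

## Worked example

Generate a synthetic two-group cohort (30 subjects per group, 9 networks,
140 volumes) whose patient group carries two extra "bridge" couplings
between the networks of two attractor wells, then run the full analysis:

```python
import numpy as np
from energyscape import RunConfig, analyze_cohort, make_cohort, make_planted_truth

truth = make_planted_truth()          # three balanced wells; the patient group
                                      # has two extra bridge couplings
cohort = make_cohort(truth, n_subjects_per_group=30, t_per_subject=140, seed=42)
bundle = analyze_cohort(cohort.series, RunConfig(seed=7), behavior=cohort.behavior)

for name, res in bundle.groups.items():
    print(f"{name}: R={res.accuracy.R:.3f} pearson_r={res.accuracy.pearson_r:.3f} "
          f"minima={[k for k, _ in res.basins.minima]}")
print(bundle.comparisons.head(3)[["measure", "t", "p", "p_bonferroni"]].to_string(index=False))
print(f"state-size chi2 = {bundle.state_size_chi2.chi2:.2f}")
```

prints

```
control: R=0.814 pearson_r=0.893 minima=[56, 7, 448, 504, 455, 63]
patient: R=0.686 pearson_r=0.845 minima=[448, 63]
                         measure          t            p  p_bonferroni
direct_transition_frequency_s1s2 -47.667211 3.227396e-48  9.682189e-48
       transition_frequency_s1s2 -39.464784 1.332831e-43  3.998493e-43
              inout_frequency_s2 -26.170786 8.272870e-34  2.481861e-33
state-size chi2 = 234.19
```

Reading this: the pairwise model explains ~80% of the independent model's
shortfall in the control group (`R=0.814`) and its pattern probabilities
correlate strongly with the empirical frequencies.  The control landscape
has six local minima (the three planted wells 7, 56, 448 plus three
shallow intermediates); in the patient group the planted bridge couplings
merge two wells, which reshapes the transition structure — and exactly the
transition-frequency comparisons of the affected state pair dominate the
group statistics, far ahead of everything else.

The same pipeline is scriptable from the shell:

```bash
energyscape synth --outdir cohort --n-subjects 30 --t 140 --seed 1
energyscape run-all --config config.yaml     # manifest, outdir, seed, ...
```

which writes per-group fitted parameters, the 512-row landscape table
(pattern, energy, probability, basin, state), the disconnectivity tree in
Newick format, per-subject measures, the tidy comparison table and a
`summary.json` stamped with the config hash and seed.

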