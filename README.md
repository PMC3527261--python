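# tftarget

Bayesian identification of transcription-factor (TF) targets from short gene
expression time-series, for systems biologists who know *which* TFs matter in
their system (say, a handful of regulators of a developmental program) and
want to know *which genes* each of them — or each combination of them —
regulates.

## The model

Transcription of a target gene *j* is driven by the latent protein activities
`p_i(t)` of `I` TFs through a pair of linear ODEs with a sigmoidal response:

```
dm_j/dt = b_j + s_j · G(p_1(t), …, p_I(t); w_j, w_j0) − d_j · m_j(t)
dp_i/dt = f_i(t) − δ_i · p_i(t)
G(p; w, w0) = 1 / (1 + exp(−w_j0 − Σ_i w_ji · log p_i(t)))
```

`f_i(t)` is the TF's own mRNA, `b_j, s_j, d_j` are basal rate, sensitivity
and mRNA decay, `δ_i` is protein decay, and the weights `w_ji` encode the
regulatory network: `w_ji = 0` means "TF *i* does not regulate gene *j*".
Smooth Gaussian-process priors on the `f_i` make continuous-time inference
from ~10 time points well posed.

Inference runs in two phases:

1. **Training.** On a small subnetwork of genes whose regulators are
   approximately known (the known links may contain errors), an MCMC sampler
   jointly infers the TF activities `p_i(t)`, the protein decay rates `δ_i`
   and all gene-level parameters. An optional per-gene *adaptive variance*
   flags training genes the modelled TFs cannot explain so they can be
   filtered out (robustified training).
2. **Prediction.** Holding the TF-activity posterior fixed, every candidate
   structure `x ∈ {0,1}^I` of every test gene is scored by its approximate
   Bayesian evidence `p(y | x, training data)` (a Chib-style marginal
   likelihood from a short per-gene chain). Bayes' rule over the `2^I`
   structures then yields per-gene posteriors, MAP structures, and
   single-link / TF-pair marginal probabilities for genome-wide ranking.

The package also ships the study's synthetic benchmark generator (four TFs,
one of them a deliberately unmodelled confounder, two experimental
conditions, ~1030 genes), a maximum-likelihood baseline, an
exhaustive-cross-validation regression baseline, the Inferelator
rank-combination rule, and ROC / enrichment / bootstrap evaluation tools.

## Worked example

Generate the built-in synthetic benchmark (four TFs, one an unmodelled
confounder, two conditions) and train on its 15-gene known subnetwork:

```python
from tftarget import TFActivityModel, TrainingConfig, PredictionConfig, StructureScorer
from tftarget.synthetic import SyntheticConfig, generate_benchmark

cfg = SyntheticConfig(n_train=15, grid_size=100)   # both conditions
ds = generate_benchmark(cfg, seed=1)

model = TFActivityModel(ds.expression, ds.training_network,
                        TrainingConfig(iterations=5000, burn_in=15000, grid_size=100))
posterior = model.fit(seed=1)
print(posterior.delta_summary().round(3))
```

prints the posterior over the TF protein degradation rates (1/h):

```
      q2.5  median  q97.5
ANT  0.601   0.781  1.219
BEE  0.202   0.393  0.836
CAR  0.064   0.441  1.760
```

The generating values are (0.994, 0.945, 0.640): ANT's and CAR's intervals
cover theirs, BEE's sits low in this run — with 15 genes, ten time points
and an unmodelled fourth TF, decay rates are genuinely weakly identified,
and the wide intervals say so. Scoring the first five test genes:

```python
scorer = StructureScorer(posterior, PredictionConfig(n_activity_samples=5))
table = scorer.score_genes(ds.expression, genes=ds.test_genes[:5], seed=1)
print(table.frame[["gene", "map_structure", "marg_ANT", "marg_BEE", "marg_CAR"]].round(3))
```

```
    gene map_structure  marg_ANT  marg_BEE  marg_CAR
0  G0016           000     0.010     0.009     0.066
1  G0017           100     0.960     0.187     0.107
2  G0018           000     0.106     0.020     0.060
3  G0019           000     0.011     0.024     0.037
4  G0020           000     0.399     0.114     0.309
```

`map_structure` is the most probable regulator set over (ANT, BEE, CAR) and
the `marg_*` columns are posterior link probabilities from model averaging
over all 8 structures — the scores used to rank genome-wide predictions.
Here the unregulated G0016 is called correctly, G0017 (a true ANT+BEE
target) gets a confident ANT call (marginal 0.96), and G0020's true ANT
link shows up as an elevated marginal (0.40) without reaching MAP level —
genes with weak interaction weights stay near the null, which is the
expected behaviour at this data size.

A command-line interface mirrors the library:
`tftarget simulate | train | predict | baseline | evaluate` (see `--help`).

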