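# bridgenet

Multilayer partial-correlation network analysis of cognition and brain
structure, for researchers studying how cognitive abilities and structural
brain measures covary in developmental cohorts.

## The problem

In network psychometrics, a battery of cognitive tasks is modeled as a
Gaussian graphical model (GGM): nodes are variables, edges are partial
correlations — the association between two variables after conditioning on
all others. The same machinery applies to brain structural covariance
(between-subject covariation of regional cortical volume, CV, or white-matter
fractional anisotropy, FA). Putting cognitive and neural variables in one
**multilayer** network makes it possible to ask which nodes *bridge* brain
and behavior.

`bridgenet` implements that full pipeline:

1. **Estimation.** Pearson correlations with pairwise deletion,
   positive-semidefinite repair, then the graphical lasso solved on a
   100-point log-spaced penalty path with the model chosen by the extended
   BIC, EBIC<sub>γ</sub> = −2ℓ(K̂) + E·log n + 4·E·γ·log p (γ = 0.5). The
   selected precision matrix K̂ is converted to edge weights
   w<sub>ij</sub> = −k<sub>ij</sub>/√(k<sub>ii</sub>k<sub>jj</sub>).
2. **Centrality.** Node strength s<sub>i</sub> = Σ<sub>j</sub>|w<sub>ij</sub>|
   and bridge strength (the same sum restricted to edges crossing community
   boundaries); nodes with z ≥ +1 are classified as central.
3. **Communities.** Walktrap (short random walks, Ward-style agglomeration)
   on absolute weights, cut at maximum Newman modularity Q; Q ≥ 0.5 is read
   as strong grouping, 0.3–0.5 moderate.
4. **Stability.** Case-drop bootstrap: the CS coefficient is the largest
   fraction of the sample that can be dropped while the subsample centrality
   ordering still rank-correlates ≥ 0.7 with the full-sample ordering with
   95% probability. Edge weights get percentile bootstrap intervals.

Because the motivating cohort data are not shareable, the package ships a
**synthetic-data generator**: planted population GGMs whose edge summaries
reproduce the published layer statistics (cognitive layer: mean 0.08, median
0.07, range 0–0.63 with a reading–spelling edge of 0.63; CV layer: mean
0.09, median 0, range −0.15–0.52; FA layer: mean 0.08, median 0, range
0–0.44), sampled at the cohort's nested layer sizes (805 / 246 / 165) with
the published per-task missingness rates.

## Worked example

```python
import bridgenet as bn

ggm = bn.build_preset("calm_trilayer")          # 30 variables + age
data = bn.simulate(ggm, n=805, spec=bn.MissingnessSpec.calm(), seed=1)
corr = bn.pairwise_pearson(data)                # pairwise deletion
corr.R = bn.nearest_psd(corr.R)
net = bn.ebic_glasso(corr, gamma=0.5)
part = bn.walktrap(net)
bridge = bn.bridge_strength(net, part)
print(bn.edge_summary(net))
print(part.n_communities, round(part.Q, 2), part.Q_label)
print(bridge.central_nodes)
```

The same analysis through the numbered drivers:

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_single_layer_networks.py
python analysis/03_multilayer_networks.py
python analysis/04_stability.py
python analysis/05_sensitivity.py
```

which prints, for example,

```
cognition (n=805): mean 0.07, median 0.05, range 0.00-0.60, 33/45 nonzero
  central nodes (z >= 1): ['NO']
...
trilayer: mean 0.03, median 0.00, range -0.09-0.56; 4 communities, Q = 0.41 (moderate)
  bridge-central nodes (z >= 1): ['Spell', 'Pea', 'Read', 'IFOF']
```

Read this as: at the behavioral sample size the regularized network
recovers the planted cognitive layer slightly shrunk (mean 0.07 vs the
planted 0.08; the strong reading–spelling edge estimated 0.60 vs 0.63);
combining all three layers yields a moderately modular network in which
mostly cognitive nodes carry cross-community (brain–behavior) edge mass.
Artifacts (edge lists, centrality tables, community assignments, GraphML,
JSON reports) are written under `results/`.

A thin CLI wraps the same functions:

```sh
bridgenet simulate --preset calm_cognitive --n 805 --seed 1 -o out/
bridgenet run --config cfg.json
bridgenet stability --config cfg.json -B 1000
```

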