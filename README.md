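# sedimeta

Community ordination, functional-gene comparison and predicted relative
metabolic turnover (PRMT) for contaminated-sediment metagenomics.

After a major oil spill, hydrocarbons settling onto the seafloor reshape
sediment microbial communities: bloom taxa track the contamination
gradient, hydrocarbon-degradation genes become enriched, and nitrogen
cycling shifts toward denitrification. `sedimeta` packages the standard
desk analysis of such a survey — for microbial ecologists working from an
OTU table, per-sample alignment hits and environmental chemistry — as a
tested, seed-deterministic pipeline, together with a synthetic-study
generator with planted ground truth so every stage can be validated without
field data.

## What it computes

**Community structure.** OTUs with < 10 total sequences are dropped, each
sample is rarefied without replacement to a common depth, and samples are
ordinated by non-metric multidimensional scaling (NMDS) on Bray–Curtis
dissimilarities, minimizing Kruskal stress-1

&nbsp;&nbsp;&nbsp;&nbsp;stress = √( Σᵢⱼ (d̂ᵢⱼ − δᵢⱼ)² / Σᵢⱼ δᵢⱼ² ),

with δ the configuration distances and d̂ their isotonic regression on the
dissimilarity ranks. Environmental variables (TPH, DIN, NH₃-N, NO₃-N) are
fitted as directions in the ordination; significance comes from permuting
the variable (999 permutations, p = (1 + #{r²ₚₑᵣₘ ≥ r²}) / 1000).

**Functional comparison.** Alignment hits are filtered (e-value ≤ 10⁻⁵,
identity ≥ 60 %, length ≥ 15), each read keeps its best hit at ≥ 40 bits,
and gene-family percent proportions are compared between samples exceeding
and not exceeding the EPA aquatic-life benchmark with two-sided Welch
t-tests (0.95 CI, effect filter |Δ proportion| ≥ 1.00 pp, BH q-values).
A bipartite sample–function network keeps edges with ≥ 20 observations.

**PRMT.** A reaction database is condensed into the environmental
transformation matrix W (metabolites × ECs, W[m,e] = mean signed
stoichiometry ±ν over the EC's reactions); EC abundances A are quantile
normalized and log₂ transformed, and each metabolite is scored against the
mean-of-samples reference,

&nbsp;&nbsp;&nbsp;&nbsp;S[m, j] = Σₑ W[m, e] · (A[e, j] − Ā[e]),

so positive scores predict relative consumption and negative scores
relative accumulation. Groups are compared by rank-sum statistics with
1000-permutation p-values.

See `docs/methods.md` for assumptions, defaults and numerical choices, and
`docs/formats.md` for the file formats.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (written under `results/`):

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_community_ordination.py --seed 1
python analysis/04_prmt_turnover.py --seed 1
```

The community step prints

```
NMDS stress = 0.0053 (converged: False)
  envfit tph   : r2 = 0.878, p = 0.001
  envfit din   : r2 = 0.753, p = 0.001
  envfit nh3_n : r2 = 0.769, p = 0.001
  envfit no3_n : r2 = 0.059, p = 0.130
```

— the ordination is essentially one contamination axis (very low stress),
and TPH, DIN and ammonium align with it at the minimum permutation p of
0.001, while nitrate (not planted as a gradient variable) does not. The
PRMT step prints

```
metabolite_id        direction  score_gap  p_value
NO3-            consumption_up     2.8219   0.0030
NO              consumption_up     1.2848   0.0030
N2             accumulation_up    -1.1156   0.0060
NO2-           accumulation_up    -1.3863   0.0130
N2O            accumulation_up    -0.3288   0.4585
...
```

— with denitrification enzymes planted 4× enriched in the contaminated
group, the pipeline predicts increased nitrate consumption and dinitrogen /
nitrite accumulation there, matching the planted ground truth
(`results/study/ground_truth.json`). `analysis/03_functional_comparison.py`
recovers exactly the nine planted gene families as significant, and
`analysis/05_null_calibration.py` shows both test stages calling
significance at ≈ 5 % on a study with nothing planted.

The same stages are available programmatically
(`sedimeta.community`, `sedimeta.func_profile`, `sedimeta.prmt`,
`sedimeta.synthetic`) or as one orchestrated, manifest-writing run:

```python
from sedimeta.pipeline import RunConfig, run_all
manifest = run_all(RunConfig(out_dir="run", master_seed=7))
```

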