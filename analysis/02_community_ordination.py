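#!/usr/bin/env python
"""Community structure: filter, rarefy, ordinate, fit environmental vectors.

Filters OTUs below 10 total sequences, rarefies to a common depth, runs NMDS
on Bray-Curtis dissimilarities and fits TPH and nitrogen variables onto the
ordination with 999-permutation p-values. Writes ordination.tsv, envfit.tsv
and species_scores.tsv under results/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from sedimeta.community import bray_curtis, envfit, filter_min_count, nmds, rarefy, species_scores
from sedimeta.io import read_feature_table, read_metadata
from sedimeta.pipeline import derive_stage_seed

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--study", type=Path, default=Path("results/study"))
ap.add_argument("--depth", type=int, default=122_804)
args = ap.parse_args()

seed = derive_stage_seed(args.seed, "community")
table = read_feature_table(args.study / "otu_table.tsv")
metadata = read_metadata(args.study / "metadata.tsv")
meta_df = pd.DataFrame([dataclasses.asdict(m) for m in metadata]).set_index("sample_id")

filtered = filter_min_count(table, 10)
rarefied = rarefy(filtered, args.depth, seed=seed)
print(f"kept {filtered.shape[0]}/{table.shape[0]} OTUs, rarefied {rarefied.shape[1]} samples to {args.depth}")

ordination = nmds(bray_curtis(rarefied), k=2, n_restarts=20, seed=seed + 1)
print(f"NMDS stress = {ordination.stress:.4f} (converged: {ordination.converged})")

out = Path("results")
out.mkdir(exist_ok=True)
pd.DataFrame(ordination.coords, index=ordination.sample_ids, columns=["axis1", "axis2"]).to_csv(
    out / "ordination.tsv", sep="\t", index_label="sample_id"
)

rows = []
for i, var in enumerate(("tph", "din", "nh3_n", "no3_n")):
    fit = envfit(ordination, meta_df[var], n_permutations=999, seed=seed + 2 + i, variable=var)
    rows.append({"variable": var, "r_squared": fit.r_squared, "p_value": fit.p_value})
    print(f"  envfit {var:6s}: r2 = {fit.r_squared:.3f}, p = {fit.p_value:.3f}")
pd.DataFrame(rows).to_csv(out / "envfit.tsv", sep="\t", index=False)

truth = json.loads((args.study / "ground_truth.json").read_text())
responders = [r for r in truth["responder_otu_ids"] if r in rarefied.data.index]
scores = species_scores(rarefied, ordination, responders)
scores.to_csv(out / "species_scores.tsv", sep="\t", index_label="feature_id")
print(f"responder species scores (abundance-weighted ordination positions):\n{scores.round(3)}")
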