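#!/usr/bin/env python
"""Functional-gene comparison of exceed vs non-exceed samples.

Filters alignment hits (e-value <= 1e-5, identity >= 60%, length >= 15),
assigns each read its best hit at >= 40 bits, converts gene-family counts to
percent proportions and runs two-sided Welch tests with a 1.00
percentage-point effect filter. Also writes the sample-function network
(edges >= 20 observations) and the hydrocarbon category profile.
"""

import argparse
from pathlib import Path

import pandas as pd

from sedimeta.community import relative_abundance
from sedimeta.func_profile import (
    assign_best_hits,
    build_network,
    compare_groups_welch,
    comparison_frame,
    filter_hits,
    hydrocarbon_category_profile,
)
from sedimeta.io import read_hit_table, read_metadata

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study"))
args = ap.parse_args()

hits_by_sample = {
    p.stem: filter_hits(read_hit_table(p)) for p in sorted((args.study / "hits").glob("*.tsv"))
}
counts = assign_best_hits(hits_by_sample)
metadata = read_metadata(args.study / "metadata.tsv")
exceed = [m.sample_id for m in metadata if m.exceeds_epa_bm and m.sample_id in counts.data.columns]
nonexceed = [m.sample_id for m in metadata if not m.exceeds_epa_bm and m.sample_id in counts.data.columns]
print(f"assigned {int(counts.counts.sum())} reads to {counts.shape[0]} gene families "
      f"({len(exceed)} exceed vs {len(nonexceed)} non-exceed samples)")

out = Path("results")
out.mkdir(exist_ok=True)
results = compare_groups_welch(relative_abundance(counts), exceed, nonexceed)
frame = comparison_frame(results)
frame.to_csv(out / "welch_comparison.tsv", sep="\t")
sig = frame[(frame["p_value"] <= 0.05) & frame["passed_effect_filter"]]
print(f"{len(sig)} families significant (p <= 0.05, |diff| >= 1.00 pp); largest shifts:")
print(sig.sort_values("diff_proportions", ascending=False)[["diff_proportions", "p_value"]].head(8).round(4))

network = build_network(counts, min_count=20)
network.to_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False)
print(f"sample-function network: {len(network.edges)} edges")

category_map = dict(
    pd.read_csv(args.study / "hydrocarbon_categories.tsv", sep="\t", dtype=str)
    .itertuples(index=False, name=None)
)
hydro = hydrocarbon_category_profile(counts, category_map)
hydro.data.to_csv(out / "hydrocarbon_profile.tsv", sep="\t", index_label="category")
print(f"hydrocarbon category counts:\n{hydro.data.sum(axis=1)}")
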