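#!/usr/bin/env python
"""Negative control: the pipeline on a study with nothing planted.

Regenerates the study with enrichment_fold = 1 and no responder taxa, then
measures how often each stage calls significance at alpha = 0.05. Rates near
0.05 show the permutation and Welch machinery is calibrated rather than
signal-hungry.
"""

import argparse

import numpy as np

from sedimeta.community import relative_abundance
from sedimeta.func_profile import compare_groups_welch
from sedimeta.prmt import build_etm, compare_prmt_groups, normalize_ec_abundance, prmt_scores
from sedimeta.synthetic import StudyConfig, generate_functional_data, generate_metadata

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-replicates", type=int, default=10)
args = ap.parse_args()

welch_calls, prmt_calls = [], []
for rep in range(args.n_replicates):
    cfg = StudyConfig(seed=args.seed + rep, enrichment_fold=1.0, responder_max_fraction=0.0)
    md = generate_metadata(cfg)
    func = generate_functional_data(cfg, md, with_hits=False)
    props = relative_abundance(func.ec_table)
    for r in compare_groups_welch(props, func.exceed_samples, func.nonexceed_samples,
                                  effect_threshold=0.0):
        welch_calls.append(r.p_value <= 0.05)
    scores = prmt_scores(normalize_ec_abundance(func.ec_table), build_etm(func.reactions))
    for c in compare_prmt_groups(scores, func.exceed_samples, func.nonexceed_samples,
                                 n_permutations=500, seed=args.seed + rep):
        prmt_calls.append(c.p_value <= 0.05)

for name, calls in (("Welch", welch_calls), ("PRMT rank-sum", prmt_calls)):
    rate = float(np.mean(calls))
    print(f"{name}: {int(np.sum(calls))}/{len(calls)} significant at alpha=0.05 "
          f"(rate {rate:.3f}; calibrated tests sit near 0.050)")
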