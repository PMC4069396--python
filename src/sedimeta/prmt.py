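"""Predicted relative metabolic turnover (PRMT).

PRMT turns per-sample enzyme (EC) abundances into metabolite-level turnover
scores. A reaction database is condensed into the environmental
transformation matrix (ETM), a metabolites x ECs weight matrix built from
signed stoichiometry: a metabolite consumed by an EC's reactions gets a
positive weight, one produced a negative weight. EC abundances are quantile
normalized and log2 transformed; each sample's deviation from the
mean-of-samples reference is pushed through the ETM, so a positive score
predicts relative consumption of that metabolite and a negative score
relative accumulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CURRENCY_METABOLITES",
    "ETM",
    "PRMTScores",
    "NormalizedAbundance",
    "PrmtComparison",
    "build_etm",
    "normalize_ec_abundance",
    "prmt_scores",
    "compare_prmt_groups",
    "annotate_metabolite_directions",
]

#: Ubiquitous cofactors excluded from ETM rows by default. Nitrogen species
#: are never excluded by default — they are the analysis target here.
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {"H2O", "H+", "ATP", "ADP", "Orthophosphate", "NAD+", "NADH", "NADP+", "NADPH", "CoA"}
)


@dataclass(frozen=True)
class ETM:
    """Environmental transformation matrix: metabolites x ECs weights."""

    W: pd.DataFrame  # index = metabolite ids, columns = EC ids

    @property
    def metabolite_ids(self) -> list[str]:
        return [str(m) for m in self.W.index]

    @property
    def ec_ids(self) -> list[str]:
        return [str(e) for e in self.W.columns]


@dataclass(frozen=True)
class PRMTScores:
    """Metabolites x samples turnover scores relative to the sample mean.

    Positive = predicted relative consumption; negative = accumulation. With
    the mean-of-samples reference every metabolite row sums to zero.
    """

    S: pd.DataFrame
    reference: str = "mean of samples"

    def __post_init__(self) -> None:
        if self.reference == "mean of samples" and self.S.size:
            row_sums = self.S.to_numpy().sum(axis=1)
            scale = max(1.0, float(np.abs(self.S.to_numpy()).max()))
            if not np.allclose(row_sums, 0.0, rtol=0, atol=1e-9 * scale):
                raise ValueError("score rows do not sum to zero under the mean reference")

    @property
    def metabolite_ids(self) -> list[str]:
        return [str(m) for m in self.S.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.S.columns]


@dataclass(frozen=True)
class NormalizedAbundance:
    """EC x sample abundances after quantile normalization and log2(x + 1)."""

    A: pd.DataFrame

    @property
    def ec_ids(self) -> list[str]:
        return [str(e) for e in self.A.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.A.columns]


@dataclass(frozen=True)
class PrmtComparison:
    metabolite_id: str
    statistic: float
    p_value: float
    mean_score_a: float
    mean_score_b: float
    n_permutations: int
    paired: bool


def build_etm(
    reactions: list[Reaction],
    currency_exclusions: frozenset[str] | set[str] = DEFAULT_CURRENCY_METABOLITES,
    ec_aggregation: str = "mean",
    skip_reversible: bool = False,
) -> ETM:
    """Condense a reaction database into metabolite x EC weights.

    For EC ``e`` with reaction set R_e, W[m, e] = (1/|R_e|) * sum over r of
    s(m, r) where s is +nu if m is a substrate of r (coefficient nu), -nu if
    a product, 0 otherwise. Averaging over |R_e| keeps promiscuous ECs from
    dominating; ``ec_aggregation='sum'`` disables the normalization.
    Reversible reactions are scored in the written direction unless
    ``skip_reversible``. Currency metabolites produce no row.
    """
    if not reactions:
        raise ValueError("empty reaction list")
    if ec_aggregation not in ("mean", "sum"):
        raise ValueError("ec_aggregation must be 'mean' or 'sum'")
    per_ec: dict[str, list[Reaction]] = {}
    for r in reactions:
        if skip_reversible and r.reversible:
            continue
        for ec in r.ec_numbers:
            per_ec.setdefault(ec, []).append(r)
    if not per_ec:
        raise ValueError("no usable reactions after reversibility filtering")
    metabolites = sorted(
        {
            m
            for rxns in per_ec.values()
            for r in rxns
            for m, _ in (*r.substrates, *r.products)
            if m not in currency_exclusions
        }
    )
    ecs = sorted(per_ec)
    w = pd.DataFrame(0.0, index=metabolites, columns=ecs)
    for ec, rxns in per_ec.items():
        denom = len(rxns) if ec_aggregation == "mean" else 1
        for r in rxns:
            for m, nu in r.substrates:
                if m in w.index:
                    w.loc[m, ec] += nu / denom
            for m, nu in r.products:
                if m in w.index:
                    w.loc[m, ec] -= nu / denom
    return ETM(W=w)


def normalize_ec_abundance(table: FeatureTable) -> NormalizedAbundance:
    """Quantile normalize sample columns, then log2(x + 1).

    Each value is replaced by the mean of the sorted values at its rank
    across samples; ties receive the mean of their rank positions' reference
    values, so identical input columns are left unchanged and all output
    columns share one sorted value multiset.
    """
    if table.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = table.counts
    order_stats = np.sort(x, axis=0)          # per-sample sorted columns
    reference = order_stats.mean(axis=1)      # mean across samples at each rank
    qn = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        ranks = stats.rankdata(col, method="average")  # 1-based, ties averaged
        # interpolate the reference at fractional (tied) rank positions
        qn[:, j] = np.interp(ranks, np.arange(1, len(col) + 1), reference)
    out = pd.DataFrame(np.log2(qn + 1.0), index=table.data.index, columns=table.data.columns)
    return NormalizedAbundance(A=out)


def prmt_scores(abundance: NormalizedAbundance, etm: ETM) -> PRMTScores:
    """Score metabolites: S[m, j] = sum_e W[m, e] * (A[e, j] - mean_j' A[e, j']).

    ECs absent from the ETM are dropped with a warning; a disjoint EC set is
    an error. The reference is the mean of all samples, so each row of S sums
    to zero and positive scores mean relative consumption.
    """
    shared = [e for e in abundance.ec_ids if e in etm.W.columns]
    missing = [e for e in abundance.ec_ids if e not in etm.W.columns]
    if not shared:
        raise ValueError("no ECs shared between abundance table and ETM")
    if missing:
        logger.warning("prmt_scores: dropping %d feature(s) absent from ETM", len(missing))
        logger.debug("prmt_scores: dropped features: %s", missing)
    a = abundance.A.loc[shared]
    deviations = a.sub(a.mean(axis=1), axis=0)
    s = etm.W[shared].to_numpy() @ deviations.to_numpy()
    return PRMTScores(
        S=pd.DataFrame(s, index=etm.W.index, columns=abundance.A.columns),
        reference="mean of samples",
    )


def _ranksum_stat(pooled_ranks: np.ndarray, idx_a: np.ndarray) -> float:
    return float(pooled_ranks[idx_a].sum())


def compare_prmt_groups(
    scores: PRMTScores,
    group_a: list[str],
    group_b: list[str],
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    paired: bool = False,
) -> list[PrmtComparison]:
    """Permutation Wilcoxon comparison of per-metabolite scores between groups.

    Unpaired (default): the rank-sum statistic W of group A with a two-sided
    permutation p-value under group-label permutation,
    p = (1 + #{ |W_perm - E0| >= |W_obs - E0| }) / (1 + n_permutations),
    with E0 the null expectation n_a (n_a + n_b + 1) / 2. Paired: the
    signed-rank statistic with sign-flip permutations (groups matched by
    position). The add-one estimator keeps p >= 1/(n_permutations + 1).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    missing = [s for s in list(group_a) + list(group_b) if s not in scores.S.columns]
    if missing:
        raise KeyError(f"group samples not in score matrix: {missing}")
    rng = np.random.default_rng(seed)
    a = scores.S[list(group_a)].to_numpy(dtype=float)
    b = scores.S[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]

    results = []
    if paired:
        if na != nb:
            raise ValueError("paired mode requires equal group sizes")
        if na < 2:
            raise ValueError("paired mode requires >= 2 pairs")
        diffs = a - b
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, na))
        for i, mid in enumerate(scores.metabolite_ids):
            d = diffs[i]
            nz = d != 0
            if not nz.any():
                results.append(
                    PrmtComparison(mid, 0.0, 1.0, float(a[i].mean()), float(b[i].mean()), n_permutations, True)
                )
                continue
            ranks = stats.rankdata(np.abs(d[nz]))
            obs = float(np.sum(np.sign(d[nz]) * ranks))
            perm = (signs[:, nz] * ranks) .sum(axis=1)
            exceed = int(np.sum(np.abs(perm) >= abs(obs) - 1e-12))
            p = (1 + exceed) / (1 + n_permutations)
            results.append(
                PrmtComparison(mid, obs, p, float(a[i].mean()), float(b[i].mean()), n_permutations, True)
            )
        return results

    if na < 2 or nb < 2:
        raise ValueError("unpaired mode requires >= 2 samples per group")
    pooled = np.concatenate([a, b], axis=1)
    n = na + nb
    e0 = na * (n + 1) / 2.0
    # one shared set of label permutations across metabolites
    perm_idx = np.array([rng.permutation(n)[:na] for _ in range(n_permutations)])
    for i, mid in enumerate(scores.metabolite_ids):
        vals = pooled[i]
        if np.ptp(vals) == 0:
            results.append(
                PrmtComparison(mid, e0, 1.0, float(a[i].mean()), float(b[i].mean()), n_permutations, False)
            )
            continue
        ranks = stats.rankdata(vals)
        obs = float(ranks[:na].sum())
        perm_stats = ranks[perm_idx].sum(axis=1)
        exceed = int(np.sum(np.abs(perm_stats - e0) >= abs(obs - e0) - 1e-12))
        p = (1 + exceed) / (1 + n_permutations)
        results.append(
            PrmtComparison(mid, obs, p, float(a[i].mean()), float(b[i].mean()), n_permutations, False)
        )
    return results


def annotate_metabolite_directions(
    comparisons: list[PrmtComparison],
) -> pd.DataFrame:
    """Label each metabolite's shift between groups by the sign of the score gap.

    Direction is ``consumption_up`` when group A's mean score exceeds group
    B's (relative consumption increased in A), ``accumulation_up`` when it is
    lower, and ``ambiguous`` at exact equality.
    """
    rows = []
    for c in comparisons:
        gap = c.mean_score_a - c.mean_score_b
        if gap > 0:
            direction = "consumption_up"
        elif gap < 0:
            direction = "accumulation_up"
        else:
            direction = "ambiguous"
        rows.append(
            {
                "metabolite_id": c.metabolite_id,
                "direction": direction,
                "score_gap": gap,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows, columns=["metabolite_id", "direction", "score_gap", "p_value"]).set_index(
        "metabolite_id"
    )
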