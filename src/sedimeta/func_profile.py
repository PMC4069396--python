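"""Metagenome functional comparison.

Hit filtering, best-hit assignment to gene families, hierarchical
aggregation, exceed vs non-exceed Welch tests on per-sample proportions with
an effect-size filter, and the sample-function bipartite network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, HierarchyMap, HitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "SampleFunctionNetwork",
    "filter_hits",
    "assign_best_hits",
    "aggregate_hierarchy",
    "compare_groups_welch",
    "build_network",
    "hydrocarbon_category_profile",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Per-feature two-group Welch comparison of proportions (percent scale)."""

    feature_id: str
    mean_prop_a: float
    mean_prop_b: float
    diff_proportions: float  # percentage points, A - B
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float  # BH over features passing the effect filter; nan otherwise
    passed_effect_filter: bool

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.diff_proportions <= self.ci_high + 1e-12):
            raise ValueError("confidence interval does not bracket the difference")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")
        if not np.isnan(self.q_value) and self.q_value < self.p_value - 1e-12:
            raise ValueError("q-value below p-value")


@dataclass(frozen=True)
class SampleFunctionNetwork:
    """Bipartite sample-function edge list with count weights."""

    edges: list[tuple[str, str, float]]  # (sample_id, function_id, weight)
    sample_nodes: list[str]
    function_nodes: list[str]
    min_count: float

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.sample_nodes, bipartite="sample")
        g.add_nodes_from(self.function_nodes, bipartite="function")
        g.add_weighted_edges_from(self.edges)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["sample_id", "function_id", "weight"])


def filter_hits(
    hits: Iterable[HitRecord],
    evalue_max: float = 1e-5,
    identity_min: float = 60.0,
    length_min: int = 15,
) -> Iterable[HitRecord]:
    """Keep hits with e-value <= max, identity >= min and length >= min.

    All boundaries are inclusive on the stated side: a hit at exactly
    (1e-5, 60%, 15) is kept.
    """
    for h in hits:
        if h.evalue <= evalue_max and h.pct_identity >= identity_min and h.aln_length >= length_min:
            yield h


def assign_best_hits(
    hits_by_sample: Mapping[str, Iterable[HitRecord]],
    bitscore_min: float = 40.0,
) -> FeatureTable:
    """Assign each query its single best hit and count per (gene family, sample).

    Hits below ``bitscore_min`` (exclusive: >= 40 is kept) are discarded; the
    surviving hit with the highest bit score wins. Equal bit scores break to
    the lexicographically smallest subject id, so the result is independent of
    input order.
    """
    counts: dict[str, dict[str, int]] = {}
    for sample_id, hits in hits_by_sample.items():
        best: dict[str, tuple[float, str]] = {}
        for h in hits:
            if h.bit_score < bitscore_min:
                continue
            key = (h.bit_score, h.subject_id)
            cur = best.get(h.query_id)
            # higher bit score wins; tie -> lexicographically smaller subject
            if cur is None or key[0] > cur[0] or (key[0] == cur[0] and key[1] < cur[1]):
                best[h.query_id] = key
        col = counts.setdefault(sample_id, {})
        for _score, subject in best.values():
            col[subject] = col.get(subject, 0) + 1
    families = sorted({f for col in counts.values() for f in col})
    data = pd.DataFrame(
        {s: [counts[s].get(f, 0) for f in families] for s in counts},
        index=families,
        dtype=np.int64,
    )
    if not families:
        data = pd.DataFrame(index=pd.Index([], dtype=object), columns=list(counts), dtype=np.int64)
    return FeatureTable(data, units_tag="counts")


def aggregate_hierarchy(table: FeatureTable, hmap: HierarchyMap, level: int | str) -> FeatureTable:
    """Sum counts within hierarchy categories at ``level`` (1, 2, 3 or 'function').

    ``level='function'`` is the identity aggregation. Column totals are
    conserved; an unmapped feature is an error listing the offending ids.
    """
    if level == "function":
        return table
    unmapped = [f for f in table.feature_ids if f not in hmap]
    if unmapped:
        raise KeyError(f"features missing from hierarchy map: {unmapped}")
    cats = [hmap.level(f, int(level)) for f in table.feature_ids]
    grouped = table.data.groupby(pd.Index(cats, name="category"), sort=True).sum()
    return FeatureTable(grouped, units_tag=table.units_tag)


def _welch(a: np.ndarray, b: np.ndarray, confidence: float) -> tuple[float, float, float, float]:
    """Welch t-test of two samples: (p, diff, ci_low, ci_high)."""
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    se2 = va / na + vb / nb
    if se2 == 0:
        # both groups constant: equal means -> no evidence (p = 1);
        # distinct constants -> degenerate complete separation
        if diff == 0:
            return 1.0, 0.0, 0.0, 0.0
        return np.finfo(float).tiny, diff, diff, diff
    se = np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df)
    return max(p, np.finfo(float).tiny), diff, diff - tcrit * se, diff + tcrit * se


def compare_groups_welch(
    table: FeatureTable,
    group_a: list[str],
    group_b: list[str],
    confidence: float = 0.95,
    effect_threshold: float = 1.00,
) -> list[ComparisonResult]:
    """Two-sided Welch's t-test per feature on per-sample percent proportions.

    ``passed_effect_filter`` is |difference of mean proportions| >= the
    threshold (1.00 percentage point by default); BH q-values are computed
    over the features that pass the filter only.
    """
    if table.units_tag != "proportions":
        raise ValueError("compare_groups_welch expects a proportions (percent) table")
    missing = [s for s in list(group_a) + list(group_b) if s not in table.data.columns]
    if missing:
        raise KeyError(f"group samples not in table: {missing}")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")

    a = table.data[list(group_a)].to_numpy(dtype=float)
    b = table.data[list(group_b)].to_numpy(dtype=float)
    results = []
    for i, fid in enumerate(table.feature_ids):
        p, diff, lo, hi = _welch(a[i], b[i], confidence)
        results.append(
            dict(
                feature_id=fid,
                mean_prop_a=float(a[i].mean()),
                mean_prop_b=float(b[i].mean()),
                diff_proportions=float(diff),
                ci_low=float(lo),
                ci_high=float(hi),
                p_value=float(p),
                passed_effect_filter=bool(abs(diff) >= effect_threshold),
            )
        )
    passing = [r for r in results if r["passed_effect_filter"]]
    if passing:
        qs = multipletests([r["p_value"] for r in passing], method="fdr_bh")[1]
        for r, q in zip(passing, qs):
            r["q_value"] = float(max(q, r["p_value"]))
    out = []
    for r in results:
        r.setdefault("q_value", float("nan"))
        out.append(ComparisonResult(**r))
    return out


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("feature_id")


def build_network(table: FeatureTable, min_count: float = 20) -> SampleFunctionNetwork:
    """Bipartite sample-function network; edges require count >= ``min_count``.

    The boundary is inclusive: a function observed exactly 20 times in a
    sample keeps its edge, 19 loses it.
    """
    edges = []
    counts = table.data
    for sample in counts.columns:
        col = counts[sample]
        for fid, c in col[col >= min_count].items():
            edges.append((str(sample), str(fid), float(c)))
    return SampleFunctionNetwork(
        edges=edges,
        sample_nodes=[str(s) for s in counts.columns],
        function_nodes=[str(f) for f in counts.index],
        min_count=float(min_count),
    )


def hydrocarbon_category_profile(
    table: FeatureTable, category_map: Mapping[str, str]
) -> FeatureTable:
    """Aggregate gene families into hydrocarbon-degradation classes.

    Families absent from ``category_map`` go to an ``unclassified`` row (with
    a logged count), so column totals are conserved.
    """
    cats = []
    n_unmapped = 0
    for f in table.feature_ids:
        if f in category_map:
            cats.append(category_map[f])
        else:
            cats.append("unclassified")
            n_unmapped += 1
    if n_unmapped:
        logger.info("hydrocarbon_category_profile: %d unmapped families -> 'unclassified'", n_unmapped)
    grouped = table.data.groupby(pd.Index(cats, name="category"), sort=True).sum()
    return FeatureTable(grouped, units_tag=table.units_tag)
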