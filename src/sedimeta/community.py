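"""16S community-structure analysis.

Filtering and rarefaction of an OTU table, Bray-Curtis dissimilarity,
non-metric multidimensional scaling (NMDS, Kruskal stress-1) and fitting of
environmental vectors onto the ordination with permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "Ordination",
    "EnvfitResult",
    "filter_min_count",
    "rarefy",
    "bray_curtis",
    "nmds",
    "envfit",
    "species_scores",
    "relative_abundance",
]


@dataclass(frozen=True)
class Ordination:
    """NMDS sample scores: centered, principal-axis rotated coordinates."""

    sample_ids: list[str]
    coords: np.ndarray  # |samples| x k
    stress: float
    n_restarts_used: int
    converged: bool

    def __post_init__(self) -> None:
        means = self.coords.mean(axis=0)
        if not np.allclose(means, 0.0, rtol=0, atol=1e-9):
            raise ValueError("ordination coordinates are not centered")
        if self.stress < 0:
            raise ValueError("negative stress")


@dataclass(frozen=True)
class EnvfitResult:
    """One environmental variable fitted as a direction in ordination space."""

    variable: str
    direction: np.ndarray  # unit vector, length k
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples_used: int

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction is not a unit vector")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if not self.p_value >= 1.0 / (self.n_permutations + 1) - 1e-15:
            raise ValueError("p-value below permutation lower bound")


def filter_min_count(table: FeatureTable, min_total: int) -> FeatureTable:
    """Keep features whose total count across all samples is >= ``min_total``.

    The boundary is inclusive: a feature with exactly ``min_total`` sequences
    is retained. The sample set is unchanged.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if table.units_tag != "counts":
        raise ValueError("filter_min_count expects a counts table")
    totals = table.data.sum(axis=1)
    kept = table.data.loc[totals >= min_total]
    return FeatureTable(kept, units_tag="counts")


def rarefy(table: FeatureTable, depth: int, seed: int | np.random.Generator) -> FeatureTable:
    """Subsample each sample WITHOUT replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a logged warning.
    Per-sample draws are multivariate hypergeometric, so expectations are
    ``depth * count / total`` and no count can exceed its input value.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.units_tag != "counts":
        raise ValueError("rarefy expects a counts table")
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    out_cols = {}
    for j, sid in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        out_cols[sid] = rng.multivariate_hypergeometric(counts[:, j], depth)
    result = pd.DataFrame(out_cols, index=table.data.index, dtype=np.int64)
    if not out_cols:
        result = pd.DataFrame(index=table.data.index, dtype=np.int64)
    return FeatureTable(result, units_tag="counts")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(u, v) = sum_f |u_f - v_f| / sum_f (u_f + v_f), in [0, 1].
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = table.counts.T  # samples x features
    col_sums = x.sum(axis=1)
    if np.any(col_sums == 0):
        bad = [s for s, t in zip(table.sample_ids, col_sums) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def _kruskal_stress(config_d: np.ndarray, fitted: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (dhat - delta)^2 / sum delta^2)."""
    denom = float(np.sum(config_d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((fitted - config_d) ** 2) / denom))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling used as the first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def _nmds_single(
    d: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool, list[float]]:
    """One NMDS run: alternate isotonic fit and a guarded Guttman update.

    An update is accepted only if it lowers stress-1 (with step halving on
    failure), so the stress sequence is non-increasing by construction.
    """
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    diss = d[iu]
    iso = IsotonicRegression(increasing=True)

    def _stress_of(x: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        delta = squareform(np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)), checks=False)
        # primary tie approach: tied dissimilarities are sub-sorted by the
        # configuration distance, so ties impose no monotonicity constraint
        order = np.lexsort((delta, diss))
        dhat_sorted = iso.fit_transform(np.arange(len(diss)), delta[order])
        dhat = np.empty_like(delta)
        dhat[order] = dhat_sorted
        return _kruskal_stress(delta, dhat), delta, dhat

    x = x0.copy()
    stress, delta, dhat = _stress_of(x)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        # Guttman transform toward the monotone-fitted distances
        full_delta = squareform(delta)
        full_dhat = squareform(dhat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(full_delta > 0, full_dhat / np.where(full_delta > 0, full_delta, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_new = (b @ x) / n

        accepted = False
        for _halve in range(8):
            s_new, delta_new, dhat_new = _stress_of(x_new)
            if s_new <= stress:
                accepted = True
                break
            x_new = 0.5 * (x_new + x)
        if not accepted:
            converged = True
            break
        rel_change = (stress - s_new) / max(stress, np.finfo(float).tiny)
        x, stress, delta, dhat = x_new, s_new, delta_new, dhat_new
        trace.append(stress)
        if rel_change < tol or stress < 1e-12:
            converged = True
            break
    return x, stress, converged, trace


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | np.random.Generator = 0,
) -> Ordination:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    The first start is a metric (Torgerson) initialization; the remaining
    ``n_restarts - 1`` starts are random. The best configuration by stress is
    returned (ties broken by lowest restart index), centered and rotated to
    its principal axes.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    scale = d[np.triu_indices(n, 1)].max() or 1.0

    best = None
    for r in range(max(1, n_restarts)):
        x0 = _classical_mds(d, k) if r == 0 else rng.normal(scale=scale, size=(n, k))
        x, stress, converged, _ = _nmds_single(d, x0, max_iter=max_iter, tol=tol)
        if best is None or stress < best[1] - 1e-15:
            best = (x, stress, converged, r)
    x, stress, converged, _ = best

    x = x - x.mean(axis=0)
    # rotate to principal axes (deterministic sign: largest-|loading| positive)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for axis in range(x.shape[1]):
        col = x[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            x[:, axis] = -col
    x = x - x.mean(axis=0)
    return Ordination(
        sample_ids=list(dm.ids),
        coords=x,
        stress=stress,
        n_restarts_used=max(1, n_restarts),
        converged=converged,
    )


def envfit(
    ord_: Ordination,
    values: "pd.Series | dict[str, float]",
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    variable: str | None = None,
) -> EnvfitResult:
    """Fit an environmental variable as a direction in ordination space.

    The (centered) variable is regressed on the ordination coordinates; the
    direction is the unit regression-coefficient vector and r-squared the
    regression R^2. The p-value permutes the raw variable values across
    samples: p = (1 + #{permuted r2 >= observed}) / (1 + n_permutations).
    Samples with a missing value are excluded from this variable's fit only.
    """
    if isinstance(values, dict):
        values = pd.Series(values)
    name = variable or (values.name if values.name is not None else "variable")
    values = values.reindex(ord_.sample_ids)
    mask = values.notna().to_numpy()
    n_used = int(mask.sum())
    if n_used < 3:
        raise ValueError(f"envfit needs >= 3 non-missing samples, got {n_used}")
    v = values.to_numpy(dtype=float)[mask]
    if np.ptp(v) == 0:
        raise ValueError("constant variable")
    x = ord_.coords[mask]
    xc = x - x.mean(axis=0)
    # orthonormal basis of the centered coordinates: r2 is a projection norm
    q, _ = np.linalg.qr(xc)

    def _r2(vals: np.ndarray) -> float:
        vc = vals - vals.mean()
        sst = float(vc @ vc)
        proj = q.T @ vc
        return float(proj @ proj) / sst

    r2_obs = _r2(v)
    coef, *_ = np.linalg.lstsq(xc, v - v.mean(), rcond=None)
    norm = np.linalg.norm(coef)
    direction = coef / norm if norm > 0 else np.eye(len(coef))[0]

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if _r2(rng.permutation(v)) >= r2_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return EnvfitResult(
        variable=str(name),
        direction=direction,
        r_squared=min(r2_obs, 1.0),
        p_value=p,
        n_permutations=n_permutations,
        n_samples_used=n_used,
    )


def species_scores(
    table: FeatureTable, ord_: Ordination, feature_ids: list[str]
) -> pd.DataFrame:
    """Abundance-weighted average ordination coordinates per feature.

    Weights are the feature's per-sample relative abundances, normalized over
    samples, so a feature present in one sample sits on that sample and a
    uniformly abundant feature sits at the ordination centroid (origin).
    """
    missing = [f for f in feature_ids if f not in table.data.index]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    shared = [s for s in ord_.sample_ids if s in table.data.columns]
    if len(shared) != len(ord_.sample_ids):
        raise ValueError("ordination samples missing from table")
    rel = table.data[shared].to_numpy(dtype=float)
    col_sums = rel.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("all-zero sample in table")
    rel = rel / col_sums
    rows = {}
    for f in feature_ids:
        w = rel[table.data.index.get_loc(f)]
        total = w.sum()
        if total == 0:
            raise ValueError(f"all-zero feature {f!r}")
        rows[f] = (w / total) @ ord_.coords
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"axis{i+1}" for i in range(ord_.coords.shape[1])])


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Rescale every sample column to sum to 100 (percent relative abundance)."""
    sums = table.data.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    return FeatureTable(100.0 * table.data / sums, units_tag="proportions")
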