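"""End-to-end orchestration: simulate -> community -> functional -> PRMT.

One master seed drives everything; per-stage seeds are derived by hashing
(master seed, stage name), so each stage is reproducible in isolation and a
rerun with the same config yields byte-identical result files. Stage wall
times go to ``run.log`` (outside the determinism contract); ``manifest.json``
records the config echo, versions, derived seeds and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    bray_curtis,
    envfit,
    filter_min_count,
    nmds,
    rarefy,
    relative_abundance,
    species_scores,
)
from .func_profile import (
    assign_best_hits,
    build_network,
    compare_groups_welch,
    comparison_frame,
    filter_hits,
    hydrocarbon_category_profile,
)
from .io import read_feature_table, read_hit_table, read_metadata, read_reaction_db
from .prmt import (
    annotate_metabolite_directions,
    build_etm,
    compare_prmt_groups,
    normalize_ec_abundance,
    prmt_scores,
)
from .synthetic import StudyConfig, write_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "StageError", "derive_stage_seed", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters plus the master seed.

    Defaults are the study's stated analysis settings: OTUs kept at >= 10
    total sequences, rarefaction at 122 804 reads, 2 ordination axes with
    999 envfit permutations, hit filtering at e-value <= 1e-5 / identity >=
    60% / length >= 15 with a 40-bit best-hit cutoff, Welch comparison at
    0.95 confidence with a 1.00 percentage-point effect filter, network
    edges at >= 20 observations, and 1000 PRMT permutations.
    """

    out_dir: str = "run"
    master_seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    min_count: int = 10
    depth: int = 122_804
    k: int = 2
    n_restarts: int = 20
    env_permutations: int = 999
    env_variables: tuple[str, ...] = ("tph", "din", "nh3_n", "no3_n")
    bitscore_min: float = 40.0
    evalue_max: float = 1e-5
    identity_min: float = 60.0
    length_min: int = 15
    confidence: float = 0.95
    effect_threshold: float = 1.00
    network_min: float = 20.0
    prmt_permutations: int = 1000

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.min_count < 0 or self.k < 1:
            raise ValueError("invalid community stage parameters")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if min(self.env_permutations, self.prmt_permutations) < 1:
            raise ValueError("permutation counts must be >= 1")


@dataclass
class RunManifest:
    config: dict
    versions: dict
    stage_seeds: dict
    input_checksums: dict
    output_checksums: dict
    stage_records: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> RunManifest:
    """Run every stage in dependency order under ``config.out_dir``.

    On a stage failure the completed stages' outputs remain and an
    ``error_manifest.json`` naming the failed stage is written before the
    :class:`StageError` propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_dir = out / "results"
    results_dir.mkdir(exist_ok=True)
    seeds = {
        stage: derive_stage_seed(config.master_seed, stage)
        for stage in ("simulate", "community", "func", "prmt")
    }
    records: dict[str, dict] = {}
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        study = dataclasses.replace(config.study, seed=seeds["simulate"])
        inputs = write_study(study, out / "inputs")
        timings[stage] = time.perf_counter() - t0

        # ---------------- community ----------------
        stage = "community"
        t0 = time.perf_counter()
        table = read_feature_table(inputs["otu_table"], units_tag="counts")
        metadata = read_metadata(inputs["metadata"])
        meta_df = pd.DataFrame([dataclasses.asdict(m) for m in metadata]).set_index("sample_id")
        filtered = filter_min_count(table, config.min_count)
        rarefied = rarefy(filtered, config.depth, seed=seeds["community"])
        if rarefied.shape[1] < 3:
            raise StageError(stage, f"only {rarefied.shape[1]} samples at depth {config.depth} ({inputs['otu_table']})")
        dm = bray_curtis(rarefied)
        ordination = nmds(dm, k=config.k, n_restarts=config.n_restarts, seed=seeds["community"] + 1)
        coords = pd.DataFrame(
            ordination.coords,
            index=ordination.sample_ids,
            columns=[f"axis{i + 1}" for i in range(config.k)],
        )
        coords.to_csv(results_dir / "ordination.tsv", sep="\t", index_label="sample_id")
        env_rows = []
        for v, variable in enumerate(config.env_variables):
            fit = envfit(
                ordination,
                meta_df[variable],
                n_permutations=config.env_permutations,
                seed=seeds["community"] + 2 + v,
                variable=variable,
            )
            env_rows.append(
                {"variable": variable, "r_squared": fit.r_squared, "p_value": fit.p_value,
                 "n_samples_used": fit.n_samples_used}
            )
        pd.DataFrame(env_rows).to_csv(results_dir / "envfit.tsv", sep="\t", index=False)
        truth = json.loads((out / "inputs" / "ground_truth.json").read_text())
        responder_ids = [r for r in truth["responder_otu_ids"] if r in rarefied.data.index]
        if responder_ids:
            species_scores(rarefied, ordination, responder_ids).to_csv(
                results_dir / "species_scores.tsv", sep="\t", index_label="feature_id"
            )
        (results_dir / "community_log.json").write_text(
            json.dumps(
                {
                    "stress": ordination.stress,
                    "converged": ordination.converged,
                    "n_features_kept": filtered.shape[0],
                    "n_samples_rarefied": rarefied.shape[1],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        records[stage] = {
            "features_filtered": table.shape[0] - filtered.shape[0],
            "samples_dropped": filtered.shape[1] - rarefied.shape[1],
        }
        timings[stage] = time.perf_counter() - t0

        # ---------------- functional comparison ----------------
        stage = "func"
        t0 = time.perf_counter()
        hits_dir = inputs["hits_dir"]
        hits_by_sample = {
            p.stem: filter_hits(
                read_hit_table(p),
                evalue_max=config.evalue_max,
                identity_min=config.identity_min,
                length_min=config.length_min,
            )
            for p in sorted(hits_dir.glob("*.tsv"))
        }
        family_counts = assign_best_hits(hits_by_sample, bitscore_min=config.bitscore_min)
        exceed = [m.sample_id for m in metadata if m.exceeds_epa_bm and m.sample_id in family_counts.data.columns]
        nonexceed = [m.sample_id for m in metadata if not m.exceeds_epa_bm and m.sample_id in family_counts.data.columns]
        proportions = relative_abundance(family_counts)
        comparison = compare_groups_welch(
            proportions, exceed, nonexceed,
            confidence=config.confidence, effect_threshold=config.effect_threshold,
        )
        comparison_frame(comparison).to_csv(results_dir / "welch_comparison.tsv", sep="\t")
        network = build_network(family_counts, min_count=config.network_min)
        network.to_frame().to_csv(results_dir / "network_edges.tsv", sep="\t", index=False)
        category_map = dict(
            pd.read_csv(inputs["category_map"], sep="\t", dtype=str).itertuples(index=False, name=None)
        )
        hydro = hydrocarbon_category_profile(family_counts, category_map)
        hydro.data.to_csv(results_dir / "hydrocarbon_profile.tsv", sep="\t", index_label="category")
        records[stage] = {
            "n_families": family_counts.shape[0],
            "n_network_edges": len(network.edges),
            "n_significant": sum(1 for r in comparison if r.p_value <= 0.05 and r.passed_effect_filter),
        }
        timings[stage] = time.perf_counter() - t0

        # ---------------- PRMT ----------------
        stage = "prmt"
        t0 = time.perf_counter()
        ec_table = read_feature_table(inputs["ec_table"], units_tag="counts")
        reactions = read_reaction_db(inputs["reactions"])
        etm = build_etm(reactions)
        normalized = normalize_ec_abundance(ec_table)
        scores = prmt_scores(normalized, etm)
        etm.W.to_csv(results_dir / "etm.tsv", sep="\t", index_label="metabolite_id")
        scores.S.to_csv(results_dir / "prmt_scores.tsv", sep="\t", index_label="metabolite_id")
        prmt_exceed = [s for s in scores.sample_ids if s in exceed]
        prmt_non = [s for s in scores.sample_ids if s in nonexceed]
        comparisons = compare_prmt_groups(
            scores, prmt_exceed, prmt_non,
            n_permutations=config.prmt_permutations, seed=seeds["prmt"],
        )
        annotate_metabolite_directions(comparisons).to_csv(results_dir / "prmt_directions.tsv", sep="\t")
        records[stage] = {"n_metabolites": len(scores.metabolite_ids)}
        timings[stage] = time.perf_counter() - t0
    except StageError:
        _write_error_manifest(out, stage, records)
        raise
    except Exception as exc:
        _write_error_manifest(out, stage, records)
        raise StageError(stage, str(exc)) from exc

    manifest = RunManifest(
        config={**dataclasses.asdict(config), "study": dataclasses.asdict(config.study)},
        versions={
            "sedimeta": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        stage_seeds=seeds,
        input_checksums={p.name: _sha256(p) for p in sorted((out / "inputs").glob("*.*"))},
        output_checksums={p.name: _sha256(p) for p in sorted(results_dir.glob("*.*"))},
        stage_records=records,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    with open(out / "run.log", "w") as fh:
        for s, dt in timings.items():
            fh.write(f"{s}\t{dt:.3f}s\n")
    return manifest


def _write_error_manifest(out: Path, stage: str, records: dict) -> None:
    (out / "error_manifest.json").write_text(
        json.dumps({"failed_stage": stage, "completed": sorted(records)}, indent=2) + "\n"
    )
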