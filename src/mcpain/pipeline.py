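"""End-to-end orchestration: simulate/load -> features -> MC -> select -> report.

Every run writes plain CSV/JSON artifacts plus a run manifest (config
snapshot, package version, seed, timestamps, SHA-256 checksums of outputs).
The global seed is expanded into named per-stage substreams so stages can be
re-run in isolation and re-runs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .evaluation import compute_pain_scores
from .mc import cohort_mc_features
from .model import MCPredictionModel
from .parcellation import default_parcellation, load_parcellation, toy_parcellation
from .samples import ROISampleSet
from .simulate import CohortSpec, generate_cohort, planted_matching

logger = logging.getLogger("mcpain")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.parcellation_path is not None:
        parc = load_parcellation(cfg.parcellation_path)
    elif cfg.simulation is not None:
        parc = toy_parcellation(cfg.simulation.n_rois)
    else:
        parc = default_parcellation()

    if cfg.simulation is not None:
        sim = cfg.simulation
        spec = CohortSpec(
            n_participants=sim.n_participants,
            n_rois=sim.n_rois,
            n_voxels=sim.n_voxels,
            subject_sd=sim.subject_sd,
            planted_edges=(
                planted_matching(sim.n_rois, sim.n_planted_edges)
                if sim.n_planted_edges
                else None
            ),
            noise_sd=sim.noise_sd,
            target_r2=sim.target_r2,
            laser_range=sim.laser_range,
            cold_mean_sd=sim.cold_mean_sd,
            seed=stage_seed(cfg.seed, "simulate"),
        )
        samples, phenotypes, truth = generate_cohort(spec, parc)
        logger.info(
            "simulated cohort: N=%d, %d ROIs, %d planted edges",
            sim.n_participants,
            sim.n_rois,
            len(truth.planted_edges),
        )
        return samples, phenotypes, truth, parc

    if cfg.samples_path.endswith((".h5", ".hdf5")):
        samples = ROISampleSet.from_hdf5(cfg.samples_path)
    else:
        samples = ROISampleSet.from_tsv(cfg.samples_path)
    phenotypes = pd.read_csv(cfg.phenotypes_path)
    return samples, phenotypes, None, parc


def run_pipeline(cfg: RunConfig, sweep: bool = False) -> dict:
    """Execute one run (or the 3x3 feature-set x threshold sweep).

    Returns the manifest dict; artifacts land in ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    samples, phenotypes, truth, parc = _load_inputs(cfg)

    scored = compute_pain_scores(phenotypes)
    scored.to_csv(out / "phenotypes_scored.csv", index=False)
    if truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(truth.to_json_dict(), indent=2)
        )

    logger.info("computing MC features (%d ROIs -> %d edges)",
                parc.n_rois, parc.n_rois * (parc.n_rois - 1) // 2)
    mc_table = cohort_mc_features(samples, parc)
    mc_table.to_csv(out / "mc_features.csv")

    combos = (
        [(fs, th) for fs in ("gmv", "mc", "gmv_mc") for th in ("laser", "cold", "score")]
        if sweep
        else [(cfg.feature_set, cfg.threshold)]
    )
    reports = {}
    for fs, th in combos:
        logger.info("run: feature_set=%s threshold=%s mode=%s", fs, th, cfg.mode)
        model = MCPredictionModel.from_cohort(
            samples,
            scored,
            parc,
            feature_set=fs,
            threshold=th,
            mc_table=mc_table,
            mode=cfg.mode,
            schedule=cfg.schedule,
            error_metric=cfg.error_metric,
            inner_cv=cfg.inner_cv,
            pls_options={
                "max_components": cfg.max_components,
                "standardize": cfg.standardize,
            },
            seed=stage_seed(cfg.seed, f"select:{fs}:{th}"),
        )
        res = model.fit()
        tag = f"{fs}_{th}"
        res.report.to_frame().to_csv(out / f"predictions_{tag}.csv", index=False)
        (out / f"report_{tag}.json").write_text(json.dumps(res.to_dict(), indent=2))
        logger.info(
            "  -> MAE=%.4f MRAE=%s r=%.4f",
            res.mae,
            "n/a" if res.mrae is None else f"{res.mrae:.4f}",
            res.pearson_r,
        )
        reports[tag] = res.to_dict()

    manifest = {
        "package_version": __version__,
        "config": json.loads(cfg.model_dump_json()),
        "seed": cfg.seed,
        "standardize": cfg.standardize,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "reports": {k: {kk: v[kk] for kk in ("mae", "mrae", "pearson_r", "n")}
                    for k, v in reports.items()},
        "checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()
            and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
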