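"""End-to-end workflow runner with a flat config and stage caching.

A config (YAML or dict) names the input paths, the stages to run and their
parameters under one flat, documented key space.  Stages run in dependency
order (fixture -> simulate -> train -> deconvolve -> evaluate); each stage
writes its outputs plus a manifest recording the parameter/input checksum,
and a rerun with unchanged inputs skips the stage.  Every stage logs its
parameters and the global seed.

Config keys (all optional unless a stage needs them)::

    seed: 0                       # global random seed
    stages: [fixture, simulate, train, deconvolve, evaluate]
    sc_matrix / labels / st_matrix: input paths (omit when using `fixture`
        and `simulate` stages, which write them into the output directory)
    fixture.n_types, fixture.genes_per_type, fixture.cells_per_type,
        fixture.depth: block-fixture dimensions
    simulate.kind: random | tme ; simulate.n_spots
    train.k_list: candidate topic numbers (defaults from the label count)
    train.feature_mode: all | markers | hvg | markers_plus_hvg
    train.n_top: markers per cell type
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .preprocessing import build_feature_set
from .topic_model import default_candidate_ks, save_model, select_topic_number
from .deconvolution import assign_dominant_celltype, deconvolve_matrix
from .evaluation import presence_split_rmse, spot_correlation, summary_table
from .simulation import make_block_fixture, simulate_random_spots, simulate_tme

log = logging.getLogger("topicspot")

STAGE_ORDER = ["fixture", "simulate", "train", "deconvolve", "evaluate"]


def _checksum(obj, paths: list[Path]) -> str:
    h = hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode())
    for p in paths:
        if p.exists():
            h.update(p.read_bytes())
    return h.hexdigest()


def _stage_done(outdir: Path, stage: str, checksum: str) -> bool:
    manifest = outdir / f"{stage}.done.json"
    if manifest.exists():
        return json.loads(manifest.read_text()).get("checksum") == checksum
    return False


def _mark_done(outdir: Path, stage: str, checksum: str) -> None:
    (outdir / f"{stage}.done.json").write_text(
        json.dumps({"stage": stage, "checksum": checksum}, indent=1)
    )


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def run_pipeline(config: str | Path | dict, outdir: str | Path,
                 overrides: dict | None = None) -> Path:
    """Run the configured stages into ``outdir``; returns the directory."""
    cfg = load_config(config)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGE_ORDER if s in stages]

    paths = {
        "sc_matrix": Path(cfg["sc_matrix"]) if "sc_matrix" in cfg else outdir / "sc_matrix.tsv",
        "labels": Path(cfg["labels"]) if "labels" in cfg else outdir / "labels.tsv",
        "st_matrix": Path(cfg["st_matrix"]) if "st_matrix" in cfg else outdir / "st_matrix.tsv",
        "truth": Path(cfg["truth"]) if "truth" in cfg else outdir / "truth.tsv",
    }
    model_dir = outdir / "model"

    for stage in stages:
        params = {k: v for k, v in cfg.items()
                  if k == "seed" or k.startswith(f"{stage}.")}
        inputs: list[Path] = []
        if stage == "train":
            inputs = [paths["sc_matrix"], paths["labels"], paths["st_matrix"]]
        elif stage == "deconvolve":
            inputs = [paths["st_matrix"], model_dir / "params.json"]
        elif stage == "evaluate":
            inputs = [paths["truth"], outdir / "spot_composition.tsv"]
        checksum = _checksum(params, inputs)
        if _stage_done(outdir, stage, checksum):
            log.info("stage %s: outputs up to date, skipped", stage)
            continue
        log.info("stage %s: running (seed=%d, params=%s)", stage, seed, params)
        try:
            _run_stage(stage, cfg, paths, outdir, model_dir, seed)
        except Exception as exc:
            record = {"stage": stage, "error": str(exc)}
            (outdir / "pipeline_error.json").write_text(json.dumps(record, indent=1))
            raise
        _mark_done(outdir, stage, checksum)
    return outdir


def _run_stage(stage: str, cfg: dict, paths: dict, outdir: Path,
               model_dir: Path, seed: int) -> None:
    if stage == "fixture":
        sc, labels = make_block_fixture(
            n_types=int(cfg.get("fixture.n_types", 5)),
            genes_per_type=int(cfg.get("fixture.genes_per_type", 20)),
            cells_per_type=int(cfg.get("fixture.cells_per_type", 100)),
            depth=int(cfg.get("fixture.depth", 2000)),
            seed=seed,
        )
        tio.write_matrix(sc, paths["sc_matrix"])
        tio.write_labels(labels, paths["labels"])
        return

    if stage == "simulate":
        sc = tio.read_matrix(paths["sc_matrix"])
        labels = tio.read_labels(paths["labels"], sc)
        kind = cfg.get("simulate.kind", "random")
        if kind == "random":
            ds = simulate_random_spots(
                sc, labels, n_spots=int(cfg.get("simulate.n_spots", 200)),
                seed=seed,
            )
        elif kind == "tme":
            ds = simulate_tme(sc, labels, seed=seed)
        else:
            raise ValueError(f"unknown simulate.kind {kind!r}")
        tio.write_matrix(ds.st_matrix, paths["st_matrix"])
        tio.write_table(ds.truth_frame(), paths["truth"])
        if ds.spot_region is not None:
            tio.write_table(
                pd.DataFrame({"region": ds.spot_region},
                             index=ds.st_matrix.column_ids),
                outdir / "spot_region.tsv",
            )
        tio.write_table(
            pd.DataFrame({"cells": [",".join(p) for p in ds.provenance]},
                         index=ds.st_matrix.column_ids),
            outdir / "provenance.tsv",
        )
        return

    if stage == "train":
        sc = tio.read_matrix(paths["sc_matrix"])
        labels = tio.read_labels(paths["labels"], sc)
        st = tio.read_matrix(paths["st_matrix"])
        fs = build_feature_set(
            sc, st, labels, mode=cfg.get("train.feature_mode", "markers"),
            n_top_markers=int(cfg.get("train.n_top", 100)),
        )
        from .preprocessing import normalize_matrix

        norm = normalize_matrix(sc.subset_genes(fs.genes))
        k_list = cfg.get("train.k_list") or default_candidate_ks(len(labels.cell_types))
        k_list = [int(k) for k in k_list]
        model, tables, acc = select_topic_number(norm, labels, k_list, seed=seed)
        save_model(model, tables, model_dir)
        tio.write_table(acc, outdir / "topic_number_accuracy.tsv")
        return

    if stage == "deconvolve":
        from .topic_model import load_model

        model, tables = load_model(model_dir)
        if tables is None:
            raise ValueError("model directory lacks cell-type tables")
        st = tio.read_matrix(paths["st_matrix"])
        y, comp = deconvolve_matrix(model, tables, st)
        tio.write_table(y.to_frame(), outdir / "spot_topics.tsv")
        tio.write_table(comp.to_frame(), outdir / "spot_composition.tsv")
        tio.write_table(assign_dominant_celltype(comp).to_frame(),
                        outdir / "dominant_celltype.tsv")
        return

    if stage == "evaluate":
        from .deconvolution import SpotComposition

        comp_df = tio.read_table(outdir / "spot_composition.tsv")
        comp = SpotComposition(
            comp_df.to_numpy(), [str(t) for t in comp_df.index],
            [str(s) for s in comp_df.columns],
        )
        truth = tio.read_table(paths["truth"])
        r = spot_correlation(comp, truth)
        rmse = presence_split_rmse(comp, truth)
        tio.write_table(r.to_frame(), outdir / "per_spot_correlation.tsv")
        tio.write_table(rmse, outdir / "per_spot_rmse.tsv")
        tio.write_table(summary_table(r, rmse), outdir / "summary.tsv")
        return

    raise ValueError(f"unknown stage {stage!r}")
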