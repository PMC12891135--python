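"""End-to-end orchestration: simulate -> extract -> assemble -> train ->
evaluate -> diff from one declarative YAML config, with structured logging
and byte-reproducible outputs under a fixed seed.

Config layout (all sections optional except seed; defaults shown where used)::

    seed: 7
    outdir: runs/demo
    simulate:            # either this ...
      n_benign: 12
      n_malignant: 12
      fragments_per_sample: 8000
      n_chroms: 2
      chrom_length: 400000
      gc_fraction: 0.41
      null_effects: false     # true -> identical class profiles
      stage_effect_scale: {III: 2.0, IV: 2.0}
    inputs:              # ... or pre-existing files
      genome: genome.fa
      fragments_dir: fragments/     # <sample_id>.tsv fragment tables
      metadata: metadata.tsv
      annotation: repeats.bed
      blacklist: blacklist.bed
      sites: sites.bed
    extract:
      end_motif_k: [4]
      include_breakpoint: false
      bin_size: 100000
    model:
      folds: 10
      repeats: 200
      train_fraction: 0.7
    diff:
      top: 30
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classifier import evaluate, predict_scores, train_glm_cv
from .differential import top_k, wilcoxon_differential
from .features import assemble_features, extract_cohort_features
from .simulate import (
    ClassProfile,
    CohortSpec,
    default_benign_profile,
    simulate_cohort,
)
from .sizes import build_bins

logger = logging.getLogger("plasmafrag.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    if "seed" not in cfg:
        raise ValueError("config requires a master 'seed' (stochastic stages)")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' or an 'inputs' section")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("genome", "fragments_dir", "metadata"):
            if key not in inputs:
                raise ValueError(f"inputs section missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ValueError(f"inputs.{key}: path {inputs[key]!r} does not exist")
        for key in ("annotation", "blacklist", "sites"):
            if key in inputs and not Path(inputs[key]).exists():
                raise ValueError(f"inputs.{key}: path {inputs[key]!r} does not exist")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config, outdir=None) -> Path:
    """Run every stage; returns the run directory.

    ``config`` is a path to a YAML file or an already-loaded dict.  On stage
    failure, partial outputs are moved under ``<outdir>/failed/`` and a
    :class:`PipelineError` naming the stage is raised.  Outputs are
    byte-identical across reruns with the same config and seed.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    validate_config(cfg)
    outdir = Path(outdir or cfg.get("outdir", "plasmafrag_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("plasmafrag")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seed = int(cfg["seed"])
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "simulate/load"
        extract_cfg = cfg.get("extract", {})
        if "simulate" in cfg:
            sim = cfg["simulate"]
            logger.info("simulate: %s", json.dumps(sim, sort_keys=True))
            benign = default_benign_profile()
            spec = CohortSpec(
                n_benign=int(sim.get("n_benign", 12)),
                n_malignant=int(sim.get("n_malignant", 12)),
                fragments_per_sample=int(sim.get("fragments_per_sample", 8000)),
                benign_profile=benign,
                malignant_profile=benign if sim.get("null_effects") else None,
                seed=seed,
                n_chroms=int(sim.get("n_chroms", 2)),
                chrom_length=int(sim.get("chrom_length", 400_000)),
                gc_fraction=float(sim.get("gc_fraction", 0.41)),
                stage_effect_scale=sim.get("stage_effect_scale"),
            )
            cohort = simulate_cohort(spec)
            genome = cohort.genome
            annotation = cohort.annotation
            sites = cohort.dip_sites
            fragment_sets = cohort.fragment_sets
            metadata = cohort.metadata
            blacklist = None
            pio.write_genome(genome, outdir / "genome.fa")
            pio.write_intervals(annotation, outdir / "repeats.bed")
            pio.write_intervals(sites, outdir / "sites.bed")
            pio.write_metadata(metadata, outdir / "metadata.tsv")
            frag_dir = outdir / "fragments"
            frag_dir.mkdir(exist_ok=True)
            for fs in fragment_sets:
                pio.write_fragments(fs, frag_dir / f"{fs.sample_id}.tsv")
        else:
            inputs = cfg["inputs"]
            for key, path in sorted(inputs.items()):
                logger.info("input %s: %s sha256=%s", key, path, _hash_file(path))
            genome = pio.read_genome(inputs["genome"])
            metadata = pio.read_metadata(inputs["metadata"])
            annotation = (
                pio.read_intervals(inputs["annotation"]) if "annotation" in inputs else None
            )
            sites = pio.read_intervals(inputs["sites"]) if "sites" in inputs else None
            blacklist = (
                pio.read_intervals(inputs["blacklist"]) if "blacklist" in inputs else None
            )
            frag_dir = Path(inputs["fragments_dir"])
            fragment_sets = [
                pio.read_fragments(p, sample_id=p.stem)
                for p in sorted(frag_dir.glob("*.tsv"))
            ]
            if not fragment_sets:
                raise ValueError(f"no fragment tables under {frag_dir}")

        # ------------------------------------------------------------------
        stage = "extract"
        bins = build_bins(
            genome, int(extract_cfg.get("bin_size", 100_000)), blacklist=blacklist
        )
        feats = extract_cohort_features(
            fragment_sets,
            genome,
            bins=bins,
            annotation=annotation,
            sites=sites,
            end_motif_k=tuple(extract_cfg.get("end_motif_k", [4])),
            include_breakpoint=bool(extract_cfg.get("include_breakpoint", False)),
        )

        # ------------------------------------------------------------------
        stage = "assemble"
        external = None
        if "inputs" in cfg and "external_features" in cfg["inputs"]:
            external = pd.read_csv(
                cfg["inputs"]["external_features"], sep="\t", index_col="sample_id"
            )
        matrix = assemble_features(feats, metadata, external=external)
        pio.write_feature_matrix(matrix, outdir / "features.tsv")

        # ------------------------------------------------------------------
        stage = "train"
        model_cfg = cfg.get("model", {})
        train_fraction = float(model_cfg.get("train_fraction", 0.7))
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x59117]))
        ids = np.asarray(matrix.sample_ids, dtype=object)
        y = matrix.labels.to_numpy()
        train_ids: list = []
        for cls in (0, 1):
            cls_ids = sorted(ids[y == cls])
            n_train = max(int(round(train_fraction * len(cls_ids))), 1)
            perm = rng.permutation(len(cls_ids))
            train_ids.extend(cls_ids[i] for i in perm[:n_train])
        val_ids = sorted(set(ids) - set(train_ids))
        train_ids = sorted(train_ids)
        logger.info("train/validation split: %d / %d", len(train_ids), len(val_ids))
        train_matrix = matrix.subset(train_ids)
        result = train_glm_cv(
            train_matrix,
            folds=int(model_cfg.get("folds", 10)),
            repeats=int(model_cfg.get("repeats", 200)),
            seed=seed,
        )
        result.to_json(outdir / "model.json")

        # ------------------------------------------------------------------
        stage = "evaluate"
        report_train = evaluate(
            result.oof_scores.to_numpy(),
            train_matrix.labels.loc[result.oof_scores.index].to_numpy(),
            metadata=train_matrix.metadata.loc[result.oof_scores.index],
        )
        # threshold locked on training oof scores, applied to validation
        locked_threshold = report_train["threshold"]
        _write_json(report_train, outdir / "report_train.json")
        if val_ids:
            val_matrix = matrix.subset(val_ids)
            val_scores = predict_scores(result, val_matrix)
            report_val = evaluate(
                val_scores.to_numpy(),
                val_matrix.labels.to_numpy(),
                metadata=val_matrix.metadata,
                threshold=locked_threshold,
            )
            _write_json(report_val, outdir / "report_validation.json")

        # ------------------------------------------------------------------
        stage = "diff"
        diff_cfg = cfg.get("diff", {})
        table = wilcoxon_differential(matrix)
        table.to_csv(outdir / "differential.tsv", sep="\t", float_format=pio.FLOAT_FORMAT)
        k = min(int(diff_cfg.get("top", 30)), len(table))
        features, z = top_k(table, matrix, k=k)
        z.to_csv(outdir / "top_features_matrix.tsv", sep="\t", float_format=pio.FLOAT_FORMAT)
        logger.info("pipeline complete: %s", outdir)
        return outdir
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for p in sorted(outdir.iterdir()):
            if p.name not in {"failed", "run.log"}:
                shutil.move(str(p), str(failed / p.name))
        logger.error("stage %r failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
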