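"""Umbrella pipeline: configuration, stage ordering and output manifest.

A pipeline config (YAML or JSON, or a plain dict) selects which stages run:

``counts``
    either ``simulate: {CountSimConfig fields}`` or ``path``/``samples``
    pointing at a count TSV and sample sheet; scored with the ``scoring``
    sub-config (the ``species`` preset sets the default ratio threshold,
    explicit values win).
``images``
    either ``simulate: {ImageSimConfig fields}`` or ``path`` to a TIFF;
    segmented per ``segmentation`` and colocalized per ``colocalization``
    over the ROIs in ``rois`` (default: the full field as one ROI).
``group_comparison``
    ``metrics`` TSV plus a ``metric`` name.

Every output file is recorded in a JSON manifest with its SHA-256 hash, a
config echo and the seed, so a rerun with identical config and seed is
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import yaml

from . import io as sio
from .colocalization import ColocConfig, coloc_with_flip, paired_comparison
from .groupstats import compare_groups
from .scoring import (SPECIES_RATIO_THRESHOLDS, ScoringConfig, score_table,
                      select_candidates)
from .segmentation import SegmentationConfig, segment_puncta
from .simulate_counts import CountSimConfig, simulate_count_table
from .simulate_images import ImageSimConfig, simulate_puncta_image
from .stacks import full_image_roi

log = logging.getLogger("synprox")


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scoring_config(cfg: dict) -> ScoringConfig:
    params = dict(cfg.get("scoring", {}))
    species = cfg.get("species")
    if species is not None:
        if species not in SPECIES_RATIO_THRESHOLDS:
            raise ValueError(
                f"unknown species preset {species!r}; expected one of "
                f"{sorted(SPECIES_RATIO_THRESHOLDS)}"
            )
        params.setdefault("ratio_threshold", SPECIES_RATIO_THRESHOLDS[species])
    sc = ScoringConfig(**params)
    sc.validate()
    return sc


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    scoring_cfg = _scoring_config(config)  # validate presets before any stage
    manifest: dict = {
        "config": config,
        "seed": seed,
        "outputs": {},
        "stages": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    def stage(name):
        t0 = time.time()
        manifest["stages"].append({"name": name, "started": t0})
        log.info("stage %s", name)
        return t0

    if "counts" in config:
        t0 = stage("counts")
        section = config["counts"]
        if "simulate" in section:
            sim = CountSimConfig(**{**section["simulate"], "seed": seed})
            table, truth = simulate_count_table(sim)
            sio.write_count_table(table, out / "counts.tsv", out / "samples.tsv")
            truth.to_frame().to_csv(out / "truth.tsv", sep="\t")
            record("counts", out / "counts.tsv")
            record("samples", out / "samples.tsv")
            record("truth", out / "truth.tsv")
        else:
            table = sio.read_count_table(section["path"], section.get("samples"))
        records = score_table(table, scoring_cfg)
        sio.write_enrichment_table(records, out / "enrichment.tsv")
        record("enrichment", out / "enrichment.tsv")
        cands = select_candidates(records, scoring_cfg)
        sio.write_enrichment_table(cands, out / "candidates.tsv")
        record("candidates", out / "candidates.tsv")
        manifest["stages"][-1]["seconds"] = time.time() - t0

    if "images" in config:
        t0 = stage("images")
        section = config["images"]
        if "simulate" in section:
            sim = ImageSimConfig(**{**section["simulate"], "seed": seed})
            stack, truth = simulate_puncta_image(sim)
            sio.write_image_stack(stack, out / "stack.tif", truth)
            record("stack", out / "stack.tif")
            record("stack_sidecar", out / "stack.json")
        else:
            stack, _ = sio.read_image_stack(section["path"])

        seg_cfg = SegmentationConfig(**config.get("segmentation", {}))
        seg_cfg.validate()
        ref = segment_puncta(stack, 0, seg_cfg)
        cand = segment_puncta(stack, 1, seg_cfg)
        for ch, ps in (("reference", ref), ("candidate", cand)):
            ps.objects.to_csv(out / f"puncta_{ch}.tsv", sep="\t", index=False)
            record(f"puncta_{ch}", out / f"puncta_{ch}.tsv")

        coloc_params = dict(config.get("colocalization", {}))
        coloc_params.setdefault("size_criterion_px2",
                                seg_cfg.size_exclusion_px2_for_coloc)
        coloc_cfg = ColocConfig(**coloc_params)
        coloc_cfg.validate()
        if config.get("rois"):
            rois = sio.read_roi_file(config["rois"])
        else:
            rois = [full_image_roi(stack.shape_yx, stack.pixel_size_um)]
        results = [coloc_with_flip(ref, cand, roi, coloc_cfg) for roi in rois]
        import pandas as pd
        pd.DataFrame(results).to_csv(out / "colocalization.tsv", sep="\t", index=False)
        record("colocalization", out / "colocalization.tsv")
        usable = [(r["pct_original"], r["pct_flipped"])
                  for r in results if not r["undefined"]]
        summary: dict = {"n_rois": len(results), "n_usable": len(usable)}
        if len(usable) >= 3:
            test = paired_comparison(usable, coloc_cfg.alpha)
            summary["paired_test"] = asdict(test)
        (out / "coloc_summary.json").write_text(json.dumps(summary, indent=2))
        record("coloc_summary", out / "coloc_summary.json")
        manifest["stages"][-1]["seconds"] = time.time() - t0

    if "group_comparison" in config:
        t0 = stage("group_comparison")
        section = config["group_comparison"]
        metrics = sio.read_metrics_table(section["metrics"])
        res = compare_groups(metrics, section["metric"])
        (out / "group_test.json").write_text(json.dumps(res.to_dict(), indent=2))
        record("group_test", out / "group_test.json")
        manifest["stages"][-1]["seconds"] = time.time() - t0

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
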