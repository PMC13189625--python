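"""Readers and writers for the pipeline's plain-text and TIFF formats.

Count tables travel as wide TSV (``protein_id`` + one column per sample)
with a sample sheet mapping columns to condition/replicate; image stacks as
multi-page TIFF in (C, Z, Y, X) order with a JSON sidecar carrying the
physical calibration (and, for simulated fixtures, the ground truth).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .counts import BAIT, CONTROL, SpectralCountTable
from .scoring import OrthologyMap
from .simulate_images import PunctaTruth
from .stacks import ImageStack, ROIBox


class ParseError(ValueError):
    """Schema violation in an input file."""


# ---------------------------------------------------------------- counts

def write_count_table(table: SpectralCountTable, counts_path: str | Path,
                      samples_path: str | Path | None = None) -> None:
    df = table.counts.copy()
    df.index.name = "protein_id"
    df.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        rep: dict[str, int] = {}
        rows = []
        for col in table.counts.columns:
            cond = table.conditions[col]
            rep[cond] = rep.get(cond, 0) + 1
            rows.append({"sample": col, "condition": cond, "replicate": rep[cond]})
        pd.DataFrame(rows).to_csv(samples_path, sep="\t", index=False)


def read_count_table(counts_path: str | Path,
                     samples_path: str | Path | None = None) -> SpectralCountTable:
    """Read a wide count TSV, with conditions from a sample sheet.

    Without a sample sheet, columns prefixed ``bait``/``ctrl``/``control``
    are assigned accordingly; anything else is a parse error.
    """
    sep = "," if str(counts_path).endswith(".csv") else "\t"
    df = pd.read_csv(counts_path, sep=sep)
    if "protein_id" not in df.columns:
        raise ParseError(f"{counts_path}: first column must be 'protein_id'")
    dup = df["protein_id"][df["protein_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{counts_path}: duplicate protein_id {dup.iloc[0]!r}")
    df = df.set_index("protein_id")

    if samples_path is not None:
        sheet = pd.read_csv(samples_path, sep="\t")
        need = {"sample", "condition"}
        if not need <= set(sheet.columns):
            raise ParseError(f"{samples_path}: needs columns {sorted(need)}")
        conditions = {}
        for _, row in sheet.iterrows():
            cond = str(row["condition"]).lower()
            if cond in ("bait", "experiment"):
                cond = BAIT
            elif cond in ("control", "ctrl", "wt"):
                cond = CONTROL
            else:
                raise ParseError(
                    f"{samples_path}: unknown condition {row['condition']!r} "
                    f"for sample {row['sample']!r}"
                )
            conditions[str(row["sample"])] = cond
        missing = set(df.columns) - set(conditions)
        if missing:
            raise ParseError(f"{samples_path}: no condition for columns {sorted(missing)}")
    else:
        conditions = {}
        for col in df.columns:
            low = col.lower()
            if low.startswith("bait"):
                conditions[col] = BAIT
            elif low.startswith(("ctrl", "control")):
                conditions[col] = CONTROL
            else:
                raise ParseError(
                    f"{counts_path}: cannot infer condition for column {col!r}; "
                    "provide a sample sheet"
                )
    for col in df.columns:
        vals = df[col]
        if not np.all(np.equal(np.mod(vals.to_numpy(float), 1), 0)):
            bad = vals[np.mod(vals.to_numpy(float), 1) != 0].index[0]
            raise ParseError(f"{counts_path}: non-integer count in column {col!r}, row {bad!r}")
    try:
        return SpectralCountTable(counts=df.astype(np.int64), conditions=conditions)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


# ---------------------------------------------------------------- images

def write_image_stack(stack: ImageStack, tiff_path: str | Path,
                      truth: PunctaTruth | None = None) -> None:
    """Write (C, Z, Y, X) TIFF plus a JSON calibration sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.data, metadata={"axes": "CZYX"})
    sidecar = {
        "axes": "CZYX",
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "channel_names": stack.channel_names,
    }
    if truth is not None:
        sidecar["truth"] = truth.to_dict()
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_image_stack(tiff_path: str | Path, axes: str | None = None,
                     pixel_size_um: float | None = None,
                     z_step_um: float | None = None,
                     ) -> tuple[ImageStack, PunctaTruth | None]:
    """Read a TIFF stack into canonical (C, Z, Y, X) order.

    Calibration comes from the JSON sidecar next to the file; explicit
    arguments override it. Without sidecar or arguments an error explains
    which flags to pass. ``axes`` may be ``"CZYX"`` or ``"ZCYX"``.
    """
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    sidecar_path = tiff_path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}

    axes = axes or sidecar.get("axes", "CZYX")
    if axes not in ("CZYX", "ZCYX"):
        raise ParseError(f"unsupported axes order {axes!r}")
    if data.ndim == 3:  # single channel on disk
        data = data[None]
    if data.ndim != 4:
        raise ParseError(f"{tiff_path}: expected a 3D or 4D stack, got shape {data.shape}")
    if axes == "ZCYX":
        data = np.transpose(data, (1, 0, 2, 3))

    px = pixel_size_um if pixel_size_um is not None else sidecar.get("pixel_size_um")
    zs = z_step_um if z_step_um is not None else sidecar.get("z_step_um")
    if px is None or zs is None:
        raise ParseError(
            f"{tiff_path}: no calibration sidecar found; pass pixel_size_um "
            "and z_step_um (CLI: --pixel-size-um / --z-step-um)"
        )
    stack = ImageStack(
        data=data, pixel_size_um=float(px), z_step_um=float(zs),
        channel_names=list(sidecar.get("channel_names", [])),
    )
    truth = PunctaTruth.from_dict(sidecar["truth"]) if "truth" in sidecar else None
    return stack, truth


# ---------------------------------------------------------------- tables

def read_roi_file(path: str | Path) -> list[ROIBox]:
    """ROI TSV: columns label, origin_row, origin_col, height_um, width_um."""
    df = pd.read_csv(path, sep="\t")
    need = {"label", "origin_row", "origin_col", "height_um", "width_um"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: ROI file needs columns {sorted(need)}")
    return [
        ROIBox(origin=(int(r.origin_row), int(r.origin_col)),
               height_um=float(r.height_um), width_um=float(r.width_um),
               label=str(r.label))
        for r in df.itertuples()
    ]


def write_roi_file(rois: list[ROIBox], path: str | Path) -> None:
    pd.DataFrame(
        [{"label": r.label, "origin_row": r.origin[0], "origin_col": r.origin[1],
          "height_um": r.height_um, "width_um": r.width_um} for r in rois]
    ).to_csv(path, sep="\t", index=False)


def read_orthology_map(path: str | Path) -> OrthologyMap:
    """Two-column TSV of orthologous protein id pairs."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: orthology map needs two columns")
    a, b = df.columns[:2]
    return OrthologyMap(pairs=list(zip(df[a].astype(str), df[b].astype(str))))


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"source", "target"} <= set(df.columns):
        raise ParseError(f"{path}: edge list needs 'source' and 'target' columns")
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_enrichment_table(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "genotype" not in df.columns:
        raise ParseError(f"{path}: metrics table needs a 'genotype' column")
    return df
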