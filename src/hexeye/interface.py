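"""Shared I/O contracts and the end-to-end pipeline.

Grid tables are CSV with one row per ommatidium (id, hex and image
coordinates, altitude, column index, provenance); label images assign every
in-mask pixel the id of its ommatidium with a 1-px boundary between
adjacent labels. ``run_pipeline`` chains focus stacking, classification,
grid expansion and analysis with per-stage logging and persisted
intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from hexeye.hexgrid import HexGrid, Ommatidium

__all__ = [
    "GRID_COLUMNS",
    "grid_to_table",
    "grid_from_table",
    "write_grid",
    "read_grid",
    "write_labels",
    "run_pipeline",
    "save_models",
    "load_models",
]

logger = logging.getLogger("hexeye")

GRID_COLUMNS = [
    "ommatidium_id",
    "x_hex",
    "y_hex",
    "x_px",
    "y_px",
    "z_um",
    "column_index",
    "origin",
]


def grid_to_table(grid: HexGrid, with_columns: bool = True) -> pd.DataFrame:
    """One row per ommatidium, ids contiguous from 1 in registration order."""
    rows = []
    for i, o in enumerate(grid, start=1):
        rows.append(
            {
                "ommatidium_id": i,
                "x_hex": o.hex[0],
                "y_hex": o.hex[1],
                "x_px": float(o.pos[0]),
                "y_px": float(o.pos[1]),
                "z_um": o.z if o.z is not None else np.nan,
                "column_index": (o.hex[0] + o.hex[1]) if with_columns else np.nan,
                "origin": o.origin,
            }
        )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def grid_from_table(table: pd.DataFrame) -> HexGrid:
    """Rebuild a HexGrid from a grid table; errors on duplicate hex coords."""
    dup = table.duplicated(subset=["x_hex", "y_hex"])
    if dup.any():
        rows = [int(i) + 2 for i in table.index[dup]]  # 1-based + header line
        raise ValueError(f"duplicate (x_hex, y_hex) at file rows {rows}")
    grid = HexGrid()
    for _, r in table.iterrows():
        z = None if pd.isna(r["z_um"]) else float(r["z_um"])
        grid.add(
            Ommatidium(
                (int(r["x_hex"]), int(r["y_hex"])),
                np.array([float(r["x_px"]), float(r["y_px"])]),
                z=z,
                origin=str(r["origin"]),
            )
        )
    return grid


def write_grid(path: str | Path, grid: HexGrid) -> None:
    """Write the grid CSV (UTF-8, '.' decimal, 17 significant digits)."""
    table = grid_to_table(grid)
    table.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_grid(path: str | Path) -> HexGrid:
    """Read a grid CSV written by :func:`write_grid`."""
    table = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in GRID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"grid CSV missing columns: {missing}")
    return grid_from_table(table)


def write_labels(
    grid: HexGrid, eye_mask: np.ndarray, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Label image: per-pixel ommatidium id within the eye mask.

    Each in-mask pixel takes the id of the ommatidium whose basin it falls
    into (watershed of the distance-to-centers map, flooded within the mask,
    so assignment respects mask connectivity); pixels where two labels meet
    are set to 0, leaving a 1-px boundary. Background is 0.
    """
    from scipy.spatial import cKDTree
    from skimage.segmentation import watershed

    if len(grid) == 0:
        raise ValueError("empty grid")
    eye_mask = np.asarray(eye_mask, dtype=bool)
    shape = shape or eye_mask.shape
    h, w = shape
    markers = np.zeros(shape, dtype=np.int32)
    ids, centers = [], []
    for i, o in enumerate(grid, start=1):
        xi, yi = int(round(o.pos[0])), int(round(o.pos[1]))
        xi, yi = np.clip(xi, 0, w - 1), np.clip(yi, 0, h - 1)
        markers[yi, xi] = i
        ids.append(i)
        centers.append([o.pos[0], o.pos[1]])
    ys, xs = np.mgrid[0:h, 0:w]
    tree = cKDTree(np.array(centers))
    d1, _ = tree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    labels = watershed(d1.reshape(shape), markers=markers, mask=eye_mask)
    # 1-px boundary where adjacent labels meet
    boundary = np.zeros(shape, dtype=bool)
    for ax, shiftpos in ((0, 1), (1, 1)):
        a = labels
        b = np.roll(labels, shiftpos, axis=ax)
        diff = (a != b) & (a > 0) & (b > 0)
        boundary |= diff
    out = labels.astype(np.uint16)
    out[boundary] = 0
    return out


def save_models(path: str | Path, eye_model, facet_model) -> None:
    """Persist the two pixel models with the feature recipe embedded."""
    import joblib

    joblib.dump(
        {
            "format_version": 1,
            "recipe": eye_model.recipe,
            "eye": eye_model.forest,
            "facet": facet_model.forest,
        },
        path,
    )


def load_models(path: str | Path):
    import joblib

    from hexeye.classify import PixelModel

    blob = joblib.load(path)
    if blob.get("format_version") != 1:
        raise ValueError("unsupported model file version")
    eye = PixelModel("eye", blob["eye"], recipe=blob["recipe"])
    facet = PixelModel("facet", blob["facet"], recipe=blob["recipe"])
    return eye, facet


@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run.

    Exactly one image source must be set: ``image`` / ``stack_path`` for
    real data, or ``synthetic`` (a SyntheticEyeSpec) for a generated eye
    with ideal probability maps.
    """

    out_dir: str = "."
    image: np.ndarray | None = None
    stack_path: str | None = None
    synthetic: object | None = None  # SyntheticEyeSpec
    model_path: str | None = None
    seeds: tuple | None = None  # ((x0,y0),(x1,y1),(x2,y2)) or None = auto
    px_size: float = 1.0
    anterior: str = "right"
    z_step: float = 8.0
    focus_window: int = 9
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run focus -> classify -> segment -> analyze and persist all outputs.

    Returns a machine-readable report (counts, L_grid, column count,
    per-stage notes). Any stage failure aborts with the stage name.
    """
    from hexeye import analysis, classify, hexgrid, imageprep, synthfly

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    stage = "setup"
    try:
        altitude = None
        if config.synthetic is not None:
            stage = "simulate"
            gt = synthfly.generate_lattice(config.synthetic)
            maps = synthfly.ideal_probability_maps(gt, config.synthetic)
            alt = np.zeros(gt.shape)
            # per-pixel altitude from the ground truth facet altitudes
            from scipy.spatial import cKDTree

            ys, xs = np.mgrid[0 : gt.shape[0], 0 : gt.shape[1]]
            _, idx = cKDTree(gt.centers).query(
                np.column_stack([xs.ravel(), ys.ravel()])
            )
            altitude = gt.z[idx].reshape(gt.shape)
            report["ground_truth_count"] = int(gt.n)
            report["stages"].append("simulate")
        else:
            stage = "focus"
            if config.stack_path is not None:
                stack = imageprep.load_stack(config.stack_path, z_step=config.z_step)
                focused = imageprep.focus_stack(stack, window=config.focus_window)
                image = focused.image
                altitude = imageprep.altitude_map(focused, z_step=config.z_step)
                report["stages"].append("focus")
            elif config.image is not None:
                image = np.asarray(config.image, dtype=float)
            else:
                raise ValueError("no input image, stack or synthetic spec")
            stage = "classify"
            if config.model_path is None:
                raise ValueError("model path required for classification")
            eye_model, facet_model = load_models(config.model_path)
            maps = classify.predict_maps(image, eye_model, facet_model)
            report["stages"].append("classify")
        stage = "segment"
        if config.seeds is not None:
            grid = hexgrid.seed_grid(*config.seeds)
        else:
            grid = hexgrid.auto_seed(maps)
        grid = hexgrid.expand_grid(grid, maps)
        report["stages"].append("segment")
        report["count"] = len(grid)
        report["L_grid"] = hexgrid.grid_edge_length(grid)
        stage = "analyze"
        if altitude is not None:
            analysis.assign_altitude(grid, altitude, config.px_size)
        else:
            for o in grid:
                o.z = 0.0
            grid.px_size = config.px_size
        reindexed = analysis.recenter_and_orient(grid, config.anterior)
        profile = analysis.column_profile(reindexed)
        spacing = analysis.spacing_per_ommatidium(reindexed)
        report["n_columns"] = profile.n_columns
        report["mean_spacing_um"] = float(np.mean(spacing.values))
        report["stages"].append("analyze")
        stage = "write"
        write_grid(out / "grid.csv", reindexed)
        labels = write_labels(grid, maps.eye_mask)
        import tifffile

        tifffile.imwrite(out / "labels.tif", labels)
        pd.DataFrame(
            {"column_index": profile.indices, "count": profile.counts}
        ).to_csv(out / "column_profile.csv", index=False)
        report["stages"].append("write")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    logger.info("pipeline finished: %d ommatidia, %d columns",
                report["count"], report["n_columns"])
    return report
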