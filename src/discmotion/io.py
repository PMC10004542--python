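"""File formats: frame stacks, displacement CSVs, manifests, and matrices.

Displacement fields are exchanged as plain CSV with one row per valid lattice
point and columns ``x, y, u, v, magnitude, peak_similarity``; floats are
written in shortest round-trip form so integer-mode fields survive a
write-read cycle bit-exactly.  The reader is tolerant of common dialect
variation in externally produced displacement files (synonymous column names
such as ``du``/``dx`` for ``u``), logging the mapping it chose.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import DisplacementField, GrayFrame, GridSpec, to_grayscale
from .heatmaps import EmotionHeatmap
from .session import Session
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "x": ("x", "row", "px", "pos_x", "xpos", "i"),
    "y": ("y", "col", "py", "pos_y", "ypos", "j"),
    "u": ("u", "du", "dx", "disp_x", "u_px", "displacement_x"),
    "v": ("v", "dv", "dy", "disp_y", "v_px", "displacement_y"),
    "magnitude": ("magnitude", "mag", "norm", "length", "disp"),
    "peak_similarity": ("peak_similarity", "similarity", "peak", "score", "corr"),
}


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------


def frame_filename(index: int) -> str:
    return f"frame_{index:04d}.png"


def write_frames(directory: str | Path, frames: Sequence[GrayFrame]) -> list[Path]:
    """Write frames as zero-padded 8-bit PNGs named by frame index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in frames:
        path = directory / frame_filename(frame.frame_index)
        iio.imwrite(path, np.clip(np.rint(frame.pixels), 0, 255).astype(np.uint8))
        paths.append(path)
    return paths


def read_frames(directory: str | Path, pattern: str = "frame_*.png") -> list[GrayFrame]:
    """Ordered grayscale frames from a PNG/JPEG stack.

    Frames are sorted by the integer index embedded in the filename, color is
    converted to grayscale via luma weights, and mixed dimensions raise an
    error listing the offending files.
    """
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern!r} in {directory}")

    def index_of(p: Path) -> int:
        m = re.search(r"(\d+)", p.stem)
        return int(m.group(1)) if m else 0

    paths.sort(key=index_of)
    frames = []
    shapes = {}
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=np.float64)
        px = to_grayscale(img) if img.ndim == 3 else img
        shapes[p.name] = px.shape
        frames.append(GrayFrame(px, frame_index=index_of(p)))
    uniq = set(shapes.values())
    if len(uniq) > 1:
        majority = max(uniq, key=lambda s: sum(1 for v in shapes.values() if v == s))
        offenders = [name for name, s in shapes.items() if s != majority]
        raise ValueError(f"non-uniform frame dimensions; offenders: {offenders}")
    return frames


# ---------------------------------------------------------------------------
# Displacement CSV
# ---------------------------------------------------------------------------


def write_displacement_csv(field: DisplacementField, path: str | Path) -> Path:
    """One row per valid lattice point; floats in shortest round-trip form."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gx, gy = np.meshgrid(field.xs, field.ys, indexing="ij")
    mag = field.magnitude
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "u", "v", "magnitude", "peak_similarity"])
        for ix, iy in np.argwhere(field.valid):
            writer.writerow(
                [
                    int(gx[ix, iy]),
                    int(gy[ix, iy]),
                    repr(float(field.u[ix, iy])),
                    repr(float(field.v[ix, iy])),
                    repr(float(mag[ix, iy])),
                    repr(float(field.peak_similarity[ix, iy])),
                ]
            )
    return path


def _map_columns(header: Sequence[str]) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    mapping: dict[str, int] = {}
    for canon, synonyms in _COLUMN_SYNONYMS.items():
        for syn in synonyms:
            if syn in lowered:
                mapping[canon] = lowered.index(syn)
                break
    missing = [c for c in ("x", "y", "u", "v") if c not in mapping]
    if missing:
        raise ValueError(f"displacement CSV is missing columns {missing}; header={header}")
    chosen = {c: header[i] for c, i in mapping.items()}
    if any(chosen[c] != c for c in chosen):
        logger.info("displacement CSV column mapping: %s", chosen)
    return mapping


def read_displacement_csv(
    path: str | Path,
    grid: GridSpec | None = None,
) -> DisplacementField:
    """Reconstruct a field from CSV; tolerant of synonymous column names.

    The lattice is inferred from the distinct x and y coordinates present;
    rows missing from the full lattice product are marked invalid.  Malformed
    rows raise with their 1-based line number.
    """
    path = Path(path)
    rows: list[tuple[int, int, float, float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path} is empty")
        mapping = _map_columns(header)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x = int(float(row[mapping["x"]]))
                y = int(float(row[mapping["y"]]))
                u = float(row[mapping["u"]])
                v = float(row[mapping["v"]])
                peak = (
                    float(row[mapping["peak_similarity"]])
                    if "peak_similarity" in mapping
                    else np.nan
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {row}") from exc
            rows.append((x, y, u, v, peak))
    if not rows:
        raise ValueError(f"{path} contains no data rows")
    xs = np.unique([r[0] for r in rows])
    ys = np.unique([r[1] for r in rows])
    nx, ny = len(xs), len(ys)
    u = np.full((nx, ny), np.nan)
    v = np.full((nx, ny), np.nan)
    peak = np.full((nx, ny), np.nan)
    valid = np.zeros((nx, ny), dtype=bool)
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: i for i, y in enumerate(ys)}
    for x, y, uu, vv, pk in rows:
        i, j = xi[x], yi[y]
        u[i, j] = uu
        v[i, j] = vv
        peak[i, j] = pk
        valid[i, j] = True
    return DisplacementField(
        xs=xs, ys=ys, u=u, v=v, peak_similarity=peak, valid=valid, grid=grid
    )


# ---------------------------------------------------------------------------
# Manifests, heatmaps, matrices, configs
# ---------------------------------------------------------------------------


def write_manifest(session: Session, path: str | Path) -> Path:
    """Session manifest: filename, index, timestamp, label, baseline index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, frame in enumerate(session.frames):
        rows.append(
            {
                "filename": frame_filename(frame.frame_index),
                "frame_index": frame.frame_index,
                "timestamp": float(frame.frame_index),
                "label": frame.label,
                "block_id": session.block_ids[i],
                "baseline_index": session.baselines.get(session.block_ids[i], 0),
                "participant_id": session.participant_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"filename", "frame_index", "label", "baseline_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def write_heatmap_csv(heatmap: EmotionHeatmap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gx, gy = np.meshgrid(heatmap.xs, heatmap.ys, indexing="ij")
    df = pd.DataFrame(
        {
            "x": gx[heatmap.valid],
            "y": gy[heatmap.valid],
            "mean_magnitude": heatmap.values[heatmap.valid],
        }
    )
    df.to_csv(path, index=False)
    return path


def write_matrix_csv(matrix: SimilarityMatrix, path: str | Path) -> Path:
    """Matrix CSV with frame labels as header row and index column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"{lbl}_{i}" for i, lbl in enumerate(matrix.labels)]
    pd.DataFrame(matrix.values, index=cols, columns=cols).to_csv(path)
    return path


def read_matrix_csv(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = tuple(c.rsplit("_", 1)[0] for c in df.columns)
    return SimilarityMatrix(values=df.to_numpy(), labels=labels)


def write_run_config(directory: str | Path, config: Mapping | object, seed: int | None = None) -> Path:
    """Provenance sidecar: the producing configuration (and seed) as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if is_dataclass(config) and not isinstance(config, type):
        payload = asdict(config)
    else:
        payload = dict(config)
    if seed is not None:
        payload["seed"] = seed
    path = directory / "run_config.json"

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        return str(o)

    path.write_text(json.dumps(payload, indent=2, default=default))
    return path
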