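"""Readers/writers for the standard formats and the end-to-end pipeline.

Volumes travel as NIfTI-1 (via nibabel) with a diagonal affine: index
``(i, j, k)`` maps to the world-mm voxel center ``origin + (i + 0.5) * size``.
Vector fields are stored as 5-D NIfTI ``(x, y, z, peak, 4)`` with components
``(v_x, v_y, v_z, d)`` and absent peaks zero-filled; ODF fields as 4-D NIfTI
plus a plain-text N x 3 direction table.  Tractograms are written as TCK
(primary, plain mm semantics) or TRK.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import yaml

from .grid import Pathway, TrackingParams, VectorField, VoxelDirectionSet, VoxelGrid
from .metrics import MetricReport, connectivity_metrics, curve_metric, spatial_metric, tangent_metric
from .peaks import OdfField, SphereSampling, build_vector_field
from .tracking import track, track_streamline

__all__ = [
    "grid_to_affine",
    "grid_from_nifti",
    "save_volume",
    "load_volume",
    "save_vector_field",
    "load_vector_field",
    "save_odf_field",
    "read_odf_field",
    "write_tractogram",
    "read_tractogram",
    "write_report",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# NIfTI volumes

def grid_to_affine(grid: VoxelGrid) -> np.ndarray:
    """Diagonal affine mapping voxel indices to world-mm voxel centers."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.voxel_size)
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.voxel_size)
    return aff


def grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) grids are supported")
    sizes = np.diag(aff[:3, :3])
    if np.any(sizes <= 0):
        raise ValueError("voxel sizes in the affine must be positive")
    origin = aff[:3, 3] - 0.5 * sizes
    return VoxelGrid(tuple(img.shape[:3]), tuple(sizes), tuple(origin))


def save_volume(data: np.ndarray, grid: VoxelGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid_to_affine(grid))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), grid_from_nifti(img)


# ---------------------------------------------------------------------------
# vector fields (5-D NIfTI: x, y, z, peak, [vx vy vz d])

def save_vector_field(field: VectorField, path) -> None:
    dims = tuple(field.grid.dims)
    n_peak = max((len(s) for s in field.sets.values()), default=1)
    data = np.zeros(dims + (n_peak, 4))
    for idx, ds in field.sets.items():
        for p, (v, d) in enumerate(ds):
            data[idx + (p,)] = [v[0], v[1], v[2], d]
    img = nib.Nifti1Image(data, grid_to_affine(field.grid))
    nib.save(img, str(path))


def load_vector_field(
    path,
    fa: Optional[np.ndarray] = None,
    wm_mask: Optional[np.ndarray] = None,
) -> VectorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 5 or data.shape[-1] != 4:
        raise ValueError(f"vector-field NIfTI must be (x, y, z, peak, 4); got {data.shape}")
    grid = grid_from_nifti(img)
    sets: dict[tuple[int, int, int], VoxelDirectionSet] = {}
    for idx in grid.all_indices():
        rows = data[idx]
        keep = rows[:, 3] > 0
        if np.any(keep):
            sets[idx] = VoxelDirectionSet(rows[keep, :3], rows[keep, 3])
    return VectorField(grid, sets, fa=fa, wm_mask=wm_mask)


# ---------------------------------------------------------------------------
# ODF fields (4-D NIfTI + plain-text direction table)

def save_odf_field(odf: OdfField, path_values, path_directions) -> None:
    img = nib.Nifti1Image(odf.values, grid_to_affine(odf.grid))
    nib.save(img, str(path_values))
    np.savetxt(str(path_directions), odf.sampling.vertices, fmt="%.17g")


def read_odf_field(path_values, path_directions) -> OdfField:
    """4-D samples plus a direction table; adjacency by convex-hull triangulation."""
    img = nib.load(str(path_values))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"ODF NIfTI must be 4-D, got {data.ndim}-D")
    dirs = np.atleast_2d(np.loadtxt(str(path_directions)))
    if dirs.shape[1] != 3:
        raise ValueError("direction table must have three columns")
    if dirs.shape[0] != data.shape[3]:
        raise ValueError(
            f"direction table has {dirs.shape[0]} rows but volume holds "
            f"{data.shape[3]} samples per voxel"
        )
    norms = np.linalg.norm(dirs, axis=1)
    bad = np.where(np.abs(norms - 1.0) > 1e-6)[0]
    if bad.size:
        raise ValueError(f"non-unit direction at table row {int(bad[0])}")
    return OdfField(grid_from_nifti(img), SphereSampling.from_vertices(dirs), data)


# ---------------------------------------------------------------------------
# tractograms

def write_tractogram(
    pathways: Sequence[Pathway], path, format: str, grid: VoxelGrid
) -> None:
    """Write pathways as TCK or TRK in world-mm coordinates."""
    streamlines = [np.asarray(p.points, dtype=np.float32) for p in pathways]
    tractogram = nib.streamlines.Tractogram(streamlines, affine_to_rasmm=np.eye(4))
    if format == "tck":
        nib.streamlines.save(tractogram, str(path))
    elif format == "trk":
        header = {
            "voxel_sizes": np.asarray(grid.voxel_size, dtype=np.float32),
            "dimensions": np.asarray(grid.dims, dtype=np.int16),
            "voxel_to_rasmm": grid_to_affine(grid).astype(np.float32),
            "voxel_order": "RAS",
        }
        nib.streamlines.save(tractogram, str(path), header=header)
    else:
        raise ValueError(f"unknown tractogram format {format!r} (use 'tck' or 'trk')")


def read_tractogram(path) -> list[np.ndarray]:
    tfile = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tfile.tractogram.streamlines]


# ---------------------------------------------------------------------------
# reports

def write_report(report: MetricReport, json_path=None, csv_path=None) -> None:
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pathway", "class"])
            for i, label in enumerate(report.labels):
                writer.writerow([i, label])


# ---------------------------------------------------------------------------
# configuration + pipeline

def _load_mask(path) -> Optional[np.ndarray]:
    if path is None:
        return None
    vol, _ = load_volume(path)
    return vol > 0


@dataclass
class RunConfig:
    """Everything one tracking run needs; YAML-serializable."""

    vector_field: Optional[str] = None
    odf_values: Optional[str] = None
    odf_directions: Optional[str] = None
    fa_map: Optional[str] = None
    wm_mask: Optional[str] = None
    seeds_file: Optional[str] = None
    seeds_mask: Optional[str] = None
    out_tractogram: str = "out.tck"
    out_format: str = "tck"
    params: TrackingParams = dc_field(default_factory=TrackingParams)
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        params = TrackingParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> None:
        if self.vector_field is None and (self.odf_values is None or self.odf_directions is None):
            raise ValueError("need either a vector field or ODF values + direction table")
        if self.seeds_file is None and self.seeds_mask is None:
            raise ValueError("need a seeds file or a seed mask")
        paths = [p for p in (self.vector_field, self.odf_values, self.out_tractogram) if p]
        if len(set(paths)) != len(paths):
            raise ValueError("input and output paths must be distinct")


def load_seeds(config: RunConfig) -> list[tuple[int, int, int]]:
    if config.seeds_file is not None:
        rows = np.atleast_2d(np.loadtxt(config.seeds_file, dtype=int))
        return [tuple(int(v) for v in r) for r in rows]
    vol, _ = load_volume(config.seeds_mask)
    return [tuple(int(v) for v in idx) for idx in np.argwhere(vol > 0)]


def run_pipeline(config: RunConfig) -> list[Pathway]:
    """ODF/vector field -> peaks -> chains -> curve fitting -> tractogram.

    Deterministic for a fixed configuration; logs per-stage counts.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fa = load_volume(config.fa_map)[0] if config.fa_map else None
    mask = _load_mask(config.wm_mask)
    if config.vector_field is not None:
        field = load_vector_field(config.vector_field, fa=fa, wm_mask=mask)
    else:
        odf = read_odf_field(config.odf_values, config.odf_directions)
        field = build_vector_field(odf, fa=fa, wm_mask=mask)
    logger.info("voxels with peaks: %d", len(field.sets))
    seeds = load_seeds(config)
    logger.info("seed voxels: %d", len(seeds))
    params = config.params
    if params.mode == "streamline":
        pathways = track_streamline(seeds, field, params)
    else:
        pathways = track(seeds, field, params)
    reasons: dict[str, int] = {}
    for p in pathways:
        key = p.termination_reason.value if p.termination_reason else "unknown"
        reasons[key] = reasons.get(key, 0) + 1
    logger.info("pathways: %d, termination reasons: %s", len(pathways), reasons)
    write_tractogram(pathways, config.out_tractogram, config.out_format, field.grid)
    return pathways


def evaluate_pathways(
    pathways: Sequence[Pathway],
    truth,
    with_local: bool = True,
) -> MetricReport:
    """Connectivity report, optionally with mean local metrics vs best-match truth."""
    report = connectivity_metrics(pathways, truth)
    if with_local and pathways and truth.curves:
        sms, tms, cms = [], [], []
        for pw in pathways:
            best = min(truth.curves, key=lambda t: spatial_metric(pw, t))
            sms.append(spatial_metric(pw, best))
            if len(pw) >= 3 and len(best) >= 3:
                tms.append(tangent_metric(pw, best))
            if len(pw) >= 5 and len(best) >= 5:
                cms.append(curve_metric(pw, best))
        report.sm = float(np.mean(sms))
        report.tm = float(np.mean(tms)) if tms else None
        report.cm = float(np.mean(cms)) if cms else None
    return report
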