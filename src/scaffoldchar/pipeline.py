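"""End-to-end characterization: segment -> pore size -> percolation (-> nuclei).

Produces a per-scaffold report mirroring the multi-scaffold comparison
workflow: voxel-weighted pore size mean ± SD, percolation diameter, and
optional cell metrics, with a full parameter echo so every report can be
regenerated from its own serialized form.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cell_quant, percolation, pore_metrics, segmentation
from .volumes import BinaryVolume, VolumeImage, read_mask, read_volume

__all__ = ["ScaffoldReport", "StageError", "characterize", "default_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    return {
        "input": None,
        "voxel_size_um": None,
        "input_is_mask": False,
        "segmentation": {
            "pore_is": "darker",
            "despeckle": "keep_largest",
            "min_size_voxels": None,
            "per_slice": False,
        },
        "poresize": {"bin_width_um": 10.0, "guard_um": None},
        "percolation": {
            "axis": "z",
            "d_min_um": None,
            "d_max_um": None,
            "step_um": None,
            "nu": percolation.NU_3D,
        },
        "nuclei": None,
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class ScaffoldReport:
    """Per-scaffold characterization with full provenance."""

    input_path: str | None
    voxel_size_um: float
    parameters: dict
    pore_size: dict
    percolation_fit: dict
    percolation_curve: dict
    porosity: float
    cell_metrics: dict | None = None
    software_version: str = field(default="")

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "voxel_size_um": self.voxel_size_um,
            "parameters": self.parameters,
            "pore_size": self.pore_size,
            "percolation_fit": self.percolation_fit,
            "percolation_curve": self.percolation_curve,
            "porosity": self.porosity,
            "cell_metrics": self.cell_metrics,
            "software_version": self.software_version,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "ScaffoldReport":
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "ScaffoldReport":
        return cls.from_dict(json.loads(text))


def characterize(config: dict | None = None,
                 volume: VolumeImage | BinaryVolume | None = None,
                 nuclei_stack: VolumeImage | None = None) -> ScaffoldReport:
    """Run the full pipeline on a volume (from config path or in memory).

    Stages run as segment -> poresize -> percolation, plus nuclei when a
    stack is configured or passed; any stage failure raises
    :class:`StageError` naming the stage. Deterministic given inputs.
    """
    from . import __version__

    cfg = _merge(default_config(), config)

    if volume is None:
        if cfg["input"] is None:
            raise StageError("input", ValueError("no input volume configured"))
        try:
            reader = read_mask if cfg["input_is_mask"] else read_volume
            volume = reader(cfg["input"], cfg["voxel_size_um"])
        except Exception as exc:  # noqa: BLE001 - report the stage
            raise StageError("input", exc) from exc

    try:
        if isinstance(volume, BinaryVolume):
            mask = volume
            if cfg["segmentation"]["despeckle"]:
                mask = segmentation.despeckle(
                    mask, policy=cfg["segmentation"]["despeckle"],
                    min_size_voxels=cfg["segmentation"]["min_size_voxels"])
        else:
            mask = segmentation.segment(
                volume,
                pore_is=cfg["segmentation"]["pore_is"],
                despeckle_policy=cfg["segmentation"]["despeckle"],
                min_size_voxels=cfg["segmentation"]["min_size_voxels"],
                per_slice=cfg["segmentation"]["per_slice"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("segmentation", exc) from exc

    try:
        tmap = pore_metrics.local_thickness(mask)
        psd = pore_metrics.pore_size_distribution(
            tmap, bin_width_um=cfg["poresize"]["bin_width_um"],
            guard_um=cfg["poresize"]["guard_um"])
    except Exception as exc:
        raise StageError("poresize", exc) from exc

    try:
        pcfg = cfg["percolation"]
        curve = percolation.percolation_curve(
            mask, d_min_um=pcfg["d_min_um"], d_max_um=pcfg["d_max_um"],
            step_um=pcfg["step_um"], axis=pcfg["axis"])
        fit = percolation.estimate_percolation_diameter(curve, nu=pcfg["nu"])
    except Exception as exc:
        raise StageError("percolation", exc) from exc

    cell_metrics = None
    ncfg = cfg.get("nuclei")
    if nuclei_stack is not None or (ncfg and ncfg.get("input")):
        ncfg = ncfg or {}
        try:
            if nuclei_stack is None:
                nuclei_stack = read_volume(ncfg["input"],
                                           ncfg.get("voxel_size_um"))
            nuclei = cell_quant.detect_nuclei(
                nuclei_stack,
                expected_radius_um=ncfg.get("expected_radius_um", 6.0),
                intensity_floor=ncfg.get("intensity_floor"))
            profile = cell_quant.depth_distribution(
                nuclei, bin_width_um=ncfg.get("bin_width_um", 50.0))
            window = ncfg.get("depth_window_um", 100.0)
            density = (cell_quant.surface_density(nuclei, window)
                       if nuclei.field_depth_um >= window else None)
            cell_metrics = {
                "count": nuclei.count,
                "surface_density_per_mm2": density,
                "depth_profile": profile.to_dict(),
                "coordinates_um": nuclei.coordinates_um.tolist(),
            }
        except Exception as exc:
            raise StageError("nuclei", exc) from exc

    return ScaffoldReport(
        input_path=str(cfg["input"]) if cfg["input"] else None,
        voxel_size_um=float(mask.voxel_size),
        parameters=cfg,
        pore_size=psd.to_dict(),
        percolation_fit=fit.to_dict(),
        percolation_curve=curve.to_dict(),
        porosity=float(np.mean(mask.mask)),
        cell_metrics=cell_metrics,
        software_version=__version__,
    )
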