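"""End-to-end per-vessel analysis and multi-vessel study orchestration.

``analyze_vessel`` composes the stages: trace both basement-membrane
surfaces (or load supplied contours), loft them into closed meshes, compute
CLN-5 density inside the endothelial surface, detect DRAQ5⁺ nuclei, classify
them into compartments and summarize their 3D spread.  ``run_study``
repeats this over groups of vessels (e.g. 12 venules per experimental
group) and applies the density group statistics.  Every report embeds the
configuration hash, seed and software version for auditability.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import DensityResult, cln5_density, compare_density_groups
from .nuclei import SpreadProfile, Spot, classify_spots, detect_nuclei, spread_profile
from .phantom import PhantomSpec, generate_phantom, phantom_preset
from .stack import ImageStack
from .surfaces import ContourSet, extract_slice_contours, loft_surface, read_contours_json

logger = logging.getLogger("vesselquant")

__all__ = ["VesselConfig", "VesselReport", "StageError", "analyze_vessel", "run_study", "run_preset_study"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class VesselConfig:
    """All knobs of the per-vessel pipeline (YAML-serializable)."""

    endothelial_channel: str = "CD31"
    parenchymal_channel: str = "Lam1"
    cln5_channel: str = "CLN-5"
    nuclei_channel: str = "DRAQ5"
    surface_threshold: str | float = "otsu"
    density_threshold: str | float = "otsu"
    nuclei_threshold: str | float = "otsu"
    surface_smoothing_sigma: float = 0.3
    ring_vertices: int = 64
    min_nucleus_diameter: float = 3.0
    split_touching: bool = False
    # optional paths to contour JSON files that bypass automated extraction
    endothelial_contours: str | None = None
    parenchymal_contours: str | None = None

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VesselConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class VesselReport:
    """Per-vessel quantification: density, compartment counts, spread."""

    vessel_id: str
    group: str
    day: str
    density: DensityResult
    compartment_counts: dict[str, int]
    spread: SpreadProfile
    spots: list[Spot] = field(repr=False, default_factory=list)
    provenance: dict = field(default_factory=dict)

    def row(self) -> dict:
        return {
            "vessel_id": self.vessel_id,
            "group": self.group,
            "day": self.day,
            "total_intensity": self.density.total_intensity,
            "surface_area": self.density.surface_area,
            "density": self.density.density,
            "threshold_used": self.density.threshold_used,
            "luminal": self.compartment_counts["luminal"],
            "perivascular": self.compartment_counts["perivascular"],
            "parenchymal": self.compartment_counts["parenchymal"],
        }


def _surface(stack: ImageStack, config: VesselConfig, which: str) -> ContourSet:
    path = getattr(config, f"{which}_contours")
    if path is not None:
        return read_contours_json(path)
    channel = getattr(config, f"{which}_channel")
    return extract_slice_contours(
        stack,
        channel,
        threshold=config.surface_threshold,
        smoothing_sigma=config.surface_smoothing_sigma,
        surface_name=f"{which}_bm",
    )


def analyze_vessel(
    stack: ImageStack,
    config: VesselConfig | None = None,
    vessel_id: str = "vessel",
    group: str = "",
    day: str = "",
) -> VesselReport:
    """Run the full per-vessel pipeline; deterministic given stack + config."""
    config = config or VesselConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            logger.info("stage %s: start", name)
            return fn(*args, **kwargs)
        except (StageError, Exception) as e:  # tag errors with the stage
            if isinstance(e, StageError):
                raise
            raise StageError(name, e) from e

    endo_contours = stage("endothelial_contours", _surface, stack, config, "endothelial")
    par_contours = stage("parenchymal_contours", _surface, stack, config, "parenchymal")
    endo_mesh = stage("loft_endothelial", loft_surface, endo_contours, stack.voxel_spacing, config.ring_vertices)
    par_mesh = stage("loft_parenchymal", loft_surface, par_contours, stack.voxel_spacing, config.ring_vertices)
    density = stage(
        "cln5_density",
        cln5_density,
        stack,
        config.cln5_channel,
        endo_mesh,
        config.density_threshold,
        vessel_id,
        group,
        day,
    )
    spots = stage(
        "detect_nuclei",
        detect_nuclei,
        stack,
        config.nuclei_channel,
        config.min_nucleus_diameter,
        config.nuclei_threshold,
        config.split_touching,
    )
    labeled = stage("classify_spots", classify_spots, spots, endo_mesh, par_mesh)
    profile = spread_profile(labeled)
    return VesselReport(
        vessel_id=vessel_id,
        group=group,
        day=day,
        density=density,
        compartment_counts=dict(profile.counts),
        spread=profile,
        spots=labeled,
        provenance={"config_hash": config.config_hash, "version": __version__},
    )


def run_study(
    vessels: list[tuple[ImageStack, str, str, str]],
    config: VesselConfig | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Analyze many vessels and compare density across groups.

    ``vessels`` is a list of (stack, vessel_id, group, day).  With a single
    group only the per-vessel table is returned (stats None, warning
    logged); otherwise the ANOVA/Bonferroni density report is attached.
    """
    config = config or VesselConfig()
    reports = [analyze_vessel(s, config, vid, grp, day) for s, vid, grp, day in vessels]
    table = pd.DataFrame([r.row() for r in reports])
    groups = table["group"].unique()
    if len(groups) < 2:
        logger.warning("single group %s: summary only, no group statistics", groups)
        return table, None
    stats_report = compare_density_groups([r.density for r in reports])
    return table, stats_report


def run_preset_study(
    presets: list[str],
    n_per_group: int = 12,
    base_seed: int = 0,
    config: VesselConfig | None = None,
    spec_overrides: dict | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Generate ``n_per_group`` phantoms per preset and run the study."""
    vessels = []
    for gi, name in enumerate(presets):
        for i in range(n_per_group):
            seed = base_seed + 1000 * gi + i
            spec = phantom_preset(name, seed=seed, **(spec_overrides or {}))
            stack, _ = generate_phantom(spec)
            vessels.append((stack, f"{name}_{i:02d}", name, ""))
    return run_study(vessels, config)
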