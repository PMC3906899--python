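"""Synthetic spinal-venule phantoms with full ground truth.

The generator emulates the kind of confocal dataset the analysis modules
expect: a straight venule imaged as 60 z-slices at 1 μm increments with
sub-micron xy sampling.  Geometry is two nested coaxial tubes — the
endothelial basement membrane (BM) and the parenchymal BM — both labeled in
the Lam1 channel, with the endothelium additionally in CD31.  The CLN-5
channel carries a junctional lattice (longitudinal + circumferential line
segments, a honeycomb-like tight-junction proxy) on the endothelial tube;
barrier disruption is parameterized by ``cln5_coverage``, the fraction of
lattice segments retained, so that low coverage mimics the focal
fragmentation of tight-junction staining seen in neuroinflamed vessels.
DRAQ5 renders nuclei placed in the luminal, perivascular (between the BMs)
or parenchymal compartment.  Optional GFAP (parenchymal astrocyte territory)
and CCL2 channels support colocalization tests.

Rendering order is: paint geometry → add background → Gaussian blur →
noise (Poisson on signal+background, or additive Gaussian).  Identical
``(spec, seed)`` gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .stack import ImageStack

__all__ = [
    "PhantomSpec",
    "NucleusRecord",
    "GroundTruth",
    "generate_phantom",
    "phantom_preset",
    "PRESET_NAMES",
    "cylinder_area",
]

COMPARTMENTS = ("luminal", "perivascular", "parenchymal")

#: Minimum center-to-center clearance between nuclei beyond touching (μm);
#: keeps blurred nuclei separable so detection ground truth is unambiguous.
_NUCLEUS_GAP = 2.0


def cylinder_area(radius: float, length: float) -> float:
    """Closed-cylinder surface area 2πrL + 2πr² (both end caps included)."""
    return 2.0 * np.pi * radius * length + 2.0 * np.pi * radius**2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic vessel phantom.

    Radii are nested: ``lumen_radius < endo_bm_radius < parench_bm_radius``
    and every radius must fit inside the xy grid extent.  ``cln5_coverage``
    is the fraction f ∈ [0, 1] of junctional lattice segments retained.
    """

    grid_shape: tuple[int, int, int] = (60, 144, 144)
    voxel_spacing: tuple[float, float, float] = (1.0, 0.3, 0.3)
    lumen_radius: float = 5.0
    endo_bm_radius: float = 7.0
    parench_bm_radius: float = 16.0
    cln5_coverage: float = 1.0
    junction_line_width: float = 0.6
    n_nuclei: dict[str, int] = field(
        default_factory=lambda: {"luminal": 0, "perivascular": 0, "parenchymal": 2}
    )
    nucleus_diameter_mean: float = 5.0
    nucleus_diameter_sd: float = 0.3
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"Lam1": 200.0, "CLN-5": 255.0, "DRAQ5": 220.0, "CD31": 180.0}
    )
    background_level: float = 5.0
    blur_sigma: tuple[float, float, float] = (0.5, 0.3, 0.3)
    noise_model: str = "poisson"  # "none" | "poisson" | "gaussian"
    gaussian_noise_sd: float = 2.0
    seed: int = 0
    # geometry details (not part of the study conditions; fixed defaults)
    bm_thickness: float = 0.8
    n_longitudinal: int = 12
    ring_spacing: float = 5.0
    placement_margin: float = 1.0

    def validate(self) -> None:
        nz, ny, nx = self.grid_shape
        dz, dy, dx = self.voxel_spacing
        if any(v <= 0 for v in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if any(int(v) <= 0 for v in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if not (0.0 < self.lumen_radius < self.endo_bm_radius < self.parench_bm_radius):
            raise ValueError(
                "radii must satisfy 0 < lumen_radius < endo_bm_radius < parench_bm_radius"
            )
        half_extent = min(ny * dy, nx * dx) / 2.0
        if self.parench_bm_radius + self.bm_thickness / 2 >= half_extent:
            raise ValueError(
                f"parench_bm_radius {self.parench_bm_radius} μm does not fit the "
                f"{2 * half_extent:.1f} μm xy field"
            )
        if not 0.0 <= self.cln5_coverage <= 1.0:
            raise ValueError("cln5_coverage must lie in [0, 1]")
        if any(c < 0 for c in self.n_nuclei.values()):
            raise ValueError("nucleus counts must be non-negative")
        if set(self.n_nuclei) - set(COMPARTMENTS):
            raise ValueError(f"unknown compartments in n_nuclei: {set(self.n_nuclei) - set(COMPARTMENTS)}")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.nucleus_diameter_mean <= 0:
            raise ValueError("nucleus_diameter_mean must be positive")

    @property
    def length(self) -> float:
        """Vessel length = full z extent, μm."""
        return self.grid_shape[0] * self.voxel_spacing[0]

    @property
    def center_yx(self) -> tuple[float, float]:
        """Vessel axis position (y, x) μm — the grid center."""
        _, ny, nx = self.grid_shape
        _, dy, dx = self.voxel_spacing
        return (ny * dy / 2.0, nx * dx / 2.0)


@dataclass
class NucleusRecord:
    center: tuple[float, float, float]  # (z, y, x) μm
    diameter: float  # μm
    compartment: str


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    contours: dict[str, list[dict]]  # surface -> [{"z": int, "polygon": [[y,x],...]}]
    analytic_areas: dict[str, float]  # closed-cylinder areas, μm²
    radii: dict[str, float]
    nuclei: list[NucleusRecord]
    realized_cln5_coverage: float
    seed: int

    def nucleus_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in COMPARTMENTS}
        for n in self.nuclei:
            counts[n.compartment] += 1
        return counts

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["nuclei"] = [NucleusRecord(tuple(n["center"]), n["diameter"], n["compartment"]) for n in d["nuclei"]]
        return cls(**d)


def _circle_polygon(radius: float, center_yx: tuple[float, float], n: int = 96) -> list[list[float]]:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    cy, cx = center_yx
    return [[float(cy + radius * np.sin(a)), float(cx + radius * np.cos(a))] for a in ang]


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-π, π]."""
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _cln5_lattice(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Render the junctional lattice and apply seeded segment removal.

    The lattice lives on the endothelial tube: ``n_longitudinal`` lines
    parallel to the axis, plus circumferential rings every ``ring_spacing``
    μm.  Lattice voxels are partitioned into segments (each voxel owned by
    exactly one segment — node voxels go to the longitudinal line); removal
    keeps exactly round(f·n) segments per type, chosen by a seeded
    permutation, so realized voxel coverage tracks f tightly.

    Returns the binary lattice volume and the realized voxel coverage
    (retained voxels / all lattice voxels).
    """
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_spacing
    cy, cx = spec.center_yx
    r = spec.endo_bm_radius
    w = spec.junction_line_width

    yc = (np.arange(ny) + 0.5) * dy - cy
    xc = (np.arange(nx) + 0.5) * dx - cx
    rho = np.hypot(yc[:, None], xc[None, :])
    theta = np.arctan2(yc[:, None], xc[None, :])  # (-π, π]
    zc = (np.arange(nz) + 0.5) * dz

    shell2d = np.abs(rho - r) <= w / 2.0

    n_long = spec.n_longitudinal
    dalpha = 2.0 * np.pi / n_long
    j_near = np.round(theta / dalpha).astype(int) % n_long
    arc_dist = r * np.abs(_wrap_angle(theta - j_near * dalpha))
    on_long2d = shell2d & (arc_dist <= w / 2.0)

    ring_z = np.arange(spec.ring_spacing / 2.0, spec.length, spec.ring_spacing)
    n_rings = len(ring_z)
    k_near = np.clip(np.round((zc - ring_z[0]) / spec.ring_spacing).astype(int), 0, n_rings - 1)
    z_dist = np.abs(zc - ring_z[k_near])
    on_ring_z = z_dist <= w / 2.0  # (nz,)

    # longitudinal segment intervals are bounded by the ring z positions
    interval = np.searchsorted(ring_z, zc)  # (nz,) in 0..n_rings
    # angular interval of a circumferential arc segment
    j_interval = (np.floor((theta + np.pi) / dalpha).astype(int)) % n_long

    long_vox = np.broadcast_to(on_long2d[None, :, :], (nz, ny, nx))
    ring_vox = on_ring_z[:, None, None] & np.broadcast_to(shell2d[None, :, :], (nz, ny, nx)) & ~long_vox

    # segment ids: longitudinal -> (line j, z interval); circumferential -> (ring k, arc j)
    long_seg = (np.broadcast_to(j_near[None, :, :], (nz, ny, nx)) * (n_rings + 1)
                + interval[:, None, None])
    ring_seg = (np.broadcast_to(k_near[:, None, None], (nz, ny, nx)) * n_long
                + np.broadcast_to(j_interval[None, :, :], (nz, ny, nx)))

    lattice = np.zeros((nz, ny, nx), dtype=bool)
    total_vox = int(long_vox.sum() + ring_vox.sum())
    if total_vox == 0:
        return lattice, 0.0

    f = spec.cln5_coverage
    retained = 0
    for vox_mask, seg_id, n_segs in (
        (long_vox, long_seg, n_long * (n_rings + 1)),
        (ring_vox, ring_seg, n_rings * n_long),
    ):
        ids = np.unique(seg_id[vox_mask])
        keep_n = int(round(f * len(ids)))
        keep = ids[rng.permutation(len(ids))[:keep_n]]
        kept_mask = vox_mask & np.isin(seg_id, keep)
        lattice |= kept_mask
        retained += int(kept_mask.sum())
    return lattice, retained / total_vox


def _place_nuclei(spec: PhantomSpec, rng: np.random.Generator) -> list[NucleusRecord]:
    """Rejection-sample non-overlapping nuclei inside their compartments.

    Constraints: the whole nucleus plus ``placement_margin`` stays strictly
    inside its compartment's radial band, inside the grid, and pairwise
    center distances exceed the sum of radii plus a fixed clearance.
    """
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_spacing
    cy, cx = spec.center_yx
    m = spec.placement_margin
    L = spec.length
    placed: list[NucleusRecord] = []

    for compartment in COMPARTMENTS:
        count = int(spec.n_nuclei.get(compartment, 0))
        for _ in range(count):
            for _try in range(20000):
                d = float(np.clip(
                    rng.normal(spec.nucleus_diameter_mean, spec.nucleus_diameter_sd),
                    spec.nucleus_diameter_mean - 2 * spec.nucleus_diameter_sd,
                    spec.nucleus_diameter_mean + 2 * spec.nucleus_diameter_sd,
                ))
                rad = d / 2.0
                z = rng.uniform(m + rad, L - m - rad)
                y = rng.uniform(rad + 0.5, ny * dy - rad - 0.5)
                x = rng.uniform(rad + 0.5, nx * dx - rad - 0.5)
                rho = float(np.hypot(y - cy, x - cx))
                if compartment == "luminal":
                    ok = rho + rad + m <= spec.lumen_radius
                elif compartment == "perivascular":
                    ok = (rho - rad - m >= spec.endo_bm_radius
                          and rho + rad + m <= spec.parench_bm_radius)
                else:  # parenchymal
                    ok = rho - rad - m >= spec.parench_bm_radius
                if not ok:
                    continue
                if any(
                    np.linalg.norm(np.subtract((z, y, x), p.center)) < rad + p.diameter / 2.0 + _NUCLEUS_GAP
                    for p in placed
                ):
                    continue
                placed.append(NucleusRecord((float(z), float(y), float(x)), d, compartment))
                break
            else:
                raise RuntimeError(
                    f"could not place a {compartment} nucleus; compartment too small for "
                    f"{count} nuclei of ~{spec.nucleus_diameter_mean} μm with {m} μm margins"
                )
    return placed


def _render_nuclei(spec: PhantomSpec, nuclei: list[NucleusRecord]) -> np.ndarray:
    """Solid spheres in physical space (anisotropic ellipsoids in voxels)."""
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_spacing
    vol = np.zeros((nz, ny, nx), dtype=np.float32)
    zc = (np.arange(nz) + 0.5) * dz
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx
    for n in nuclei:
        z0, y0, x0 = n.center
        r = n.diameter / 2.0
        zi = np.flatnonzero(np.abs(zc - z0) <= r)
        yi = np.flatnonzero(np.abs(yc - y0) <= r)
        xi = np.flatnonzero(np.abs(xc - x0) <= r)
        if zi.size == 0 or yi.size == 0 or xi.size == 0:
            continue
        dz2 = (zc[zi] - z0)[:, None, None] ** 2
        dy2 = (yc[yi] - y0)[None, :, None] ** 2
        dx2 = (xc[xi] - x0)[None, None, :] ** 2
        inside = dz2 + dy2 + dx2 <= r * r
        sub = vol[np.ix_(zi, yi, xi)]
        sub[inside] = 1.0
        vol[np.ix_(zi, yi, xi)] = sub
    return vol


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a phantom stack and its ground truth.

    Channels present are those with an entry in ``spec.channel_gains``
    (ordering fixed as Lam1, CLN-5, DRAQ5, CD31, GFAP, CCL2).  Deterministic:
    the same spec (including its seed) always returns bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_spacing
    cy, cx = spec.center_yx

    yc = (np.arange(ny) + 0.5) * dy - cy
    xc = (np.arange(nx) + 0.5) * dx - cx
    rho = np.hypot(yc[:, None], xc[None, :])

    def tube_shell(radius: float) -> np.ndarray:
        shell2d = np.abs(rho - radius) <= spec.bm_thickness / 2.0
        return np.broadcast_to(shell2d[None, :, :], (nz, ny, nx)).astype(np.float32)

    lattice, realized = _cln5_lattice(spec, rng)
    nuclei = _place_nuclei(spec, rng)

    renders: dict[str, np.ndarray] = {}
    gains = spec.channel_gains
    if "Lam1" in gains:
        renders["Lam1"] = (tube_shell(spec.endo_bm_radius) + tube_shell(spec.parench_bm_radius)).clip(0, 1)
    if "CLN-5" in gains:
        renders["CLN-5"] = lattice.astype(np.float32)
    if "DRAQ5" in gains:
        renders["DRAQ5"] = _render_nuclei(spec, nuclei)
    if "CD31" in gains:
        renders["CD31"] = tube_shell(spec.endo_bm_radius)
    if "GFAP" in gains:
        parenchyma = (rho >= spec.parench_bm_radius + spec.bm_thickness).astype(np.float32)
        renders["GFAP"] = 0.6 * np.broadcast_to(parenchyma[None, :, :], (nz, ny, nx)).copy()
    if "CCL2" in gains:
        renders["CCL2"] = tube_shell(spec.endo_bm_radius)

    sigma_vox = tuple(s / d for s, d in zip(spec.blur_sigma, spec.voxel_spacing))
    channels = []
    names = []
    for name in ("Lam1", "CLN-5", "DRAQ5", "CD31", "GFAP", "CCL2"):
        if name not in renders:
            continue
        img = renders[name] * float(gains[name]) + spec.background_level
        if any(s > 0 for s in sigma_vox):
            img = gaussian_filter(img, sigma=sigma_vox)
        if spec.noise_model == "poisson":
            img = rng.poisson(np.maximum(img, 0.0)).astype(np.float32)
        elif spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.gaussian_noise_sd, size=img.shape)
        img = np.maximum(img, 0.0).astype(np.float32)
        channels.append(img)
        names.append(name)

    stack = ImageStack(np.stack(channels), spec.voxel_spacing, tuple(names))
    truth = GroundTruth(
        contours={
            "endothelial_bm": [
                {"z": int(z), "polygon": _circle_polygon(spec.endo_bm_radius, (cy, cx))}
                for z in range(nz)
            ],
            "parenchymal_bm": [
                {"z": int(z), "polygon": _circle_polygon(spec.parench_bm_radius, (cy, cx))}
                for z in range(nz)
            ],
        },
        analytic_areas={
            "endothelial_bm": cylinder_area(spec.endo_bm_radius, spec.length),
            "parenchymal_bm": cylinder_area(spec.parench_bm_radius, spec.length),
        },
        radii={
            "lumen": spec.lumen_radius,
            "endothelial_bm": spec.endo_bm_radius,
            "parenchymal_bm": spec.parench_bm_radius,
        },
        nuclei=nuclei,
        realized_cln5_coverage=realized,
        seed=spec.seed,
    )
    return stack, truth


#: Presets encode the qualitative disease regimes quantified in the study:
#: junctional coverage degrades with disease (naive continuous → WT d16 most
#: fragmented), perivascular cellularity rises, and only the endothelial
#: CCL2 knockout accumulates cells inside the lumen (stalled transmigration).
_PRESETS: dict[str, dict] = {
    "naive": dict(cln5_coverage=1.0, n_nuclei={"luminal": 0, "perivascular": 0, "parenchymal": 2}),
    "wt_d9": dict(cln5_coverage=0.40, n_nuclei={"luminal": 0, "perivascular": 8, "parenchymal": 3}),
    "wt_d16": dict(cln5_coverage=0.20, n_nuclei={"luminal": 0, "perivascular": 12, "parenchymal": 4}),
    "astro_ko_d16": dict(cln5_coverage=0.40, n_nuclei={"luminal": 0, "perivascular": 12, "parenchymal": 2}),
    "endo_ko_d16": dict(cln5_coverage=0.30, n_nuclei={"luminal": 4, "perivascular": 5, "parenchymal": 2}),
}

PRESET_NAMES = tuple(_PRESETS)


def phantom_preset(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """A named study-condition phantom spec.

    Presets differ only in ``cln5_coverage`` and nucleus counts; geometry,
    gains and noise are shared.  ``seed`` and keyword overrides are passed
    through to :class:`PhantomSpec`.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    spec = PhantomSpec(seed=seed, **kwargs)
    spec.validate()
    return spec
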