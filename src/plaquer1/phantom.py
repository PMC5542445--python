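"""Synthetic vessel phantoms with known T1, B1 and plaque ground truth.

The generator emulates a longitudinal mouse-aorta contrast study without any
scanner data: a straight vessel (lumen + wall annulus) runs along the slice
axis, ellipsoidal plaque blobs sit on the wall, a gadolinium-based agent
accumulates only in plaque and raises the local longitudinal rate by
``r1 * C_Gd`` (relaxivity times concentration), and a smooth B1 field plus
Rician magnitude noise corrupt the simulated saturation-recovery readouts.

Everything is deterministic given a seed; the ground truth (label volume, T1
maps, B map, plaque volume) travels with the simulated images so estimators
can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import ImageSeries
from .grid import Grid, save_nifti
from .relaxometry import sr_signal

__all__ = [
    "BACKGROUND",
    "LUMEN",
    "WALL",
    "PLAQUE",
    "B1Field",
    "VesselGeometry",
    "PlaqueBlob",
    "PhantomSpec",
    "GroundTruth",
    "PairedStudy",
    "build_ground_truth",
    "simulate_sr_series",
    "simulate_anatomy_volume",
    "make_paired_study",
    "wildtype_spec",
    "progression_spec",
    "regression_spec",
    "DEFAULT_DELAYS_MS",
    "DEFAULT_TR_MS",
    "DELTA_R1_CALIBRATION",
]

# compartment labels
BACKGROUND, LUMEN, WALL, PLAQUE = 0, 1, 2, 3
_COMPARTMENTS = ("background", "lumen", "wall", "plaque")

#: canonical saturation-delay scheme (ms) and repetition time (ms)
DEFAULT_DELAYS_MS = (77.0, 200.0, 350.0, 500.0, 1200.0)
DEFAULT_TR_MS = 1500.0

#: group-level mean plaque ΔR1 targets (s^-1) used to calibrate the agent
#: concentration ladder of the presets, indexed by weeks on high-fat diet.
DELTA_R1_CALIBRATION = {
    "progression": {9: 0.28, 13: 0.5, 17: 1.06, 21: 3.29},
    "regression": {13: 0.49, 19: 0.58, 25: 1.33},
}


@dataclass(frozen=True)
class B1Field:
    """Smooth B parameter field: constant plus one long-wavelength Gaussian bump.

    B is the cosine of the effective saturation flip angle, so a calibrated
    system sits near 0.  The default keeps B below ~0.15: beyond that the
    recovery signal at the shortest delay dips negative for long-T1 tissue,
    which would break the non-negativity that magnitude-image fitting relies
    on (no polarity restoration is attempted downstream).
    """

    mean: float = 0.08
    amplitude: float = 0.07
    length_scale_mm: float = 2.5
    center_mm: tuple[float, float, float] = (0.8, -0.6, 0.4)

    def evaluate(self, x, y, z) -> np.ndarray:
        d2 = (
            (x - self.center_mm[0]) ** 2
            + (y - self.center_mm[1]) ** 2
            + (z - self.center_mm[2]) ** 2
        )
        b = self.mean + self.amplitude * np.exp(-d2 / (2.0 * self.length_scale_mm**2))
        return np.clip(b, 0.0, 0.99)


@dataclass(frozen=True)
class VesselGeometry:
    """Straight vessel along the slice (last) axis."""

    lumen_radius_mm: float = 0.45
    wall_thickness_mm: float = 0.16
    center_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def outer_radius_mm(self) -> float:
        return self.lumen_radius_mm + self.wall_thickness_mm


@dataclass(frozen=True)
class PlaqueBlob:
    """Ellipsoidal plaque deposit attached to the vessel wall."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic animal.

    T1 values (ms) are in the physiological range for blood, vessel wall and
    plaque at high field; ``gd_concentration`` (mmol/L) is non-zero only
    where the agent accumulates, and ``r1_agent`` is its longitudinal
    relaxivity in L·mmol^-1·s^-1.  ``noise_sigma`` is the magnitude-noise
    standard deviation as a fraction of the maximum compartment S0.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (0.14, 0.14, 0.22)
    vessel: VesselGeometry = field(default_factory=VesselGeometry)
    plaques: tuple[PlaqueBlob, ...] = ()
    t1_tissue: dict = field(
        default_factory=lambda: {"lumen": 2000.0, "wall": 1200.0, "plaque": 1000.0, "background": 1400.0}
    )
    s0_tissue: dict = field(
        default_factory=lambda: {"lumen": 1.0, "wall": 0.8, "plaque": 0.9, "background": 0.25}
    )
    gd_concentration: dict = field(
        default_factory=lambda: {"lumen": 0.0, "wall": 0.0, "plaque": 0.0, "background": 0.0}
    )
    r1_agent: float = 18.0
    b1_field: B1Field = field(default_factory=B1Field)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if any(self.t1_tissue.get(c, 1.0) <= 0 for c in _COMPARTMENTS):
            raise ValueError("all tissue T1 values must be positive")
        if any(self.gd_concentration.get(c, 0.0) < 0 for c in _COMPARTMENTS):
            raise ValueError("gd_concentration must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.b1_field.mean < 1.0:
            raise ValueError("B must lie in [0, 1)")

    @property
    def grid(self) -> Grid:
        shape = tuple(int(s) for s in self.grid_shape)
        vs = self.voxel_size
        # centre the FOV on the vessel axis
        origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, vs))
        return Grid(shape=shape, voxel_size=vs, fov_origin=origin)


@dataclass
class GroundTruth:
    """Noise-free truth for one synthetic animal."""

    labels: np.ndarray
    t1_pre: np.ndarray
    t1_post: np.ndarray
    b_map: np.ndarray
    s0_map: np.ndarray
    gd_map: np.ndarray
    grid: Grid
    plaque_volume_mm3: float
    spec: PhantomSpec

    @property
    def delta_r1_truth(self) -> np.ndarray:
        """Ground-truth ΔR1 (s^-1) = r1 * C_Gd, exactly."""
        return self.spec.r1_agent * self.gd_map

    def plaque_mask(self) -> np.ndarray:
        return self.labels == PLAQUE

    def plaque_projected_area_mm2(self, axis: int = 0) -> float:
        """Area of the plaque silhouette projected along one axis (mm^2).

        Serves as the 2D total-plaque-area analogue of an opened-vessel
        surface preparation: the plaque's footprint seen from the lumen.
        """
        proj = self.plaque_mask().any(axis=axis)
        vs = [v for i, v in enumerate(self.grid.voxel_size) if i != axis]
        return float(proj.sum() * vs[0] * vs[1])

    def save(self, directory, stem: str = "truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_nifti(self.labels.astype(np.int16), self.grid, directory / f"{stem}_labels.nii")
        save_nifti(self.t1_pre, self.grid, directory / f"{stem}_t1_pre.nii")
        save_nifti(self.t1_post, self.grid, directory / f"{stem}_t1_post.nii")
        save_nifti(self.b_map, self.grid, directory / f"{stem}_b.nii")


@dataclass
class PairedStudy:
    """One animal's pre/post-contrast acquisitions plus ground truth."""

    sr_pre: ImageSeries
    sr_post: ImageSeries
    anatomy_pre: ImageSeries
    anatomy_post: ImageSeries
    truth: GroundTruth
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# ground truth construction
# ---------------------------------------------------------------------------


def _compartment_volume(values: dict, labels: np.ndarray) -> np.ndarray:
    out = np.empty(labels.shape, dtype=float)
    for idx, name in enumerate(_COMPARTMENTS):
        out[labels == idx] = float(values.get(name, 0.0))
    return out


def build_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Voxelise the phantom and derive pre/post T1 maps and the B field.

    The agent shortens T1 through R1_post = R1_pre + r1 * C_Gd (rates in
    s^-1, T1 in ms, so R1 = 1000 / T1); with zero concentration the pre and
    post maps are identical.
    """
    grid = spec.grid
    x, y, z = grid.coordinate_arrays()

    r = np.hypot(x - spec.vessel.center_mm[0], y - spec.vessel.center_mm[1])
    labels = np.full(grid.shape, BACKGROUND, dtype=np.int16)
    labels[r <= spec.vessel.outer_radius_mm] = WALL
    labels[r <= spec.vessel.lumen_radius_mm] = LUMEN

    wall_ring = (r > spec.vessel.lumen_radius_mm) & (r <= spec.vessel.outer_radius_mm)
    for n, blob in enumerate(spec.plaques):
        cx, cy, cz = blob.center_mm
        ax, ay, az = blob.semi_axes_mm
        if min(ax, ay, az) <= 0:
            raise ValueError(f"plaque blob {n}: semi-axes must be positive")
        inside = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
        if not inside.any():
            raise ValueError(f"plaque blob {n} lies entirely outside the grid")
        if not (inside & wall_ring).any():
            raise ValueError(f"plaque blob {n} does not intersect the vessel wall")
        labels[inside] = PLAQUE

    t1_pre = _compartment_volume(spec.t1_tissue, labels)
    gd_map = _compartment_volume(spec.gd_concentration, labels)
    r1_post = 1000.0 / t1_pre + spec.r1_agent * gd_map
    t1_post = 1000.0 / r1_post

    b_map = spec.b1_field.evaluate(x, y, z)
    s0_map = _compartment_volume(spec.s0_tissue, labels)
    plaque_volume = float((labels == PLAQUE).sum()) * grid.voxel_volume_mm3

    return GroundTruth(
        labels=labels,
        t1_pre=t1_pre,
        t1_post=t1_post,
        b_map=b_map,
        s0_map=s0_map,
        gd_map=gd_map,
        grid=grid,
        plaque_volume_mm3=plaque_volume,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _rician(noiseless: np.ndarray, sigma_abs: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex Gaussian perturbation around the true signal."""
    if sigma_abs == 0:
        return noiseless.copy()
    re = noiseless + rng.normal(0.0, sigma_abs, noiseless.shape)
    im = rng.normal(0.0, sigma_abs, noiseless.shape)
    return np.hypot(re, im)


def simulate_sr_series(
    truth: GroundTruth,
    delays_ms=DEFAULT_DELAYS_MS,
    tr_ms: float = DEFAULT_TR_MS,
    noise_sigma: float | None = None,
    seed: int | None = None,
    contrast: str = "pre",
    c: float = 1.0,
) -> ImageSeries:
    """Forward-simulate the saturation-recovery series of one contrast state.

    Each voxel's noiseless intensity is the signal model evaluated at its
    compartment S0, true T1 and true B (C = 1); magnitude noise is Rician
    with absolute sigma ``noise_sigma * max(S0)``.
    """
    delays_ms = np.asarray(delays_ms, dtype=float)
    if delays_ms.size == 0:
        raise ValueError("delays must be non-empty")
    if noise_sigma is None:
        noise_sigma = truth.spec.noise_sigma
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    t1 = truth.t1_post if contrast == "post" else truth.t1_pre
    sigma_abs = noise_sigma * float(truth.s0_map.max())
    rng = np.random.default_rng(truth.spec.seed if seed is None else seed)
    volumes = []
    for t in delays_ms:
        clean = sr_signal(truth.s0_map, t1, truth.b_map, t, tr_ms, c=c)
        volumes.append(_rician(clean, sigma_abs, rng))
    return ImageSeries(volumes=volumes, delays_ms=delays_ms, tr_ms=tr_ms, grid=truth.grid)


def simulate_anatomy_volume(
    truth: GroundTruth,
    ti_ms: float = 250.0,
    tr_ms: float = 650.0,
    hi_res_factor: int = 1,
    noise_sigma: float | None = None,
    seed: int | None = None,
    contrast: str = "post",
    fov_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ImageSeries:
    """Simulate the high-resolution anatomical volume used for volumetry.

    The ground-truth maps are resampled to a ``hi_res_factor``-times finer
    grid by label replication before signal synthesis, and the field of view
    may be shifted to exercise cross-grid ROI transfer.  The same recovery
    signal model is reused at a single effective delay ``ti_ms`` — a stated
    simplification standing in for a dedicated anatomical readout.
    """
    f = int(hi_res_factor)
    if f < 1:
        raise ValueError("hi_res_factor must be >= 1")
    if noise_sigma is None:
        noise_sigma = truth.spec.noise_sigma
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")

    def up(a: np.ndarray) -> np.ndarray:
        for axis in range(3):
            a = np.repeat(a, f, axis=axis)
        return a

    t1 = up(truth.t1_post if contrast == "post" else truth.t1_pre)
    s0 = up(truth.s0_map)
    b = up(truth.b_map)

    coarse = truth.grid
    vs = tuple(v / f for v in coarse.voxel_size)
    origin = tuple(
        o - (cv - fv) / 2.0 + s
        for o, cv, fv, s in zip(coarse.fov_origin, coarse.voxel_size, vs, fov_shift_mm)
    )
    grid = Grid(shape=t1.shape, voxel_size=vs, fov_origin=origin)

    clean = sr_signal(s0, t1, b, ti_ms, tr_ms)
    rng = np.random.default_rng(truth.spec.seed if seed is None else seed)
    vol = _rician(clean, noise_sigma * float(truth.s0_map.max()), rng)
    return ImageSeries(volumes=[vol], delays_ms=np.array([ti_ms]), tr_ms=tr_ms, grid=grid)


def make_paired_study(
    spec: PhantomSpec,
    delays_ms=DEFAULT_DELAYS_MS,
    tr_ms: float = DEFAULT_TR_MS,
    anatomy_ti_ms: float = 250.0,
    anatomy_tr_ms: float = 650.0,
    hi_res_factor: int = 1,
    anatomy_shift_mm: tuple[float, float, float] = (0.07, -0.05, 0.0),
    out_dir=None,
) -> PairedStudy:
    """Bundle pre/post saturation-recovery series and anatomy volumes.

    Sub-seeds for the four acquisitions are derived from ``spec.seed`` so
    the whole study is reproducible from a single integer.  With an output
    directory given, all volumes are written as NIfTI plus a JSON manifest.
    """
    truth = build_ground_truth(spec)
    sub = np.random.SeedSequence(spec.seed).generate_state(4).tolist()
    sr_pre = simulate_sr_series(truth, delays_ms, tr_ms, seed=sub[0], contrast="pre")
    sr_post = simulate_sr_series(truth, delays_ms, tr_ms, seed=sub[1], contrast="post")
    anat_pre = simulate_anatomy_volume(
        truth, anatomy_ti_ms, anatomy_tr_ms, hi_res_factor, seed=sub[2],
        contrast="pre", fov_shift_mm=anatomy_shift_mm,
    )
    anat_post = simulate_anatomy_volume(
        truth, anatomy_ti_ms, anatomy_tr_ms, hi_res_factor, seed=sub[3],
        contrast="post", fov_shift_mm=anatomy_shift_mm,
    )
    study = PairedStudy(sr_pre, sr_post, anat_pre, anat_post, truth, spec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sr_pre.save(out_dir, "sr_pre")
        sr_post.save(out_dir, "sr_post")
        anat_pre.save(out_dir, "anatomy_pre")
        anat_post.save(out_dir, "anatomy_post")
        truth.save(out_dir)
        manifest = {
            "delays_ms": list(np.asarray(delays_ms, dtype=float)),
            "tr_ms": float(tr_ms),
            "anatomy_ti_ms": float(anatomy_ti_ms),
            "anatomy_tr_ms": float(anatomy_tr_ms),
            "voxel_size_mm": list(spec.grid.voxel_size),
            "fov_origin_mm": list(spec.grid.fov_origin),
            "seed": int(spec.seed),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return study


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

_BASE_SEMI_AXES = (0.30, 0.24, 0.45)  # mm; base blob volume 4/3*pi*abc = 0.136 mm^3

#: group-mean total plaque volume targets (mm^3) the geometry ladder is
#: calibrated against (in vivo volumetry scale); the size ``scale`` per week
#: solves 4/3*pi*abc*scale^3*(1 + 0.7^3 per extra blob) = target.
TPV_CALIBRATION = {
    "progression": {9: 0.44, 13: 0.63, 17: 1.36, 21: 1.91},
    "regression": {13: 1.04, 19: 1.30, 25: 1.58},
}
#: (size scale, number of blobs) per week, derived from TPV_CALIBRATION
_PROGRESSION_SCALE = {9: (1.48, 1), 13: (1.67, 1), 17: (1.96, 2), 21: (2.19, 2)}
_REGRESSION_SCALE = {13: (1.79, 2), 19: (1.92, 2), 25: (2.06, 2)}
_DELTA_R1_REL_SD = 0.5  # lognormal sigma of the per-animal agent-uptake factor
_SIZE_REL_SD = 0.12  # lognormal sigma of the per-animal plaque-size factor
#: correlation between the animal's size and uptake latent factors: advanced
#: plaques carry more binding matrix, so concentration co-varies with extent
_SIZE_UPTAKE_RHO = 0.6


def _plaque_ladder(
    scale: float,
    n_blobs: int,
    size_factor: float,
    rng: np.random.Generator,
    vessel: VesselGeometry,
) -> tuple[PlaqueBlob, ...]:
    """Wall-attached ellipsoids whose total size grows with ``scale``."""
    theta = rng.uniform(0.0, 2 * np.pi)
    rad = vessel.lumen_radius_mm + 0.5 * vessel.wall_thickness_mm
    axes = tuple(a * scale * size_factor for a in _BASE_SEMI_AXES)
    z0 = float(rng.uniform(-0.3, 0.3))
    blobs = [
        PlaqueBlob(
            center_mm=(rad * np.cos(theta), rad * np.sin(theta), z0),
            semi_axes_mm=axes,
        )
    ]
    if n_blobs >= 2:  # advanced disease: a second, smaller deposit
        theta2 = theta + np.pi * (0.8 + 0.4 * rng.uniform())
        axes2 = tuple(0.7 * a for a in axes)
        blobs.append(
            PlaqueBlob(
                center_mm=(rad * np.cos(theta2), rad * np.sin(theta2), -z0),
                semi_axes_mm=axes2,
            )
        )
    return tuple(blobs)


def _group_spec(group: str, week: int, seed: int, scale_table: dict) -> PhantomSpec:
    if week not in scale_table:
        raise ValueError(f"no {group} preset at week {week}; choose from {sorted(scale_table)}")
    rng = np.random.default_rng(seed)
    vessel = VesselGeometry()
    scale, n_blobs = scale_table[week]
    # correlated mean-one lognormal animal effects for size and uptake,
    # so preset group means stay on the calibration ladders
    z_size = rng.standard_normal()
    z_uptake = _SIZE_UPTAKE_RHO * z_size + np.sqrt(1 - _SIZE_UPTAKE_RHO**2) * rng.standard_normal()
    size_factor = float(np.exp(-0.5 * _SIZE_REL_SD**2 + _SIZE_REL_SD * z_size))
    uptake_factor = float(
        np.exp(-0.5 * _DELTA_R1_REL_SD**2 + _DELTA_R1_REL_SD * z_uptake)
    )
    blobs = _plaque_ladder(scale, n_blobs, size_factor, rng, vessel)
    target_dr1 = DELTA_R1_CALIBRATION[group][week]
    c_gd = target_dr1 / 18.0 * uptake_factor
    # mild biological variation of tissue T1 between animals
    t1_jitter = {
        comp: base * float(np.exp(rng.normal(-0.5 * 0.03**2, 0.03)))
        for comp, base in (("wall", 1200.0), ("plaque", 1000.0))
    }
    return PhantomSpec(
        vessel=vessel,
        plaques=blobs,
        t1_tissue={"lumen": 2000.0, "background": 1400.0, **t1_jitter},
        gd_concentration={"lumen": 0.0, "wall": 0.0, "plaque": c_gd, "background": 0.0},
        seed=seed,
    )


def progression_spec(week: int, seed: int = 0) -> PhantomSpec:
    """Synthetic animal kept on high-fat diet, imaged at ``week`` (9/13/17/21).

    Plaque size and agent concentration follow a monotone ladder calibrated
    so group-mean ΔR1 matches the progression trajectory; per-animal factors
    (blob position, size, uptake) are drawn from ``seed``.
    """
    return _group_spec("progression", week, seed, _PROGRESSION_SCALE)


def regression_spec(week: int, seed: int = 0) -> PhantomSpec:
    """Synthetic diet-reversal animal at ``week`` (13/19/25) after diet start."""
    return _group_spec("regression", week, seed, _REGRESSION_SCALE)


def wildtype_spec(seed: int = 0) -> PhantomSpec:
    """Healthy control: intact vessel, no plaque, no agent uptake."""
    return PhantomSpec(plaques=(), seed=seed)
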