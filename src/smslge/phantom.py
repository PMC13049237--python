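"""Synthetic short-axis cardiac phantoms with IR contrast, motion and coils.

Everything downstream (encoding, reconstruction, motion correction, metrics)
is exercised against stacks produced here, so every generator is a pure,
seeded function of its configuration.

Conventions: image arrays are indexed ``(y, x)`` with 0-based pixel indices,
``y`` the phase-encode direction and ``x`` the readout direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_BLOOD",
    "LABEL_MYOCARDIUM",
    "LABEL_SCAR",
    "TissueParams",
    "PhantomStack",
    "MotionState",
    "CoilMaps",
    "PhantomConfig",
    "ir_signal",
    "make_phantom",
    "make_coil_maps",
    "motion_trace",
    "render_single_shot",
    "apply_motion",
]

LABEL_BACKGROUND = 0
LABEL_BLOOD = 1
LABEL_MYOCARDIUM = 2
LABEL_SCAR = 3


@dataclass(frozen=True)
class TissueParams:
    """Relaxation/equilibrium parameters for one labelled tissue class.

    Parameters
    ----------
    name
        One of ``blood``, ``myocardium``, ``scar``, ``background``.
    T1
        Longitudinal relaxation time in ms. Must be positive for any
        non-background tissue.
    M0
        Equilibrium signal in arbitrary units, ``>= 0``. Background has 0.
    """

    name: str
    T1: float
    M0: float

    def __post_init__(self) -> None:
        if self.name != "background" and self.T1 <= 0:
            raise ValueError(f"tissue {self.name!r} requires T1 > 0, got {self.T1}")
        if self.M0 < 0:
            raise ValueError(f"tissue {self.name!r} requires M0 >= 0, got {self.M0}")
        if self.name == "background" and self.M0 != 0:
            raise ValueError("background tissue must have M0 = 0")


#: Default post-contrast tissue table (synthetic values; scar recovers fastest
#: so it is bright at the myocardium-nulling TI).
DEFAULT_TISSUES: dict[int, TissueParams] = {
    LABEL_BACKGROUND: TissueParams("background", T1=1.0, M0=0.0),
    LABEL_BLOOD: TissueParams("blood", T1=350.0, M0=1.0),
    LABEL_MYOCARDIUM: TissueParams("myocardium", T1=450.0, M0=0.8),
    LABEL_SCAR: TissueParams("scar", T1=280.0, M0=0.9),
}

#: TI nulling the default myocardium: T1 * ln 2.
DEFAULT_TI = 450.0 * float(np.log(2.0))


@dataclass(frozen=True)
class MotionState:
    """Rigid translation plus an optional smooth sinusoidal warp, in pixels."""

    dx: float = 0.0
    dy: float = 0.0
    deform_amplitude: float = 0.0

    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and self.deform_amplitude == 0.0

    @property
    def displacement(self) -> float:
        return float(np.hypot(self.dx, self.dy))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the annular-myocardium phantom.

    All radii in pixels, centred in the matrix. A scar sector (angular wedge
    of the myocardial annulus) is inserted in ``scar_slices``.
    """

    n_slices: int = 2
    matrix: tuple[int, int] = (64, 64)
    pixel_spacing: tuple[float, float] = (1.48, 1.98)
    slice_thickness: float = 8.0
    blood_radius: float = 10.0
    myo_outer_radius: float = 19.0
    scar_slices: tuple[int, ...] = (0, 1)
    scar_angle_deg: tuple[float, float] = (-60.0, 60.0)
    scar_transmural: bool = True
    tissues: dict[int, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )


@dataclass
class PhantomStack:
    """Label maps and tissue parameters for a short-axis stack."""

    n_slices: int
    matrix: tuple[int, int]
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    labels: np.ndarray  # (n_slices, ny, nx) int
    tissue_table: dict[int, TissueParams]
    scar_mask: np.ndarray  # (n_slices, ny, nx) bool

    @property
    def stack_extent_mm(self) -> float:
        return self.n_slices * self.slice_thickness

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    def scar_volume_ml(self) -> float:
        """Ground-truth scar volume: exact pixel-count arithmetic, in mL."""
        n_px = int(self.scar_mask.sum())
        return n_px * self.pixel_area_mm2 * self.slice_thickness / 1000.0

    def tissue_mask(self, label: int, slice_idx: int) -> np.ndarray:
        return self.labels[slice_idx] == label


@dataclass
class CoilMaps:
    """Smooth complex receive sensitivities on the extended PE grid."""

    n_coils: int
    maps: np.ndarray  # (n_coils, ny_ext, nx) complex

    @property
    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


def ir_signal(tissue: TissueParams, TI: float) -> float:
    """Ideal single-inversion longitudinal signal ``M0 * (1 - 2 exp(-TI/T1))``.

    Monotonically increasing in TI; crosses zero at ``TI = T1 ln 2``.
    """
    if TI < 0:
        raise ValueError(f"TI must be >= 0, got {TI}")
    if tissue.T1 <= 0:
        raise ValueError(f"T1 must be > 0, got {tissue.T1}")
    return float(tissue.M0 * (1.0 - 2.0 * np.exp(-TI / tissue.T1)))


def _disk(ny: int, nx: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:ny, 0:nx]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def make_phantom(config: PhantomConfig, seed: int = 0) -> PhantomStack:
    """Build an annular-myocardium phantom stack; deterministic in *seed*.

    The seed perturbs the ventricle centre by a fraction of a pixel per slice
    so that distinct seeds give distinct (but equivalent) geometries.
    """
    ny, nx = config.matrix
    if ny < 64 or nx < 64:
        raise ValueError(f"matrix must be at least 64x64, got {config.matrix}")
    if config.n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if config.myo_outer_radius <= config.blood_radius:
        raise ValueError("myocardial outer radius must exceed blood-pool radius")
    if config.myo_outer_radius >= min(ny, nx) / 2 - 2:
        raise ValueError(
            f"phantom of radius {config.myo_outer_radius} does not fit the "
            f"{ny}x{nx} matrix"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros((config.n_slices, ny, nx), dtype=np.int16)
    scar_mask = np.zeros((config.n_slices, ny, nx), dtype=bool)
    for s in range(config.n_slices):
        cy = (ny - 1) / 2.0 + rng.uniform(-0.3, 0.3)
        cx = (nx - 1) / 2.0 + rng.uniform(-0.3, 0.3)
        blood = _disk(ny, nx, cy, cx, config.blood_radius)
        myo = _disk(ny, nx, cy, cx, config.myo_outer_radius) & ~blood
        labels[s][myo] = LABEL_MYOCARDIUM
        labels[s][blood] = LABEL_BLOOD
        if s in config.scar_slices:
            yy, xx = np.mgrid[0:ny, 0:nx]
            ang = np.degrees(np.arctan2(yy - cy, xx - cx))
            lo, hi = config.scar_angle_deg
            sector = (ang >= lo) & (ang <= hi)
            scar = myo & sector
            if not config.scar_transmural:
                inner = _disk(
                    ny,
                    nx,
                    cy,
                    cx,
                    (config.blood_radius + config.myo_outer_radius) / 2.0,
                )
                scar &= inner
            labels[s][scar] = LABEL_SCAR
            scar_mask[s] = scar
    return PhantomStack(
        n_slices=config.n_slices,
        matrix=config.matrix,
        pixel_spacing=config.pixel_spacing,
        slice_thickness=config.slice_thickness,
        labels=labels,
        tissue_table=dict(config.tissues),
        scar_mask=scar_mask,
    )


def make_coil_maps(
    n_coils: int,
    grid: tuple[int, int],
    seed: int = 0,
    ramp_cycles: float = 3.0,
) -> CoilMaps:
    """Generate smooth complex coil sensitivities on ``grid = (ny_ext, nx)``.

    Each coil is a Gaussian magnitude lobe centred around the FOV with a
    coil-specific linear phase ramp (up to ``ramp_cycles`` cycles across the
    grid, distinct per coil) plus a small random bilinear term. The distinct
    ramps spread the coils' k-space signatures along the phase-encode axis,
    which is what keeps the parallel-imaging unaliasing well conditioned —
    the synthetic analogue of element-to-element phase variation in a large
    receive array.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    ny, nx = grid
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    yy = yy / ny - 0.5
    xx = xx / nx - 0.5
    maps = np.empty((n_coils, ny, nx), dtype=np.complex128)
    for c in range(n_coils):
        theta = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cy = 0.55 * np.sin(theta)
        cx = 0.55 * np.cos(theta)
        width = 0.55 + rng.uniform(-0.05, 0.05)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width**2))
        ramp_angle = 2 * np.pi * (c + 0.5) / n_coils + rng.uniform(-0.1, 0.1)
        ky_c = ramp_cycles * np.sin(ramp_angle)
        kx_c = ramp_cycles * np.cos(ramp_angle)
        phase = (
            rng.uniform(-np.pi, np.pi)
            + 2 * np.pi * (ky_c * yy + kx_c * xx)
            + rng.uniform(-0.8, 0.8) * yy * xx
        )
        maps[c] = mag * np.exp(1j * phase)
    # normalize so RSS ~ 1 in the FOV centre
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[ny // 2, nx // 2]
    return CoilMaps(n_coils=n_coils, maps=maps)


def motion_trace(
    n_reps: int,
    amplitude: float,
    outlier_indices: set[int] | frozenset[int] = frozenset(),
    outlier_scale: float = 5.0,
    seed: int = 0,
    deform_amplitude: float = 0.0,
) -> list[MotionState]:
    """Seeded per-repetition respiratory motion states.

    Regular repetitions move within ``amplitude`` pixels of the origin;
    repetitions listed in ``outlier_indices`` are pushed to a displacement
    magnitude of at least ``outlier_scale * amplitude`` (emulating deep
    breaths that the selection stage must discard).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    bad = [i for i in outlier_indices if not (0 <= i < n_reps)]
    if bad:
        raise ValueError(f"outlier indices out of range [0, {n_reps}): {bad}")
    rng = np.random.default_rng(seed)
    states: list[MotionState] = []
    for i in range(n_reps):
        if amplitude == 0 and i not in outlier_indices:
            states.append(MotionState(0.0, 0.0, 0.0))
            continue
        phase = rng.uniform(0, 2 * np.pi)
        r = amplitude * rng.uniform(0.3, 1.0)
        dx = r * np.cos(phase)
        dy = r * np.sin(phase)
        if i in outlier_indices:
            base = max(amplitude, 1.0)
            target = outlier_scale * base * rng.uniform(1.0, 1.3)
            norm = max(np.hypot(dx, dy), 1e-9)
            dx, dy = dx / norm * target, dy / norm * target
        states.append(
            MotionState(float(dx), float(dy), float(deform_amplitude))
        )
    return states


def _warp_coordinates(
    shape: tuple[int, int], motion: MotionState
) -> tuple[np.ndarray, np.ndarray]:
    """Backward-warp sampling coordinates realizing *motion*."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    src_y = yy - motion.dy
    src_x = xx - motion.dx
    if motion.deform_amplitude != 0.0:
        # one-cycle sinusoidal in-plane warp, zero at the frame border
        a = motion.deform_amplitude
        src_y = src_y - a * np.sin(2 * np.pi * xx / nx) * np.sin(np.pi * yy / ny)
        src_x = src_x - a * np.sin(2 * np.pi * yy / ny) * np.sin(np.pi * xx / nx)
    return src_y, src_x


def apply_motion(img: np.ndarray, motion: MotionState) -> np.ndarray:
    """Warp *img* by the motion state (linear interpolation, zero boundary)."""
    if motion.is_identity():
        return img.copy()
    src_y, src_x = _warp_coordinates(img.shape, motion)
    coords = np.stack([src_y, src_x])
    if np.iscomplexobj(img):
        re = ndimage.map_coordinates(img.real, coords, order=1, cval=0.0)
        im = ndimage.map_coordinates(img.imag, coords, order=1, cval=0.0)
        return re + 1j * im
    return ndimage.map_coordinates(img, coords, order=1, cval=0.0)


def render_single_shot(
    phantom: PhantomStack,
    slice_idx: int,
    TI: float | None,
    motion: MotionState = MotionState(),
    edge_blur: float = 0.6,
) -> np.ndarray:
    """Render one complex single-shot image of *slice_idx*.

    ``TI=None`` renders the reference (no inversion) shot used by the
    two-heartbeat PSIR scheme: every tissue contributes its plain ``M0``.
    Otherwise each pixel carries the signed inversion-recovery signal of its
    tissue; a light Gaussian blur (``edge_blur`` px, 0 disables) smooths the
    label edges before the motion warp so sub-pixel shifts are well behaved.
    """
    if not (0 <= slice_idx < phantom.n_slices):
        raise IndexError(f"slice index {slice_idx} out of range")
    labels = phantom.labels[slice_idx]
    img = np.zeros(labels.shape, dtype=float)
    for label, tissue in phantom.tissue_table.items():
        if tissue.name == "background":
            continue
        value = tissue.M0 if TI is None else ir_signal(tissue, TI)
        img[labels == label] = value
    if edge_blur > 0:
        img = ndimage.gaussian_filter(img, sigma=edge_blur)
    img = apply_motion(img, motion)
    return img.astype(np.complex128)


def nulling_ti(tissue: TissueParams) -> float:
    """TI at which the ideal IR signal of *tissue* crosses zero."""
    return float(tissue.T1 * np.log(2.0))


def shift_tissue_t1(
    phantom: PhantomStack, label: int, new_t1: float
) -> PhantomStack:
    """Return a copy of the stack with one tissue's T1 replaced."""
    table = dict(phantom.tissue_table)
    table[label] = replace(table[label], T1=new_t1)
    out = PhantomStack(
        n_slices=phantom.n_slices,
        matrix=phantom.matrix,
        pixel_spacing=phantom.pixel_spacing,
        slice_thickness=phantom.slice_thickness,
        labels=phantom.labels.copy(),
        tissue_table=table,
        scar_mask=phantom.scar_mask.copy(),
    )
    return out
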