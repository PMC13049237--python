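"""Motion correction: centre-of-mass selection, non-rigid registration, averaging.

Per slice, the repeated single shots are reduced to one image in three steps:

1. the two repetitions whose centre of mass is most dissimilar from the rest
   of the series are discarded (8 -> 6 by default);
2. the retained magnitude images are co-registered non-rigidly onto the
   repetition closest to the refined mean centre of mass;
3. the warped images (PSIR values, using the magnitude-derived motion fields)
   are averaged pixelwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_tvl1

__all__ = [
    "SelectionResult",
    "DeformationField",
    "RegistrationConfig",
    "center_of_mass",
    "select_images",
    "register_nonrigid",
    "warp",
    "moco_average",
]


@dataclass
class SelectionResult:
    """Outcome of the centre-of-mass outlier-rejection step."""

    coms: list[tuple[float, float]]
    initial_mean: tuple[float, float]
    refined_mean: tuple[float, float]
    retained: list[int]
    discarded: list[int]


@dataclass
class DeformationField:
    """Backward displacement field (px) mapping onto a target repetition."""

    displacements: np.ndarray  # (2, ny, nx): (dy, dx)
    target: int
    converged: bool = True


@dataclass(frozen=True)
class RegistrationConfig:
    """Multi-resolution optical-flow settings for non-rigid registration."""

    pyramid_levels: int = 3
    smoothing: float = 2.0
    iterations: int = 12
    attachment: float = 8.0
    tightness: float = 0.3


def center_of_mass(img: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid ``(y, x)`` of a non-negative image."""
    img = np.asarray(img, dtype=float)
    total = img.sum()
    if total <= 0:
        raise ValueError("center of mass undefined for an image with no mass")
    ny, nx = img.shape
    yy = np.arange(ny)
    xx = np.arange(nx)
    cy = float((img.sum(axis=1) * yy).sum() / total)
    cx = float((img.sum(axis=0) * xx).sum() / total)
    return cy, cx


def select_images(
    coms: list[tuple[float, float]], n_keep: int = 6
) -> SelectionResult:
    """Discard the repetitions with the most dissimilar centres of mass.

    The initial mean over all centres is refined to the mean of its 4 closest
    points; the ``n_keep`` centres closest to the refined mean are retained.
    Distance ties are broken by lower repetition index.
    """
    n = len(coms)
    if n < n_keep + 1:
        raise ValueError(
            f"need at least {n_keep + 1} centres of mass to discard any, "
            f"got {n}"
        )
    pts = np.asarray(coms, dtype=float)
    initial = pts.mean(axis=0)
    d_init = np.linalg.norm(pts - initial, axis=1)
    closest4 = np.lexsort((np.arange(n), d_init))[:4]
    refined = pts[closest4].mean(axis=0)
    d_ref = np.linalg.norm(pts - refined, axis=1)
    order = np.lexsort((np.arange(n), d_ref))
    retained = sorted(int(i) for i in order[:n_keep])
    discarded = sorted(int(i) for i in order[n_keep:])
    return SelectionResult(
        coms=[(float(y), float(x)) for y, x in pts],
        initial_mean=(float(initial[0]), float(initial[1])),
        refined_mean=(float(refined[0]), float(refined[1])),
        retained=retained,
        discarded=discarded,
    )


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum((a - b) ** 2))


def register_nonrigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
    target: int = -1,
) -> DeformationField:
    """Estimate a dense displacement field warping *moving* onto *fixed*.

    Multi-resolution TV-L1 optical flow; the field is only accepted if it
    reduces the sum of squared differences, otherwise the best available
    field (possibly identity) is returned with ``converged=False`` — the
    operation never raises on difficult pairs.
    """
    if moving.shape != fixed.shape:
        raise ValueError(
            f"grid mismatch: moving {moving.shape} vs fixed {fixed.shape}"
        )
    mov = np.ascontiguousarray(moving, dtype=float)
    fix = np.ascontiguousarray(fixed, dtype=float)
    scale = max(np.abs(fix).max(), np.abs(mov).max())
    if scale == 0:
        return DeformationField(
            displacements=np.zeros((2,) + fix.shape), target=target
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        flow = optical_flow_tvl1(
            fix / scale,
            mov / scale,
            num_warp=config.pyramid_levels + 2,
            num_iter=config.iterations,
            attachment=config.attachment,
            tightness=config.tightness,
            prefilter=True,
        )
    flow = np.asarray(flow)
    if config.smoothing > 0 and flow.any():
        # Gaussian field regularization suppresses noise-driven deformation
        flow = np.stack(
            [ndimage.gaussian_filter(f, config.smoothing) for f in flow]
        )
    field = DeformationField(displacements=flow, target=target)
    ssd_before = _ssd(mov, fix)
    ssd_after = _ssd(warp(mov, field), fix)
    if ssd_after > ssd_before:
        return DeformationField(
            displacements=np.zeros((2,) + fix.shape),
            target=target,
            converged=False,
        )
    return field


def warp(img: np.ndarray, field: DeformationField) -> np.ndarray:
    """Backward-warp *img* by the field (linear interpolation, zero boundary)."""
    if field.displacements.shape[1:] != img.shape:
        raise ValueError(
            f"field grid {field.displacements.shape[1:]} does not match "
            f"image grid {img.shape}"
        )
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    coords = np.stack(
        [yy + field.displacements[0], xx + field.displacements[1]]
    )
    if np.iscomplexobj(img):
        re = ndimage.map_coordinates(img.real, coords, order=1, cval=0.0)
        im = ndimage.map_coordinates(img.imag, coords, order=1, cval=0.0)
        return re + 1j * im
    return ndimage.map_coordinates(
        np.asarray(img, dtype=float), coords, order=1, cval=0.0
    )


def moco_average(
    series: list[np.ndarray],
    magnitude_series: list[np.ndarray] | None = None,
    n_keep: int = 6,
    config: RegistrationConfig = RegistrationConfig(),
) -> tuple[np.ndarray, SelectionResult, list[DeformationField]]:
    """Run the full selection/registration/averaging chain on one slice.

    ``series`` holds the images to be averaged (typically signed PSIR
    values); ``magnitude_series`` drives the centre-of-mass selection and the
    motion estimation (defaults to ``|series|``), and its fields are reused
    to warp ``series``. The reference repetition is the retained one whose
    centre of mass lies closest to the refined mean.
    """
    n = len(series)
    if n < 3:
        raise ValueError(f"need at least 3 repetitions, got {n}")
    if magnitude_series is None:
        magnitude_series = [np.abs(s) for s in series]
    if len(magnitude_series) != n:
        raise ValueError("magnitude series length mismatch")
    n_keep = min(n_keep, n - 2)
    coms = [center_of_mass(np.abs(m)) for m in magnitude_series]
    sel = select_images(coms, n_keep=n_keep)
    refined = np.asarray(sel.refined_mean)
    retained_pts = np.asarray([coms[i] for i in sel.retained])
    d = np.linalg.norm(retained_pts - refined, axis=1)
    ref_idx = sel.retained[int(np.argmin(d))]
    fixed_mag = np.abs(magnitude_series[ref_idx])
    fields: list[DeformationField] = []
    warped: list[np.ndarray] = []
    for i in sel.retained:
        if i == ref_idx:
            f = DeformationField(
                displacements=np.zeros((2,) + fixed_mag.shape), target=ref_idx
            )
        else:
            f = register_nonrigid(
                np.abs(magnitude_series[i]), fixed_mag, config, target=ref_idx
            )
        fields.append(f)
        warped.append(warp(series[i], f))
    if all(np.array_equal(w, warped[0]) for w in warped[1:]):
        final = warped[0].copy()  # keep bit-exactness for identical inputs
    else:
        final = np.mean(warped, axis=0)
    return final, sel, fields
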