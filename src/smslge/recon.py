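"""Reconstruction: T-GRAPPA, coil combination, FOV partitioning and PSIR.

The interleaved undersampled repetitions are merged into a fully sampled
calibration k-space (most recent repetition wins per line); GRAPPA weights
fitted on it synthesize the missing lines of every single shot. The coil
images are combined with the known sensitivities, the extended-FOV composite
is split into the two simultaneously excited slices, and signed PSIR values
are restored from the reference-shot phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CoilMaps
from .sms_encode import KSpaceData, ProtocolParams, ifft2c

__all__ = [
    "GrappaWeights",
    "PsirImage",
    "build_acs",
    "calibrate_grappa",
    "apply_grappa",
    "coil_combine",
    "partition_fov",
    "partition_fov_multicoil",
    "psir",
    "reconstruct_shot",
]

#: default kernel: 4 source lines x 5 source columns
DEFAULT_KERNEL = (4, 5)


@dataclass
class GrappaWeights:
    """Fitted GRAPPA interpolation weights for one acceleration factor.

    ``weights[d]`` maps stacked source samples (all coils x kernel points)
    to the target samples of all coils at gap offset ``d`` (1..R-1) below a
    sampled line.
    """

    kernel: tuple[int, int]
    weights: dict[int, np.ndarray]  # d -> (n_src, n_coils)
    R: int
    n_coils: int
    quality_flag: bool = False  # True when the fit looked underdetermined

    @property
    def ky_offsets(self) -> dict[int, np.ndarray]:
        n_ky = self.kernel[0]
        out = {}
        for d in range(1, self.R):
            j = np.arange(n_ky) - (n_ky // 2 - 1)
            out[d] = -d + j * self.R
        return out

    @property
    def kx_offsets(self) -> np.ndarray:
        n_kx = self.kernel[1]
        return np.arange(n_kx) - n_kx // 2


@dataclass
class PsirImage:
    """Signed-signal image restored by phase-sensitive reconstruction."""

    values: np.ndarray  # (ny, nx) real
    provenance: tuple[str, str] = ("ir", "ref")


def build_acs(reps: list[KSpaceData]) -> np.ndarray:
    """Merge interleaved repetitions into one fully sampled k-space.

    Every phase-encode line is taken from the most recent (last in the list)
    repetition that sampled it. Raises if the repetitions do not jointly
    cover all line offsets modulo R.
    """
    if not reps:
        raise ValueError("need at least one repetition")
    R = reps[0].R
    covered = {rep.rep_index % R for rep in reps}
    missing = sorted(set(range(R)) - covered)
    if missing:
        raise ValueError(
            f"repetitions do not cover all {R} line offsets; missing offsets "
            f"{missing}"
        )
    acs = np.zeros_like(reps[0].data)
    for rep in reps:  # later repetitions overwrite earlier ones
        acs[:, rep.mask, :] = rep.data[:, rep.mask, :]
    return acs


def _gather_sources(
    k: np.ndarray,
    targets_y: np.ndarray,
    ky_off: np.ndarray,
    kx_off: np.ndarray,
) -> np.ndarray:
    """Stack source samples for each target line into an (n_t*nx, n_src) matrix.

    k is (n_coils, ny, nx); out-of-range ky clamps to zero rows via padding.
    """
    n_coils, ny, nx = k.shape
    pad_y = int(max(abs(ky_off.min()), abs(ky_off.max())))
    pad_x = int(max(abs(kx_off.min()), abs(kx_off.max())))
    kp = np.pad(
        k, ((0, 0), (pad_y, pad_y), (pad_x, pad_x)), mode="constant"
    )
    cols = []
    for dy in ky_off:
        for dx in kx_off:
            block = kp[
                :,
                targets_y + pad_y + dy,
                :,
            ][:, :, pad_x + dx : pad_x + dx + nx]
            # block: (n_coils, n_t, nx) -> (n_t*nx, n_coils)
            cols.append(block.transpose(1, 2, 0).reshape(-1, n_coils))
    return np.concatenate(cols, axis=1)  # (n_t*nx, n_ky*n_kx*n_coils)


def calibrate_grappa(
    acs: np.ndarray,
    R: int,
    kernel: tuple[int, int] = DEFAULT_KERNEL,
    lam: float = 1e-5,
) -> GrappaWeights:
    """Fit GRAPPA weights on a fully sampled calibration k-space.

    Solves the ridge-regularized least squares ``min ||S w - t||^2 +
    lam*tr(S^H S)/n * ||w||^2`` for each gap offset, with all coils and a
    ``kernel = (source lines, source columns)`` neighbourhood as sources.
    """
    n_coils, ny, nx = acs.shape
    n_ky, n_kx = kernel
    if R == 1:
        return GrappaWeights(kernel=kernel, weights={}, R=1, n_coils=n_coils)
    span = (n_ky - 1) * R + 1
    if ny < span:
        raise ValueError(
            f"ACS height {ny} smaller than kernel span {span} at R={R}"
        )
    quality = n_coils < R
    w = GrappaWeights(
        kernel=kernel, weights={}, R=R, n_coils=n_coils, quality_flag=quality
    )
    ky_offsets = w.ky_offsets
    kx_off = w.kx_offsets
    for d in range(1, R):
        ky_off = ky_offsets[d]
        lo = int(-ky_off.min())
        hi = int(ny - ky_off.max())
        targets_y = np.arange(lo, hi)
        if targets_y.size == 0:
            raise ValueError("ACS region too small for the kernel geometry")
        S = _gather_sources(acs, targets_y, ky_off, kx_off)
        t = acs[:, targets_y, :].transpose(1, 2, 0).reshape(-1, n_coils)
        A = S.conj().T @ S
        scale = np.trace(A).real / A.shape[0]
        if lam == 0:
            cond = np.linalg.cond(A)
            if cond > 1e12:
                raise np.linalg.LinAlgError(
                    "singular GRAPPA normal equations; use lam > 0"
                )
            w.weights[d] = np.linalg.solve(A, S.conj().T @ t)
        else:
            A = A + lam * scale * np.eye(A.shape[0])
            w.weights[d] = np.linalg.solve(A, S.conj().T @ t)
    return w


def apply_grappa(k: KSpaceData, w: GrappaWeights) -> np.ndarray:
    """Synthesize missing phase-encode lines; sampled lines pass through."""
    if w.R != k.R:
        raise ValueError(f"weights fitted at R={w.R}, data has R={k.R}")
    full = k.data.copy()
    if w.R == 1 or k.mask.all():
        return full
    n_coils, ny, nx = full.shape
    offset0 = k.rep_index % k.R
    ky_offsets = w.ky_offsets
    kx_off = w.kx_offsets
    all_y = np.arange(ny)
    for d in range(1, w.R):
        targets_y = all_y[(all_y - offset0) % w.R == d % w.R]
        if targets_y.size == 0:
            continue
        S = _gather_sources(full, targets_y, ky_offsets[d], kx_off)
        t = S @ w.weights[d]  # (n_t*nx, n_coils)
        full[:, targets_y, :] = t.reshape(
            targets_y.size, nx, n_coils
        ).transpose(2, 0, 1)
    return full


def _sens_combine(
    imgs: np.ndarray, maps: np.ndarray, rss_threshold: float
) -> np.ndarray:
    """Sensitivity-weighted combine ``sum(c* I) / sum(|c|^2)`` with RSS fallback."""
    rss2 = np.sum(np.abs(maps) ** 2, axis=0)
    num = np.sum(np.conj(maps) * imgs, axis=0)
    rss = np.sqrt(rss2)
    inside = rss >= rss_threshold * rss.max()
    combined = np.zeros_like(num)
    combined[inside] = num[inside] / rss2[inside]
    mag = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    combined[~inside] = mag[~inside]
    return combined


def coil_combine(
    kfull: np.ndarray, coils: CoilMaps, rss_threshold: float = 0.05
) -> np.ndarray:
    """Inverse FFT per coil and sensitivity-weighted combination.

    Inside coil support the combine is ``sum(c* I) / sum(|c|^2)``; where the
    root-sum-of-squares sensitivity falls below ``rss_threshold`` times its
    maximum the phase is undefined and the RSS magnitude is returned instead.
    """
    if kfull.shape != coils.maps.shape:
        raise ValueError(
            f"k-space grid {kfull.shape} does not match coil grid "
            f"{coils.maps.shape}"
        )
    return _sens_combine(ifft2c(kfull), coils.maps, rss_threshold)


def partition_fov_multicoil(
    kfull: np.ndarray,
    coils: CoilMaps,
    params: ProtocolParams,
    rss_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Partition per-coil composite images, combining each band with the
    correspondingly shifted sensitivities.

    The half-FOV-shifted slice is weighted by circularly shifted coil maps in
    the composite frame, so its band must be combined with the shifted maps —
    combining the composite first and cropping after would scale that band by
    ``sum(c*(y) c(y - N/2)) / sum |c(y)|^2``.
    """
    if kfull.shape != coils.maps.shape:
        raise ValueError(
            f"k-space grid {kfull.shape} does not match coil grid "
            f"{coils.maps.shape}"
        )
    ny, nx = params.matrix
    ny_ext = kfull.shape[1]
    imgs = ifft2c(kfull)
    y0 = (ny_ext - ny) // 2
    band = slice(y0, y0 + ny)
    slice_a = _sens_combine(
        imgs[:, band], coils.maps[:, band], rss_threshold
    )
    if params.multiband == 1:
        return slice_a, None
    if ny_ext != 2 * ny:
        raise ValueError(
            f"multiband 2 requires ny_ext = 2*ny, got ny_ext={ny_ext}, ny={ny}"
        )
    # rolling the shifted replica back to the central band restores the
    # original (unshifted) coil weighting it was encoded with
    imgs_b = np.roll(imgs, -ny_ext // 2, axis=1)[:, band]
    slice_b = _sens_combine(imgs_b, coils.maps[:, band], rss_threshold)
    return slice_a, slice_b


def partition_fov(
    composite: np.ndarray, params: ProtocolParams
) -> tuple[np.ndarray, np.ndarray | None]:
    """Split the extended-FOV composite into the two encoded slices.

    Slice A occupies the central prescribed-FOV band; slice B is the band
    circularly shifted by half the extended FOV. For multiband 1 the central
    crop (to the prescribed FOV) is returned with ``None`` as the second
    slice.
    """
    ny, nx = params.matrix
    ny_ext = composite.shape[0]
    if composite.shape[1] != nx:
        raise ValueError(
            f"composite readout size {composite.shape[1]} != matrix nx {nx}"
        )
    y0 = (ny_ext - ny) // 2
    slice_a = composite[y0 : y0 + ny].copy()
    if params.multiband == 1:
        return slice_a, None
    if ny_ext != 2 * ny:
        raise ValueError(
            f"multiband 2 requires ny_ext = 2*ny, got ny_ext={ny_ext}, "
            f"ny={ny}"
        )
    slice_b = np.roll(composite, -ny_ext // 2, axis=0)[y0 : y0 + ny].copy()
    return slice_a, slice_b


def psir(
    ir_img: np.ndarray,
    ref_img: np.ndarray,
    background_threshold: float = 1e-3,
) -> PsirImage:
    """Restore the sign of the IR image from the reference shot's phase.

    ``values = |ir| * sign(cos(angle(ir) - angle(ref)))``; where the
    reference magnitude is below ``background_threshold`` times its maximum
    the sign is forced positive (air has no meaningful phase).
    """
    if ir_img.shape != ref_img.shape:
        raise ValueError(
            f"grid mismatch: ir {ir_img.shape} vs ref {ref_img.shape}"
        )
    ref_mag = np.abs(ref_img)
    background = ref_mag < background_threshold * ref_mag.max()
    sign = np.sign(np.cos(np.angle(ir_img) - np.angle(ref_img)))
    sign[sign == 0] = 1.0
    sign[background] = 1.0
    return PsirImage(values=np.abs(ir_img) * sign)


def reconstruct_shot(
    k: KSpaceData,
    weights: GrappaWeights,
    coils: CoilMaps,
    params: ProtocolParams,
) -> tuple[np.ndarray, np.ndarray | None]:
    """GRAPPA-fill, combine and partition one repetition's k-space."""
    full = apply_grappa(k, weights)
    return partition_fov_multicoil(full, coils, params)
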