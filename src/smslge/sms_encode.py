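"""SMS-CAIPIRINHA bSSFP encoding of slice pairs into composite k-space.

Two simultaneously excited slices are distributed across a doubled
phase-encode field of view by slice-specific RF phase cycling: the second
slice's k-space lines carry a relative phase of pi per phase-encode line,
which in image space is a circular shift by half the extended FOV. The
composite is then undersampled with an interleaved (time-shifted) Cartesian
pattern so that consecutive repetitions sample complementary line sets.

Centered FFT convention: DC at the array centre; phase-encode line index m
counts from the top of the extended FOV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import CoilMaps

__all__ = [
    "ProtocolParams",
    "KSpaceData",
    "slice_pairing",
    "sampling_mask",
    "encode_sms",
    "add_noise",
    "fft2c",
    "ifft2c",
    "extended_ny",
    "embed_fov",
]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered 2D FFT over the last two axes (orthonormal)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered 2D inverse FFT over the last two axes (orthonormal)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


@dataclass(frozen=True)
class ProtocolParams:
    """Acquisition prescription for one arm of the experiment.

    ``inplane_accel`` is the overall prescribed in-plane acceleration R on
    the extended grid; the nominal (effective) in-plane factor is
    ``R / phase_oversampling``.
    """

    n_slices: int = 16
    multiband: int = 2
    n_reps: int = 8
    rr_per_image: int = 2
    inplane_accel: int = 5
    phase_oversampling: float = 2.0
    matrix: tuple[int, int] = (64, 64)
    fov: tuple[float, float] = (380.0, 380.0)
    tr: float = 2.71
    te: float = 1.15
    flip: float = 45.0
    ti: float = 450.0 * float(np.log(2.0))
    slice_thickness: float = 8.0

    def __post_init__(self) -> None:
        if self.multiband not in (1, 2):
            raise ValueError(f"multiband must be 1 or 2, got {self.multiband}")
        if self.n_slices % self.multiband != 0:
            raise ValueError(
                f"n_slices={self.n_slices} not divisible by multiband="
                f"{self.multiband}"
            )
        if self.inplane_accel < 1:
            raise ValueError("inplane_accel must be >= 1")
        if self.phase_oversampling < 1:
            raise ValueError("phase_oversampling must be >= 1")

    @property
    def ny_ext(self) -> int:
        return extended_ny(self.matrix[0], self.phase_oversampling)


def extended_ny(ny: int, phase_oversampling: float) -> int:
    """Extended phase-encode size: ``round(ny * oversampling)``, forced even."""
    n = int(round(ny * phase_oversampling))
    return n + (n % 2)


@dataclass
class KSpaceData:
    """One repetition of undersampled multi-coil composite k-space."""

    data: np.ndarray  # (n_coils, ny_ext, nx) complex; zero on unsampled lines
    mask: np.ndarray  # (ny_ext,) bool
    rep_index: int
    R: int
    caipi: dict = field(
        default_factory=lambda: {
            "phase_increment_slice1": np.pi / 2,
            "phase_increment_slice2": -np.pi / 2,
        }
    )

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def ny_ext(self) -> int:
        return self.data.shape[1]

    @property
    def pe_shift_pattern(self) -> int:
        return self.rep_index % self.R


def slice_pairing(n_slices: int, multiband: int) -> list[tuple[int, ...]]:
    """Group slices for simultaneous excitation (0-based indices).

    For multiband 2 the pairs are ``(i, i + n_slices/2)`` — maximal slice gap,
    e.g. 16 slices give 1-9, 2-10, ..., 8-16 in 1-based labels.
    """
    if multiband < 1:
        raise ValueError("multiband must be >= 1")
    if n_slices % multiband != 0:
        raise ValueError(
            f"n_slices={n_slices} not divisible by multiband={multiband}"
        )
    if multiband == 1:
        return [(i,) for i in range(n_slices)]
    half = n_slices // 2
    return [(i, i + half) for i in range(half)]


def sampling_mask(ny_ext: int, R: int, rep_index: int) -> np.ndarray:
    """Interleaved Cartesian mask: lines ``m ≡ rep_index (mod R)`` sampled."""
    if R < 1:
        raise ValueError("R must be >= 1")
    m = np.arange(ny_ext)
    return (m % R) == (rep_index % R)


def embed_fov(img: np.ndarray, ny_ext: int) -> np.ndarray:
    """Zero-pad an (ny, nx) image symmetrically into the extended PE grid."""
    ny, nx = img.shape
    if ny_ext < ny:
        raise ValueError(f"ny_ext={ny_ext} smaller than image ny={ny}")
    out = np.zeros((ny_ext, nx), dtype=np.complex128)
    y0 = (ny_ext - ny) // 2
    out[y0 : y0 + ny] = img
    return out


def encode_sms(
    img1: np.ndarray,
    img2: np.ndarray | None,
    coils: CoilMaps,
    params: ProtocolParams,
    rep_index: int = 0,
) -> KSpaceData:
    """Encode one (or a pair of) slice image(s) into composite k-space.

    Each image is placed in the extended FOV, weighted by the coil maps and
    Fourier transformed. Slice 2's lines are modulated by ``exp(i*pi*m)``
    (the difference of the +pi/2 / -pi/2 per-line RF increments), shifting it
    by ``ny_ext/2`` rows in the composite image. Only phase-encode lines with
    ``m ≡ rep_index (mod R)`` are retained.
    """
    ny, nx = params.matrix
    ny_ext = params.ny_ext
    for name, img in (("img1", img1), ("img2", img2)):
        if img is not None and img.shape != (ny, nx):
            raise ValueError(
                f"{name} grid {img.shape} does not match prescribed matrix "
                f"{(ny, nx)}"
            )
    if coils.maps.shape[1:] != (ny_ext, nx):
        raise ValueError(
            f"coil grid {coils.maps.shape[1:]} does not match extended grid "
            f"{(ny_ext, nx)}"
        )
    k = coils.maps * embed_fov(img1, ny_ext)[None]
    k = fft2c(k)
    if img2 is not None:
        k2 = fft2c(coils.maps * embed_fov(img2, ny_ext)[None])
        m = np.arange(ny_ext)
        k = k + k2 * np.exp(1j * np.pi * m)[None, :, None]
    mask = sampling_mask(ny_ext, params.inplane_accel, rep_index)
    k[:, ~mask, :] = 0.0
    return KSpaceData(
        data=k, mask=mask, rep_index=rep_index, R=params.inplane_accel
    )


def add_noise(k: KSpaceData, sigma: float, seed: int = 0) -> KSpaceData:
    """Add iid complex Gaussian noise (SD *sigma* per component) to sampled lines."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return KSpaceData(
            data=k.data.copy(),
            mask=k.mask.copy(),
            rep_index=k.rep_index,
            R=k.R,
            caipi=dict(k.caipi),
        )
    rng = np.random.default_rng(seed)
    data = k.data.copy()
    shape = data[:, k.mask, :].shape
    noise = rng.normal(0, sigma, shape) + 1j * rng.normal(0, sigma, shape)
    data[:, k.mask, :] += noise
    return KSpaceData(
        data=data,
        mask=k.mask.copy(),
        rep_index=k.rep_index,
        R=k.R,
        caipi=dict(k.caipi),
    )
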