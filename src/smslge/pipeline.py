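"""End-to-end experiments: phantom -> encode -> recon -> moco -> metrics.

Runs the accelerated multiband arm and the single-band reference arm on the
same phantom and motion trace (paired design) and reports per-arm metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import metrics as met
from . import moco as mc
from . import recon as rc
from .phantom import (
    LABEL_BLOOD,
    LABEL_MYOCARDIUM,
    LABEL_SCAR,
    CoilMaps,
    MotionState,
    PhantomConfig,
    PhantomStack,
    make_coil_maps,
    make_phantom,
    motion_trace,
    render_single_shot,
)
from .sms_encode import (
    KSpaceData,
    ProtocolParams,
    add_noise,
    encode_sms,
    slice_pairing,
)

__all__ = [
    "ExperimentConfig",
    "ArmResult",
    "default_sms_protocol",
    "default_reference_protocol",
    "simulate_arm",
    "run_experiment",
    "config_from_dict",
]


def default_sms_protocol(
    n_slices: int = 2, matrix: tuple[int, int] = (64, 64), n_reps: int = 8
) -> ProtocolParams:
    """Multiband-2 arm: overall in-plane R=5 on a doubled phase FOV."""
    return ProtocolParams(
        n_slices=n_slices,
        multiband=2,
        n_reps=n_reps,
        inplane_accel=5,
        phase_oversampling=2.0,
        matrix=matrix,
    )


def default_reference_protocol(
    n_slices: int = 2, matrix: tuple[int, int] = (64, 64), n_reps: int = 8
) -> ProtocolParams:
    """Single-band arm: R=3 with 1.2 phase oversampling, cropped after recon."""
    return ProtocolParams(
        n_slices=n_slices,
        multiband=1,
        n_reps=n_reps,
        inplane_accel=3,
        phase_oversampling=1.2,
        matrix=matrix,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration shared by both arms of a paired experiment."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    sms: ProtocolParams = field(default_factory=default_sms_protocol)
    reference: ProtocolParams = field(default_factory=default_reference_protocol)
    n_coils: int = 8
    noise_sigma: float = 0.002
    motion_amplitude: float = 0.75
    motion_outliers: tuple[int, ...] = (2, 5)
    motion_outlier_scale: float = 6.0
    deform_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        nominal_sms = self.sms.inplane_accel / self.sms.phase_oversampling
        nominal_ref = (
            self.reference.inplane_accel / self.reference.phase_oversampling
        )
        if abs(nominal_sms - nominal_ref) > 1e-9:
            raise ValueError(
                "paired design requires equal nominal in-plane acceleration "
                f"across arms, got {nominal_sms} vs {nominal_ref}"
            )


@dataclass
class ArmResult:
    """Images and metrics produced by one arm."""

    name: str
    final_psir: np.ndarray  # (n_slices, ny, nx)
    final_magnitude: np.ndarray  # (n_slices, ny, nx)
    selections: list[mc.SelectionResult]
    report: met.MetricsReport
    per_slice_scar_masks: np.ndarray  # (n_slices, ny, nx) bool


def _simulate_group_kspace(
    phantom: PhantomStack,
    group: tuple[int, ...],
    coils: CoilMaps,
    params: ProtocolParams,
    motions: list[MotionState],
    noise_sigma: float,
    seed: int,
) -> tuple[list[KSpaceData], list[KSpaceData]]:
    """Encode the IR and reference (no-inversion) shots of one slice group."""
    ir_reps: list[KSpaceData] = []
    ref_reps: list[KSpaceData] = []
    for rep in range(params.n_reps):
        motion = motions[rep]
        imgs_ir = [
            render_single_shot(phantom, s, params.ti, motion) for s in group
        ]
        imgs_ref = [
            render_single_shot(phantom, s, None, motion) for s in group
        ]
        img2_ir = imgs_ir[1] if len(group) == 2 else None
        img2_ref = imgs_ref[1] if len(group) == 2 else None
        k_ir = encode_sms(imgs_ir[0], img2_ir, coils, params, rep)
        k_ref = encode_sms(imgs_ref[0], img2_ref, coils, params, rep)
        ir_reps.append(add_noise(k_ir, noise_sigma, seed=seed + 2 * rep))
        ref_reps.append(
            add_noise(k_ref, noise_sigma, seed=seed + 2 * rep + 1)
        )
    return ir_reps, ref_reps


def _reconstruct_group(
    ir_reps: list[KSpaceData],
    ref_reps: list[KSpaceData],
    coils: CoilMaps,
    params: ProtocolParams,
    group: tuple[int, ...],
) -> dict[int, dict[str, list[np.ndarray]]]:
    """T-GRAPPA + PSIR reconstruction of one slice group's repetitions.

    Two calibration passes: the first merges all repetitions into the ACS;
    its reconstructions drive a centre-of-mass pre-selection whose retained
    (motion-consistent) repetitions rebuild the ACS for the final pass. If
    the retained repetitions do not cover every line offset the first-pass
    weights are kept.

    Returns per-slice lists of signed PSIR values and magnitude images.
    """

    def _recon_all(weights: rc.GrappaWeights) -> dict:
        res: dict[int, dict[str, list[np.ndarray]]] = {
            s: {"psir": [], "magnitude": []} for s in group
        }
        for k_ir, k_ref in zip(ir_reps, ref_reps):
            slices_ir = rc.reconstruct_shot(k_ir, weights, coils, params)
            slices_ref = rc.reconstruct_shot(k_ref, weights, coils, params)
            for pos, s in enumerate(group):
                res[s]["psir"].append(
                    rc.psir(slices_ir[pos], slices_ref[pos]).values
                )
                res[s]["magnitude"].append(np.abs(slices_ir[pos]))
        return res

    weights1 = rc.calibrate_grappa(
        rc.build_acs(ir_reps), params.inplane_accel
    )
    out = _recon_all(weights1)
    if params.inplane_accel == 1 or len(ir_reps) < 3:
        return out
    # motion-consistent recalibration driven by the first slice's CoMs
    # (the slice pair shares one motion state per repetition)
    coms = [mc.center_of_mass(m) for m in out[group[0]]["magnitude"]]
    sel = mc.select_images(coms, n_keep=min(6, len(ir_reps) - 2))
    try:
        acs2 = rc.build_acs([ir_reps[i] for i in sel.retained])
    except ValueError:
        return out  # retained repetitions miss a line offset; keep pass 1
    weights2 = rc.calibrate_grappa(acs2, params.inplane_accel)
    return _recon_all(weights2)


def _aligned_labels(
    phantom: PhantomStack,
    slice_idx: int,
    final_mag: np.ndarray,
    ti: float,
) -> np.ndarray:
    """Shift the ground-truth label map onto the final image's motion state.

    The motion-corrected average sits in the reference repetition's frame,
    not the phantom's; a phase-correlation shift of the clean render (at the
    acquisition TI, so contrasts match) onto the final magnitude stands in
    for drawing ROIs on the image itself.
    """
    from skimage.registration import phase_cross_correlation

    clean = np.abs(
        render_single_shot(phantom, slice_idx, ti, MotionState())
    )
    shift, _, _ = phase_cross_correlation(
        final_mag, clean, upsample_factor=10, normalization=None
    )
    labels = phantom.labels[slice_idx]
    shifted = ndimage.shift(
        labels.astype(float), shift, order=0, mode="constant", cval=0
    )
    return shifted.astype(labels.dtype)


def _slice_metrics(
    phantom: PhantomStack,
    slice_idx: int,
    final_psir: np.ndarray,
    final_mag: np.ndarray,
    warped_last_two: tuple[np.ndarray, np.ndarray],
    ti: float,
) -> dict:
    """Per-slice sharpness, Ne, CNRe and scar segmentation."""
    labels = _aligned_labels(phantom, slice_idx, final_mag, ti)
    rois = met.roi_set_from_labels(
        labels, LABEL_BLOOD, LABEL_MYOCARDIUM, LABEL_SCAR
    )
    spacing = float(np.mean(phantom.pixel_spacing))
    curves = met.interface_curves_from_labels(
        labels, LABEL_BLOOD, LABEL_MYOCARDIUM, pixel_spacing=spacing
    )
    try:
        sharp, _ = met.sharpness_index(final_psir, curves)
    except ValueError:
        sharp = float("nan")
    ne = met.noise_estimate(
        warped_last_two[0], warped_last_two[1], rois.blood
    )
    result = {
        "sharpness": sharp,
        "ne": ne,
        "cnre_blood_myo": met.cnre(final_psir, rois.blood, rois.myocardium, ne)
        if ne > 0
        else float("nan"),
    }
    if rois.scar is not None:
        result["cnre_scar_myo"] = (
            met.cnre(final_psir, rois.scar, rois.myocardium, ne)
            if ne > 0
            else float("nan")
        )
        result["cnre_scar_blood"] = (
            met.cnre(final_psir, rois.scar, rois.blood, ne)
            if ne > 0
            else float("nan")
        )
    # scar segmentation region: aligned myocardium+scar with a 1-px margin,
    # excluding the (bright) blood pool
    region = (labels == LABEL_MYOCARDIUM) | (labels == LABEL_SCAR)
    region = ndimage.binary_dilation(region, iterations=1)
    region &= labels != LABEL_BLOOD
    has_scar = bool(phantom.scar_mask[slice_idx].any())
    result["scar_mask"] = (
        met.segment_scar(final_psir, region)
        if has_scar
        else np.zeros_like(region, dtype=bool)
    )
    return result


def simulate_arm(
    name: str,
    phantom: PhantomStack,
    params: ProtocolParams,
    coils: CoilMaps,
    motions: list[MotionState],
    noise_sigma: float,
    seed: int,
    reg_config: mc.RegistrationConfig = mc.RegistrationConfig(),
) -> ArmResult:
    """Simulate, reconstruct, motion-correct and evaluate one protocol arm."""
    ny, nx = params.matrix
    n_slices = phantom.n_slices
    final_psir = np.zeros((n_slices, ny, nx))
    final_mag = np.zeros((n_slices, ny, nx))
    scar_masks = np.zeros((n_slices, ny, nx), dtype=bool)
    selections: list[mc.SelectionResult] = []
    per_slice: list[dict] = []
    groups = slice_pairing(n_slices, params.multiband)
    for gi, group in enumerate(groups):
        ir_reps, ref_reps = _simulate_group_kspace(
            phantom, group, coils, params, motions, noise_sigma,
            seed=seed + 10_000 * gi,
        )
        recon_out = _reconstruct_group(ir_reps, ref_reps, coils, params, group)
        for s in group:
            psir_series = recon_out[s]["psir"]
            mag_series = recon_out[s]["magnitude"]
            final, sel, fields = mc.moco_average(
                psir_series, mag_series, config=reg_config
            )
            selections.append(sel)
            final_psir[s] = final
            final_mag[s] = np.abs(final)
            # the two last motion-corrected repetitions, before averaging
            last_two = sorted(sel.retained)[-2:]
            warped = {
                i: mc.warp(psir_series[i], fields[sel.retained.index(i)])
                for i in last_two
            }
            sm = _slice_metrics(
                phantom,
                s,
                final,
                np.abs(final),
                (warped[last_two[0]], warped[last_two[1]]),
                params.ti,
            )
            scar_masks[s] = sm.pop("scar_mask")
            per_slice.append(sm)
    report = met.MetricsReport()
    report.sharpness_per_slice = [d["sharpness"] for d in per_slice]
    valid = [v for v in report.sharpness_per_slice if np.isfinite(v)]
    report.sharpness_subject = float(np.mean(valid)) if valid else float("nan")
    report.ne = float(np.mean([d["ne"] for d in per_slice]))
    report.cnre_blood_myo = float(
        np.mean([d["cnre_blood_myo"] for d in per_slice])
    )
    scar_slices = [d for d in per_slice if "cnre_scar_myo" in d]
    if scar_slices:
        report.cnre_scar_myo = float(
            np.mean([d["cnre_scar_myo"] for d in scar_slices])
        )
        report.cnre_scar_blood = float(
            np.mean([d["cnre_scar_blood"] for d in scar_slices])
        )
    report.scar_volume_ml = met.scar_volume(
        scar_masks, phantom.pixel_area_mm2, phantom.slice_thickness
    )
    heartbeats, nominal, total, _ = met.protocol_counts(params)
    report.heartbeats = heartbeats
    report.accel_nominal_inplane = nominal
    report.accel_total = total
    return ArmResult(
        name=name,
        final_psir=final_psir,
        final_magnitude=final_mag,
        selections=selections,
        report=report,
        per_slice_scar_masks=scar_masks,
    )


def run_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> dict[str, ArmResult]:
    """Run both arms on a shared phantom/motion trace; optionally write files."""
    phantom = make_phantom(config.phantom, seed=config.seed)
    motions = motion_trace(
        n_reps=config.sms.n_reps,
        amplitude=config.motion_amplitude,
        outlier_indices=set(config.motion_outliers),
        outlier_scale=config.motion_outlier_scale,
        seed=config.seed + 1,
        deform_amplitude=config.deform_amplitude,
    )
    results: dict[str, ArmResult] = {}
    for name, params, sub_seed in (
        ("sms", config.sms, 100),
        ("reference", config.reference, 200),
    ):
        coils = make_coil_maps(
            config.n_coils, (params.ny_ext, params.matrix[1]),
            seed=config.seed + 2,
        )
        results[name] = simulate_arm(
            name,
            phantom,
            params,
            coils,
            motions,
            config.noise_sigma,
            seed=config.seed + sub_seed,
        )
    if outdir is not None:
        _write_outputs(Path(outdir), config, phantom, results)
    return results


def _write_outputs(
    outdir: Path,
    config: ExperimentConfig,
    phantom: PhantomStack,
    results: dict[str, ArmResult],
) -> None:
    from .io import save_json, save_nifti

    outdir.mkdir(parents=True, exist_ok=True)
    comparison: dict[str, dict] = {"schema_version": 1}  # type: ignore[dict-item]
    for name, arm in results.items():
        save_nifti(
            outdir / f"{name}_psir.nii.gz",
            arm.final_psir,
            phantom.pixel_spacing,
            phantom.slice_thickness,
        )
        save_nifti(
            outdir / f"{name}_magnitude.nii.gz",
            arm.final_magnitude,
            phantom.pixel_spacing,
            phantom.slice_thickness,
        )
        payload = arm.report.to_dict()
        payload["selections"] = [
            {
                "retained": sel.retained,
                "discarded": sel.discarded,
                "refined_mean": list(sel.refined_mean),
            }
            for sel in arm.selections
        ]
        save_json(outdir / f"{name}_report.json", payload)
        comparison[name] = arm.report.to_dict()
    comparison["ground_truth_scar_volume_mL"] = phantom.scar_volume_ml()
    save_json(outdir / "comparison.json", comparison)


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a (YAML-loaded) mapping."""
    raw = dict(raw)
    phantom_cfg = PhantomConfig(**_tupled(raw.pop("phantom", {})))
    sms_kwargs = _tupled(raw.pop("sms", {}))
    ref_kwargs = _tupled(raw.pop("reference", {}))
    sms = (
        ProtocolParams(**{**_protocol_defaults(default_sms_protocol()), **sms_kwargs})
        if sms_kwargs
        else default_sms_protocol(n_slices=phantom_cfg.n_slices,
                                  matrix=phantom_cfg.matrix)
    )
    ref = (
        ProtocolParams(
            **{**_protocol_defaults(default_reference_protocol()), **ref_kwargs}
        )
        if ref_kwargs
        else default_reference_protocol(n_slices=phantom_cfg.n_slices,
                                        matrix=phantom_cfg.matrix)
    )
    if "motion_outliers" in raw:
        raw["motion_outliers"] = tuple(raw["motion_outliers"])
    return ExperimentConfig(phantom=phantom_cfg, sms=sms, reference=ref, **raw)


def _protocol_defaults(p: ProtocolParams) -> dict:
    return asdict(p)


def _tupled(d: dict) -> dict:
    """YAML gives lists; dataclass fields expect tuples for fixed pairs."""
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out
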