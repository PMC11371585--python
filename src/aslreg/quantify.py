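"""pCASL CBF quantification: motion correction, control−label subtraction,
single-compartment kinetic model, and time-series averaging.

The kinetic model is the standard single-compartment pCASL closed form
(consensus white-paper model):

    CBF = 6000 · λ · ΔM · exp(PLD / T1b)
          ─────────────────────────────────────────────
          2 · α · T1b · M0 · (1 − exp(−τ / T1b))

in mL/100g/min, with λ the blood–brain partition coefficient (mL/g),
α the labeling efficiency, τ the labeling duration (s), PLD the
post-labeling delay (s), and T1b the longitudinal relaxation time of
arterial blood (s). Quantification is linear in ΔM and inverse-linear
in M0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .transforms import RigidTransform, resample_volume, transform_residual
from .volume import Volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcquisitionParams:
    """pCASL kinetic-model constants.

    tau : labeling duration, s (default 1.8)
    pld : post-labeling delay, s (default 1.8)
    alpha : labeling efficiency, dimensionless in (0, 1] (default 0.72)
    t1_blood : arterial blood T1, s (default 1.65)
    lambda_partition : blood–brain partition coefficient, mL/g (default 0.9)
    """

    tau: float = 1.8
    pld: float = 1.8
    alpha: float = 0.72
    t1_blood: float = 1.65
    lambda_partition: float = 0.9

    def __post_init__(self) -> None:
        for name in ("tau", "pld", "alpha", "t1_blood", "lambda_partition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha > 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class CBFMap:
    """Mean CBF volume (mL/100g/min) with provenance."""

    volume: Volume
    params_used: AcquisitionParams
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def kinetic_scale(params: AcquisitionParams) -> float:
    """Factor k with CBF = k · ΔM / M0 (closed form above)."""
    t1b = params.t1_blood
    return (
        6000.0
        * params.lambda_partition
        * np.exp(params.pld / t1b)
        / (2.0 * params.alpha * t1b * (1.0 - np.exp(-params.tau / t1b)))
    )


def quantify_cbf(
    delta_m: Volume,
    m0: Volume,
    params: AcquisitionParams,
    m0_threshold_frac: float = 0.1,
) -> Volume:
    """Voxelwise kinetic-model CBF from a ΔM and M0 pair.

    Voxels with M0 at or below ``m0_threshold_frac`` of the M0 maximum are
    undefined — dividing by near-zero M0 at the brain edge amplifies noise
    into arbitrarily large CBF — and are set to 0 (the implicit brain mask
    downstream). M0 must be positive somewhere.
    """
    if not delta_m.same_grid(m0):
        raise ValueError("delta_m and m0 grids do not match")
    m0_max = m0.data.max()
    if m0_max <= 0:
        raise ValueError("M0 has no positive voxels")
    k = kinetic_scale(params)
    valid = m0.data > m0_threshold_frac * m0_max
    cbf = np.zeros_like(delta_m.data)
    cbf[valid] = k * delta_m.data[valid] / m0.data[valid]
    return Volume(cbf, delta_m.affine.copy())


def subtract_pairs(series: list[Volume], control_first: bool = True) -> list[Volume]:
    """Pairwise ΔM = control − label volumes from an interleaved series.

    The interleaving order is an acquisition-manifest fact, not an
    assumption: ``control_first=True`` means even indices are controls.
    """
    if len(series) % 2 != 0:
        raise ValueError(f"series length {len(series)} is odd; need control/label pairs")
    out = []
    for i in range(0, len(series), 2):
        a, b = series[i], series[i + 1]
        if not a.same_grid(b):
            raise ValueError(f"volumes {i} and {i + 1} are on different grids")
        control, label = (a, b) if control_first else (b, a)
        out.append(Volume(control.data - label.data, control.affine.copy()))
    return out


def mean_cbf(cbf_series: list[Volume], params: AcquisitionParams | None = None) -> CBFMap:
    """Voxelwise arithmetic mean of the CBF time series."""
    if not cbf_series:
        raise ValueError("cannot average an empty CBF series")
    first = cbf_series[0]
    for v in cbf_series[1:]:
        if not v.same_grid(first):
            raise ValueError("CBF series volumes are on different grids")
    mean = np.mean([v.data for v in cbf_series], axis=0)
    return CBFMap(
        Volume(mean, first.affine.copy()),
        params if params is not None else AcquisitionParams(),
        n_pairs=len(cbf_series),
    )


def quantify_series(
    series: list[Volume],
    m0: Volume,
    params: AcquisitionParams,
    control_first: bool = True,
) -> CBFMap:
    """Subtract pairs, quantify each ΔM, and average — the §quantification
    path applied to a full label/control series."""
    deltas = subtract_pairs(series, control_first=control_first)
    cbf = [quantify_cbf(d, m0, params) for d in deltas]
    return mean_cbf(cbf, params)


def motion_correct(
    series: list[Volume],
    reference_index: int = 0,
    max_displacement_fraction: float = 0.5,
    reg_config=None,
) -> tuple[list[Volume], list[RigidTransform]]:
    """Rigidly align every volume of a series to a reference volume.

    Runs the intensity-based 6-DOF engine per volume (head-motion model);
    each volume is resampled ONCE with trilinear interpolation. A volume
    whose registration fails (cost not reduced and displacement beyond
    ``max_displacement_fraction`` of the field of view) is dropped with a
    log entry; its transform slot is still reported.
    """
    from .registration import RigidRegConfig, rigid_register

    if len(series) < 2:
        raise ValueError("motion correction needs at least 2 volumes")
    ref = series[reference_index]
    for v in series:
        if not v.same_grid(ref):
            raise ValueError("motion correction requires a common grid")
    if reg_config is None:
        reg_config = RigidRegConfig(pyramid_factors=(2, 1))
    fov = np.max(np.asarray(ref.shape) * ref.spacing)
    corrected: list[Volume] = []
    transforms: list[RigidTransform] = []
    for i, vol in enumerate(series):
        if i == reference_index:
            corrected.append(vol.copy())
            transforms.append(RigidTransform.identity())
            continue
        res = rigid_register(vol, ref, config=reg_config)
        transforms.append(res.transform)
        disp, _ = transform_residual(RigidTransform.identity(), res.transform)
        if (not res.converged) and disp > max_displacement_fraction * fov:
            logger.warning("volume %d dropped: motion registration failed", i)
            continue
        corrected.append(resample_volume(vol, res.transform, ref))
    return corrected, transforms
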