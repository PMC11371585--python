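"""Synthetic cohort generation: pCASL acquisition forward model, per-
participant ground-truth rigid transforms, group hypoperfusion effects, and
a severity covariate linearly coupled to CBF in designated ROIs.

The forward acquisition model is the exact inverse of the kinetic
quantification: ΔM = CBF · M0 / k with k the kinetic scale factor, so a
zero-noise acquisition followed by quantification is the identity on the
CBF map. A radial-sinusoid "ringing" artifact multiplies the static
(M0-like) component of each raw volume; because both volumes of a
label-control pair share the artifact, it cancels exactly in the
control − label subtraction, as spiral-readout artifacts do in practice.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .phantom import PhantomSpec, baseline_cbf_map, generate_phantom, tissue_label_map
from .quantify import AcquisitionParams, CBFMap, kinetic_scale
from .surface import GM_LABEL, BoundarySurface, Parcellation, build_parcellation
from .transforms import AffineTransform, RigidTransform, resample_volume
from .volume import Volume

logger = logging.getLogger(__name__)

# M0 (proton-density-like) intensities per tissue class
M0_INTENSITIES = {"csf": 1000.0, "gm": 900.0, "wm": 800.0}

N_PAIRS_DEFAULT = 14  # label-control pairs per acquisition (28 volumes)


@dataclass
class GroupEffectSpec:
    """Regional effect model of one diagnostic group.

    ``cbf_reduction_fraction`` scales GM CBF multiplicatively in
    ``affected_rois``; ``atrophy_thinning_mm`` thins the cortical ribbon;
    ``severity_slope`` (mL/100g/min per severity unit, <= 0 for an inverse
    association) couples a clinical-severity score to affected-ROI CBF.
    Controls carry no effect and severity fixed at 0.
    """

    group: str
    affected_rois: tuple[int, ...] = ()
    cbf_reduction_fraction: float = 0.0
    atrophy_thinning_mm: float = 0.0
    severity_slope: float = 0.0
    severity_noise_sd: float = 0.0
    severity_mean: float = 6.5
    severity_sd: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.cbf_reduction_fraction < 1.0:
            raise ValueError("cbf_reduction_fraction must lie in [0, 1)")
        if self.atrophy_thinning_mm < 0:
            raise ValueError("atrophy_thinning_mm must be >= 0")
        if self.group == "control" and (
            self.affected_rois or self.cbf_reduction_fraction or self.severity_slope
        ):
            raise ValueError("controls must carry no regional effect")


@dataclass
class GroundTruth:
    """Everything known by construction about one phantom participant."""

    true_transform: RigidTransform
    true_cbf_map: Volume
    roi_effect_table: dict[int, float]
    severity: float

    def __post_init__(self) -> None:
        if np.any(self.true_cbf_map.data < 0):
            raise ValueError("true CBF map must be nonnegative")


@dataclass
class ASLAcquisition:
    """One simulated pCASL session: interleaved raw series plus M0."""

    series: list[Volume]
    m0: Volume
    true_cbf_asl: Volume  # ground-truth CBF resampled to the acquisition grid
    control_first: bool = True

    @property
    def n_pairs(self) -> int:
        return len(self.series) // 2


@dataclass
class CohortRecord:
    """One participant, filled in progressively by the pipeline stages."""

    participant_id: str
    group: str
    ground_truth: GroundTruth
    structural: Volume
    tissue_labels: Volume
    acquisition: ASLAcquisition | None = None
    age: float = float("nan")
    sex: str = ""
    # pipeline outputs, keyed by registration-method label
    cbf_map: CBFMap | None = None
    transforms: dict[str, AffineTransform] = field(default_factory=dict)
    roi_means: dict[str, pd.DataFrame] = field(default_factory=dict)
    roi_volumes: pd.DataFrame | None = None
    qei: float = float("nan")
    registration_failed: bool = False

    @property
    def severity(self) -> float:
        return self.ground_truth.severity


def generate_asl_series(
    tissue_labels: Volume,
    true_cbf_map: Volume,
    params: AcquisitionParams,
    spec: PhantomSpec,
    true_transform: RigidTransform | None = None,
    n_pairs: int = N_PAIRS_DEFAULT,
    rng: np.random.Generator | None = None,
) -> ASLAcquisition:
    """Forward-simulate an interleaved control/label pCASL series plus M0.

    The structural-space M0 and true-CBF maps are resampled onto the ASL
    grid through the inverse of the participant's true ASL→T1w transform
    (the acquisition happens in head/ASL space). Control volumes carry the
    ringing-modulated M0 signal; label volumes subtract the kinetic-model
    ΔM. Per-voxel Gaussian noise of ``spec.noise_sd`` is added to every raw
    volume; the returned M0 is noise-free.
    """
    if not tissue_labels.same_grid(true_cbf_map):
        raise ValueError("tissue_labels and true_cbf_map grids do not match")
    if true_transform is None:
        true_transform = RigidTransform.identity()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    m0_struct = np.zeros(tissue_labels.shape)
    for tissue, label in (("csf", 1), ("gm", GM_LABEL), ("wm", 3)):
        m0_struct[tissue_labels.data == label] = M0_INTENSITIES[tissue]
    m0_struct_vol = Volume(m0_struct, tissue_labels.affine.copy())

    asl_grid = spec.asl_grid()
    # value_asl(x) = value_t1w(T(x)): pull the T1w-space truth back through T
    inv = true_transform.inverse()
    m0_asl = resample_volume(m0_struct_vol, inv, asl_grid)
    cbf_asl = resample_volume(true_cbf_map, inv, asl_grid)

    delta_m = cbf_asl.data * m0_asl.data / kinetic_scale(params)

    # radial coordinate for the ringing field (ASL world mm)
    radius = np.linalg.norm(asl_grid.world_grid(), axis=1).reshape(spec.asl_shape)
    wavelength = 30.0  # mm, a few voxels at acquisition resolution

    series: list[Volume] = []
    for _ in range(n_pairs):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ring = 1.0 + spec.ringing_amplitude * np.sin(
            2.0 * np.pi * radius / wavelength + phase
        )
        static = ring * m0_asl.data
        control = static + rng.normal(0.0, spec.noise_sd, spec.asl_shape) \
            if spec.noise_sd > 0 else static
        label = static - delta_m
        if spec.noise_sd > 0:
            label = label + rng.normal(0.0, spec.noise_sd, spec.asl_shape)
        series.append(Volume(control, asl_grid.affine.copy()))
        series.append(Volume(label, asl_grid.affine.copy()))
    return ASLAcquisition(series=series, m0=m0_asl, true_cbf_asl=cbf_asl)


def _apply_group_effects(
    base_cbf: Volume,
    tissue_labels: Volume,
    boundary: BoundarySurface,
    parcellation: Parcellation,
    effect: GroupEffectSpec,
    severity: float,
    gm_baseline: float,
    rng: np.random.Generator,
) -> tuple[Volume, dict[int, float]]:
    """Multiplicative ROI reduction plus centered severity coupling.

    Affected-parcel GM CBF becomes
        baseline(v) · (1 − reduction) + slope · (severity − severity_mean) + ε
    voxelwise (ε one draw per ROI), clipped at 0. Centering the severity
    term keeps the group-mean ROI effect at the nominal reduction fraction
    while inducing the linear CBF–severity association the regression
    stage estimates. The returned table records the REALIZED per-parcel
    reduction, 1 − mean_after / mean_before, so effect conservation holds
    by construction.
    """
    cbf = base_cbf.data.copy()
    table: dict[int, float] = {}
    if not effect.affected_rois:
        return Volume(cbf, base_cbf.affine.copy()), table
    bad = set(effect.affected_rois) - set(parcellation.parcel_ids.tolist())
    if bad:
        raise ValueError(f"affected_rois {sorted(bad)} not in the parcellation")
    gm = tissue_labels.data == GM_LABEL
    idx = np.argwhere(gm).astype(float)
    world = tissue_labels.voxel_to_world(idx)
    _, nearest = cKDTree(boundary.vertices).query(world)
    vox_parcel = parcellation.labels[nearest]
    gm_flat = np.flatnonzero(gm.ravel())
    flat = cbf.ravel()
    for parcel in effect.affected_rois:
        sel = gm_flat[vox_parcel == parcel]
        if len(sel) == 0:
            continue
        before = flat[sel]
        shift = effect.severity_slope * (severity - effect.severity_mean)
        if effect.severity_noise_sd > 0:
            shift += rng.normal(0.0, effect.severity_noise_sd)
        after = np.maximum(before * (1.0 - effect.cbf_reduction_fraction) + shift, 0.0)
        flat[sel] = after
        table[int(parcel)] = float(1.0 - after.mean() / before.mean())
    return Volume(flat.reshape(cbf.shape), base_cbf.affine.copy()), table


def generate_cohort(
    n_per_group: dict[str, int],
    effects: list[GroupEffectSpec],
    spec: PhantomSpec,
    seed: int = 0,
    params: AcquisitionParams | None = None,
    transform_range: tuple[float, float] = (5.0, 5.0),
    n_parcels: int = 219,
    simulate_series: bool = True,
) -> tuple[list[CohortRecord], BoundarySurface, Parcellation]:
    """Generate a seeded cohort of phantom participants.

    Every participant gets an independent random-number stream spawned from
    the master seed, so adding a participant never perturbs the draws of
    the others. True ASL→T1w transforms are drawn uniformly within
    ``transform_range`` (default ±5 mm, ±5° per axis). The WM–GM boundary
    mesh and the parcellation are shared across the cohort (identical
    interface geometry), so parcel ids correspond by construction.
    """
    params = params or AcquisitionParams()
    effect_by_group = {e.group: e for e in effects}
    for group, count in n_per_group.items():
        if count < 2:
            raise ValueError(f"group '{group}' needs >= 2 participants, got {count}")
        if group not in effect_by_group:
            effect_by_group[group] = GroupEffectSpec(group=group)

    # shared geometry + parcellation (WM interface identical across phantoms)
    _, labels0, boundary = generate_phantom(spec)
    parcellation = build_parcellation(boundary, n_parcels=n_parcels, seed=spec.seed)

    master = np.random.SeedSequence(seed)
    total = sum(n_per_group.values())
    streams = master.spawn(total)

    records: list[CohortRecord] = []
    i = 0
    trans_mm, rot_deg = transform_range
    for group, count in n_per_group.items():
        effect = effect_by_group[group]
        for _ in range(count):
            rng = np.random.default_rng(streams[i])
            pid = f"sub-{i + 1:03d}"

            structural, tissue_labels, _ = generate_phantom(
                spec,
                thinning_mm=effect.atrophy_thinning_mm,
                seed=int(rng.integers(2**31)),
            )
            true_transform = RigidTransform(
                rotation_deg=rng.uniform(-rot_deg, rot_deg, 3),
                translation_mm=rng.uniform(-trans_mm, trans_mm, 3),
                center_mm=np.zeros(3),
            )
            if group == "control":
                severity = 0.0
            else:
                severity = float(
                    max(rng.normal(effect.severity_mean, effect.severity_sd), 0.0)
                )
            base = baseline_cbf_map(spec, tissue_labels)
            true_cbf, table = _apply_group_effects(
                base, tissue_labels, boundary, parcellation, effect,
                severity, spec.gm_cbf_baseline, rng,
            )
            truth = GroundTruth(true_transform, true_cbf, table, severity)
            rec = CohortRecord(
                participant_id=pid,
                group=group,
                ground_truth=truth,
                structural=structural,
                tissue_labels=tissue_labels,
                age=float(rng.normal(65.0, 7.0)),
                sex="F" if rng.random() < 0.5 else "M",
            )
            if simulate_series:
                rec.acquisition = generate_asl_series(
                    tissue_labels, true_cbf, params, spec,
                    true_transform=true_transform, rng=rng,
                )
            records.append(rec)
            i += 1
    return records, boundary, parcellation


def cohort_manifest(records: list[CohortRecord]) -> pd.DataFrame:
    """Tabular participant summary (id, group, severity, demographics)."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "group": [r.group for r in records],
            "severity": [r.severity for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "qei": [r.qei for r in records],
        }
    )
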