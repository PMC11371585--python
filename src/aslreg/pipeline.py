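"""End-to-end experiment orchestration: simulate → quantify → QC →
register (three methods) → surface projection → consistency evaluation →
group statistics.

Outputs can be kept fully in memory (for tests) or written to a
BIDS-inspired directory layout (``sub-XX/anat``, ``sub-XX/perf``,
``derivatives/``) with TSV/JSON/NIfTI artifacts. A master seed drives a
hierarchy of per-participant streams, so runs are bit-for-bit reproducible
and adding a participant never perturbs the others' draws.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    ASLAcquisition,
    CohortRecord,
    GroupEffectSpec,
    cohort_manifest,
    generate_cohort,
)
from .consistency import (
    MethodComparison,
    PairwiseCCSet,
    combine_patient_groups,
    compare_groups_mean_cc,
    compare_methods,
    mean_participant_cc,
    pairwise_cc,
)
from .group_stats import (
    roi_group_ttest,
    roi_results_frame,
    severity_regression,
)
from .phantom import PhantomSpec
from .qc import compute_qei, filter_by_qei
from .quantify import AcquisitionParams, motion_correct, quantify_series
from .registration import (
    BBRConfig,
    RegistrationError,
    RigidRegConfig,
    bbr_refine,
    emulate_manual,
    rigid_register,
)
from .surface import (
    BoundarySurface,
    Parcellation,
    project_to_surface,
    roi_mean_cbf,
    roi_volume,
)
from .transforms import resample_volume

logger = logging.getLogger(__name__)

METHODS = ("manual", "manual+BBR", "FLIRT+BBR")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulated experiment."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 6, "tau_like": 4, "tdp_like": 4}
    )
    effects: list[GroupEffectSpec] = field(default_factory=list)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    rigid_config: RigidRegConfig = field(default_factory=RigidRegConfig)
    bbr_config: BBRConfig = field(default_factory=BBRConfig)
    operator_sd: tuple[float, float] = (1.0, 1.0)
    qei_threshold: float = 0.4
    cc_test: str = "paired"
    n_parcels: int = 219
    projection_offset: float = 1.0
    transform_range: tuple[float, float] = (5.0, 5.0)
    run_motion_correction: bool = False
    seed: int = 0
    out_dir: str | None = None

    def to_json(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


@dataclass
class ExperimentReport:
    """In-memory results of one experiment run."""

    config: ExperimentConfig
    records: list[CohortRecord]
    kept: list[CohortRecord]
    excluded_qei: list[str]
    failed_registration: list[str]
    boundary: BoundarySurface
    parcellation: Parcellation
    cc_sets: dict[tuple[str, str], PairwiseCCSet]  # (group, method) -> set
    mean_cc: pd.DataFrame  # participant, group, method, mean_cc
    method_comparisons: pd.DataFrame
    group_comparisons: pd.DataFrame
    roi_tests: dict[tuple[str, str, str], pd.DataFrame]  # (a, b, method)
    severity_results: dict[str, pd.DataFrame]  # group -> per-parcel OLS
    manifest: pd.DataFrame

    def significant_roi_counts(self) -> pd.DataFrame:
        rows = [
            {
                "group_a": a, "group_b": b, "method": m,
                "n_significant": int(t["significant_fwe"].sum()) if len(t) else 0,
            }
            for (a, b, m), t in self.roi_tests.items()
        ]
        return pd.DataFrame(rows)


def quantify_participant(
    rec: CohortRecord,
    params: AcquisitionParams,
    run_motion_correction: bool = False,
) -> None:
    """Mean-CBF quantification (optionally motion-corrected) for one record."""
    acq: ASLAcquisition = rec.acquisition
    if acq is None:
        raise ValueError(f"{rec.participant_id} has no simulated acquisition")
    series = acq.series
    if run_motion_correction:
        series, _ = motion_correct(series)
    rec.cbf_map = quantify_series(series, acq.m0, params, acq.control_first)


def score_participant_qei(rec: CohortRecord, threshold: float) -> None:
    """QEI from the CBF map and the segmentation mapped into ASL space.

    The tissue labels are carried into acquisition space through the true
    transform with nearest-neighbor resampling — the QC gate scores map
    quality, not registration quality, so it uses the generative geometry.
    """
    labels_asl = resample_volume(
        rec.tissue_labels,
        rec.ground_truth.true_transform.inverse(),
        rec.cbf_map.volume,
        order=0,
    )
    report = compute_qei(rec.cbf_map.volume, labels_asl, threshold=threshold)
    rec.qei = report.qei


def register_participant(
    rec: CohortRecord,
    boundary: BoundarySurface,
    rigid_config: RigidRegConfig,
    bbr_config: BBRConfig,
    operator_sd: tuple[float, float],
    operator_seed: int,
) -> None:
    """Compute the three method transforms for one participant.

    ``manual`` perturbs the ground truth by the operator-error model;
    ``FLIRT`` is the automated rigid fit of the mean CBF map to the T1w;
    the two BBR variants refine each initialization against the GM–WM
    boundary. Any failure flags the participant for exclusion, mirroring
    the failed-registration accounting of real pipelines.
    """
    moving = rec.cbf_map.volume
    try:
        manual = emulate_manual(
            rec.ground_truth.true_transform, operator_sd, seed=operator_seed
        )
        rec.transforms["manual"] = manual
        flirt = rigid_register(moving, rec.structural, config=rigid_config)
        rec.transforms["flirt"] = flirt.transform
        mb = bbr_refine(manual, moving, boundary, bbr_config, method="manual+BBR")
        rec.transforms["manual+BBR"] = mb.transform
        fb = bbr_refine(
            flirt.transform, moving, boundary, bbr_config, method="FLIRT+BBR"
        )
        rec.transforms["FLIRT+BBR"] = fb.transform
        if not (flirt.converged and mb.converged and fb.converged):
            raise RegistrationError("optimizer failed to reduce cost")
    except RegistrationError as err:
        logger.warning("registration failed for %s: %s", rec.participant_id, err)
        rec.registration_failed = True


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full simulated experiment and return all stage outputs."""
    records, boundary, parcellation = generate_cohort(
        config.n_per_group,
        config.effects,
        config.phantom,
        seed=config.seed,
        params=config.acquisition,
        transform_range=config.transform_range,
        n_parcels=config.n_parcels,
    )
    op_seeds = np.random.SeedSequence(config.seed).spawn(len(records) + 1)[-1]
    op_rng = np.random.default_rng(op_seeds)

    for rec in records:
        quantify_participant(rec, config.acquisition, config.run_motion_correction)
        score_participant_qei(rec, config.qei_threshold)
        rec.acquisition = None  # raw series no longer needed; free memory

    kept, excluded = filter_by_qei(records, config.qei_threshold)

    for rec in kept:
        register_participant(
            rec, boundary, config.rigid_config, config.bbr_config,
            config.operator_sd, operator_seed=int(op_rng.integers(2**31)),
        )
    failed = [r.participant_id for r in kept if r.registration_failed]
    kept = [r for r in kept if not r.registration_failed]

    # surface projection + ROI tables
    surface_maps: dict[str, dict[str, object]] = {m: {} for m in METHODS}
    for rec in kept:
        for m in METHODS:
            smap = project_to_surface(
                rec.cbf_map.volume, rec.transforms[m], boundary,
                projection_offset=config.projection_offset,
                method=m, participant_id=rec.participant_id,
            )
            surface_maps[m][rec.participant_id] = smap
            rec.roi_means[m] = roi_mean_cbf(smap, parcellation)
        rec.roi_volumes = roi_volume(rec.tissue_labels, parcellation, boundary)

    # consistency framework
    groups = list(config.n_per_group)
    cc_sets: dict[tuple[str, str], PairwiseCCSet] = {}
    mean_cc_rows = []
    for m in METHODS:
        for g in groups:
            maps = [
                surface_maps[m][r.participant_id]
                for r in kept if r.group == g
            ]
            if len(maps) < 2:
                continue
            cc_sets[(g, m)] = pairwise_cc(maps, group=g, method=m)
        patient_groups = [g for g in groups if g != "control"]
        if len(patient_groups) == 2 and all(
            (g, m) in cc_sets for g in patient_groups
        ):
            cc_sets[("patients", m)] = combine_patient_groups(
                cc_sets[(patient_groups[0], m)], cc_sets[(patient_groups[1], m)]
            )
        for g in groups:
            if (g, m) not in cc_sets:
                continue
            for pcc in mean_participant_cc(cc_sets[(g, m)]):
                mean_cc_rows.append(
                    {"participant_id": pcc.participant_id, "group": g,
                     "method": m, "mean_cc": pcc.mean_cc, "n_pairs": pcc.n_pairs}
                )
    mean_cc = pd.DataFrame(mean_cc_rows)

    method_rows = []
    for g in list(groups) + ["patients"]:
        for ma, mb in (("manual", "manual+BBR"), ("manual", "FLIRT+BBR"),
                       ("manual+BBR", "FLIRT+BBR")):
            if (g, ma) not in cc_sets or (g, mb) not in cc_sets:
                continue
            cmp_ = compare_methods(cc_sets[(g, ma)], cc_sets[(g, mb)], config.cc_test)
            method_rows.append({"group": g, **vars(cmp_)})
    method_comparisons = pd.DataFrame(method_rows)

    group_rows = []
    if len(mean_cc):
        for m in METHODS:
            sub = mean_cc[mean_cc["method"] == m]
            pats = sub[sub["group"] != "control"]
            ctl = sub[sub["group"] == "control"]
            contrasts = [("control", "patients", ctl, pats)]
            for g in groups:
                if g == "control":
                    continue
                contrasts.append(("control", g, ctl, sub[sub["group"] == g]))
            for name_a, name_b, da, db in contrasts:
                if len(da) < 2 or len(db) < 2:
                    continue
                from .consistency import ParticipantCC

                pa = [ParticipantCC(r.participant_id, m, r.mean_cc, r.n_pairs)
                      for r in da.itertuples()]
                pb = [ParticipantCC(r.participant_id, m, r.mean_cc, r.n_pairs)
                      for r in db.itertuples()]
                cmp_ = compare_groups_mean_cc(pa, pb)
                group_rows.append(
                    {"group_a": name_a, "group_b": name_b, "method": m,
                     "t_statistic": cmp_.t_statistic, "df": cmp_.df,
                     "p_value": cmp_.p_value, "cohens_d": cmp_.cohens_d}
                )
    group_comparisons = pd.DataFrame(group_rows)

    # ROI-wise group statistics, per method
    def roi_table(group: str, method: str) -> pd.DataFrame:
        frames = []
        for r in kept:
            if r.group != group:
                continue
            t = r.roi_means[method][["parcel", "mean_cbf"]].copy()
            t["participant_id"] = r.participant_id
            frames.append(t)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames).pivot(
            index="participant_id", columns="parcel", values="mean_cbf"
        )

    roi_tests: dict[tuple[str, str, str], pd.DataFrame] = {}
    patient_groups = [g for g in groups if g != "control"]
    contrasts = [(g, "control") for g in patient_groups]
    if len(patient_groups) == 2:
        contrasts.append((patient_groups[1], patient_groups[0]))
    for m in METHODS:
        for ga, gb in contrasts:
            ta, tb = roi_table(ga, m), roi_table(gb, m)
            if len(ta) < 2 or len(tb) < 2:
                continue
            res = roi_group_ttest(ta, tb, n_tests=config.n_parcels)
            roi_tests[(ga, gb, m)] = roi_results_frame(res)

    # severity regression (per patient group, automated-registration maps)
    severity_results: dict[str, pd.DataFrame] = {}
    for g in patient_groups:
        tbl = roi_table(g, "FLIRT+BBR")
        sev = pd.Series(
            {r.participant_id: r.severity for r in kept if r.group == g}
        )
        if len(tbl) >= 3 and sev.var() > 0:
            res = severity_regression(tbl, sev)
            severity_results[g] = pd.DataFrame([vars(x) for x in res])

    report = ExperimentReport(
        config=config,
        records=records,
        kept=kept,
        excluded_qei=[r.participant_id for r in excluded],
        failed_registration=failed,
        boundary=boundary,
        parcellation=parcellation,
        cc_sets=cc_sets,
        mean_cc=mean_cc,
        method_comparisons=method_comparisons,
        group_comparisons=group_comparisons,
        roi_tests=roi_tests,
        severity_results=severity_results,
        manifest=cohort_manifest(records),
    )
    if config.out_dir is not None:
        write_outputs(report, Path(config.out_dir))
    return report


def write_outputs(report: ExperimentReport, out_dir: Path) -> dict:
    """Write TSV/JSON derivatives and return a manifest of paths."""
    out_dir = Path(out_dir)
    deriv = out_dir / "derivatives"
    deriv.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        path = deriv / name
        df.to_csv(path, sep="\t", index=False)
        manifest[name] = str(path)

    save_tsv(report.manifest, "participants.tsv")
    save_tsv(report.mean_cc, "participant_mean_cc.tsv")
    save_tsv(report.method_comparisons, "method_comparisons.tsv")
    save_tsv(report.group_comparisons, "group_mean_cc_comparisons.tsv")
    save_tsv(report.significant_roi_counts(), "significant_roi_counts.tsv")

    cc_rows = [
        {"group": g, "method": m, "id_a": a, "id_b": b, "cc": cc}
        for (g, m), ccset in report.cc_sets.items()
        for a, b, cc in ccset.pairs
    ]
    save_tsv(pd.DataFrame(cc_rows), "pairwise_cc.tsv")

    for (ga, gb, m), df in report.roi_tests.items():
        save_tsv(df, f"roi_ttest_{ga}_vs_{gb}_{m.replace('+', '')}.tsv")
    for g, df in report.severity_results.items():
        save_tsv(df, f"severity_regression_{g}.tsv")

    summary = {
        "n_participants": len(report.records),
        "n_kept": len(report.kept),
        "excluded_qei": report.excluded_qei,
        "failed_registration": report.failed_registration,
        "n_failed_registration": len(report.failed_registration),
        "n_parcels": report.parcellation.n_parcels,
    }
    (deriv / "summary.json").write_text(json.dumps(summary, indent=2))
    (deriv / "config.json").write_text(report.config.to_json())
    manifest["summary.json"] = str(deriv / "summary.json")
    return manifest


def write_raw_participant(rec: CohortRecord, out_dir: Path) -> None:
    """Write one participant's raw data in a BIDS-inspired layout."""
    sub = Path(out_dir) / rec.participant_id
    (sub / "anat").mkdir(parents=True, exist_ok=True)
    (sub / "perf").mkdir(parents=True, exist_ok=True)
    rec.structural.save(sub / "anat" / "T1w.nii.gz")
    rec.tissue_labels.save(sub / "anat" / "tissue_labels.nii.gz")
    if rec.acquisition is not None:
        acq = rec.acquisition
        acq.m0.save(sub / "perf" / "m0.nii.gz")
        for i, vol in enumerate(acq.series):
            tag = "control" if (i % 2 == 0) == acq.control_first else "label"
            vol.save(sub / "perf" / f"asl_{i:03d}_{tag}.nii.gz")
    truth = {
        "true_transform": rec.ground_truth.true_transform.matrix.tolist(),
        "severity": rec.ground_truth.severity,
        "roi_effect_table": {
            str(k): v for k, v in rec.ground_truth.roi_effect_table.items()
        },
        "group": rec.group,
    }
    (sub / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def make_fixtures(seed: int = 0, out_dir: str | Path | None = None):
    """One miniature participant for tests: small grids, full 28-volume
    series, M0, boundary mesh, and ground-truth JSON."""
    spec = PhantomSpec(
        structural_shape=(32, 32, 28),
        structural_spacing=(3.0, 3.0, 3.0),
        asl_shape=(24, 24, 16),
        asl_spacing=(5.0, 5.0, 5.0),
        mesh_subdivisions=3,
        noise_sd=0.5,
        seed=seed,
    )
    records, boundary, parcellation = generate_cohort(
        {"control": 2}, [], spec, seed=seed, n_parcels=100
    )
    rec = records[0]
    if out_dir is not None:
        write_raw_participant(rec, Path(out_dir))
        boundary.save(Path(out_dir) / "boundary_surface.txt")
    return rec, boundary, parcellation, spec
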