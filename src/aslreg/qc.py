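"""CBF-map quality scoring (QEI-style) and the exclusion gate.

The quality evaluation index combines three components, each sensitive to
a distinct failure mode of ASL CBF maps:

* ``structural_correlation`` — Pearson r between the CBF map and a
  segmentation-derived pseudo-CBF (GM 60, WM 20, CSF 0); low when the map
  has no anatomical structure.
* ``spatial_cv`` — coefficient of variation of GM CBF; high when the map
  is dominated by noise.
* ``negative_gm_fraction`` — fraction of GM voxels with negative CBF;
  physiologically impossible signal.

The index is

    QEI = clip(r, 0, 1)^a · exp(−b · CV) · (1 − negfrac)^c

with exponents (a, b, c) in :class:`QEIConfig`. It is increasing in r,
decreasing in CV and in the negative fraction, maps into [0, 1], and is
invariant to global positive rescaling of the CBF map (all three
components are scale-free). Maps pass the gate iff QEI strictly exceeds
the threshold (default 0.4).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .surface import GM_LABEL, WM_LABEL
from .volume import Volume

logger = logging.getLogger(__name__)

QEI_THRESHOLD_DEFAULT = 0.4
PSEUDO_CBF = {GM_LABEL: 60.0, WM_LABEL: 20.0}


@dataclass(frozen=True)
class QEIConfig:
    corr_exponent: float = 1.0
    cv_rate: float = 1.0
    negfrac_exponent: float = 2.0


@dataclass
class QualityReport:
    qei: float
    structural_correlation: float
    spatial_cv: float
    negative_gm_fraction: float
    passed: bool


def compute_qei(
    cbf: Volume,
    tissue_labels: Volume,
    threshold: float = QEI_THRESHOLD_DEFAULT,
    config: QEIConfig | None = None,
) -> QualityReport:
    """Score one CBF map against its tissue segmentation."""
    config = config or QEIConfig()
    if not cbf.same_grid(tissue_labels):
        raise ValueError("CBF map and tissue labels must share a grid")
    gm = tissue_labels.data == GM_LABEL
    if not gm.any():
        raise ValueError("GM mask is empty")
    brain = tissue_labels.data > 0

    pseudo = np.zeros_like(cbf.data)
    for label, value in PSEUDO_CBF.items():
        pseudo[tissue_labels.data == label] = value

    x, y = cbf.data[brain], pseudo[brain]
    if x.std() == 0 or y.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])

    gm_vals = cbf.data[gm]
    gm_mean = gm_vals.mean()
    cv = float(gm_vals.std() / gm_mean) if gm_mean > 0 else np.inf
    neg = float((gm_vals < 0).mean())

    qei = (
        np.clip(r, 0.0, 1.0) ** config.corr_exponent
        * (np.exp(-config.cv_rate * cv) if np.isfinite(cv) else 0.0)
        * (1.0 - neg) ** config.negfrac_exponent
    )
    return QualityReport(
        qei=float(qei),
        structural_correlation=r,
        spatial_cv=cv,
        negative_gm_fraction=neg,
        passed=bool(qei > threshold),
    )


def filter_by_qei(records, threshold: float = QEI_THRESHOLD_DEFAULT):
    """Partition cohort records into (kept, excluded) by strict QEI > threshold.

    Records must already carry a ``qei`` score; each exclusion is logged
    with id and score.
    """
    kept, excluded = [], []
    for rec in records:
        if not np.isfinite(rec.qei):
            raise ValueError(f"{rec.participant_id} has no QEI score")
        if rec.qei > threshold:
            kept.append(rec)
        else:
            logger.info(
                "excluding %s: QEI %.3f <= %.2f", rec.participant_id, rec.qei, threshold
            )
            excluded.append(rec)
    return kept, excluded
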