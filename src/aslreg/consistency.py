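"""Registration-consistency framework: pairwise vertex-wise Pearson
correlations between participants' surface CBF maps, per-participant mean
correlation, and method/group comparisons.

A well-registered group of perfusion maps is mutually similar; each
unordered pair of participants (within a group, for one registration
method) contributes one Pearson correlation coefficient (CC) computed over
vertices valid in both maps. A participant's consistency score is the mean
of the CCs of all pairs containing them. Methods are compared with paired
t-tests on the per-pair CCs (a two-sample pooled-variance mode is also
provided, matching the degrees-of-freedom convention 2·n_pairs − 2);
groups are compared with pooled two-sample t-tests on participant mean
CCs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .surface import SurfaceMap

logger = logging.getLogger(__name__)


@dataclass
class PairwiseCCSet:
    """All unordered within-group pairwise CCs for one registration method."""

    group: str
    method: str
    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def values(self) -> np.ndarray:
        return np.array([cc for _, _, cc in self.pairs])

    @property
    def participant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b, _ in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


@dataclass
class ParticipantCC:
    participant_id: str
    method: str
    mean_cc: float
    n_pairs: int


@dataclass
class MethodComparison:
    method_a: str
    method_b: str
    t_statistic: float
    df: int
    p_value: float
    cohens_d: float
    test_kind: str


def pairwise_cc(
    surface_maps: list[SurfaceMap], group: str = "", method: str = ""
) -> PairwiseCCSet:
    """Pearson CC over common valid vertices for every unordered pair.

    Pairs with fewer than 3 common valid vertices are undefined and logged
    as dropped. For a group of n maps the result has n·(n−1)/2 pairs.
    """
    if len(surface_maps) < 2:
        raise ValueError("need at least 2 surface maps")
    nv = len(surface_maps[0].values)
    for m in surface_maps:
        if len(m.values) != nv:
            raise ValueError("surface maps must share a vertex count")
    method = method or surface_maps[0].method
    out = PairwiseCCSet(group=group, method=method)
    for ma, mb in combinations(surface_maps, 2):
        common = ma.valid_mask & mb.valid_mask
        if common.sum() < 3:
            logger.info(
                "pair (%s, %s): <3 common valid vertices, CC undefined",
                ma.participant_id, mb.participant_id,
            )
            out.dropped.append((ma.participant_id, mb.participant_id))
            continue
        x, y = ma.values[common], mb.values[common]
        if x.std() == 0 or y.std() == 0:
            cc = 0.0
        else:
            cc = float(np.corrcoef(x, y)[0, 1])
        out.pairs.append((ma.participant_id, mb.participant_id, cc))
    return out


def combine_patient_groups(cc_a: PairwiseCCSet, cc_b: PairwiseCCSet) -> PairwiseCCSet:
    """Concatenate two groups' pair sets WITHOUT forming cross-group pairs."""
    if cc_a.method != cc_b.method:
        raise ValueError(f"method mismatch: {cc_a.method!r} vs {cc_b.method!r}")
    return PairwiseCCSet(
        group=f"{cc_a.group}+{cc_b.group}" if cc_a.group and cc_b.group else
        (cc_a.group or cc_b.group),
        method=cc_a.method,
        pairs=list(cc_a.pairs) + list(cc_b.pairs),
        dropped=list(cc_a.dropped) + list(cc_b.dropped),
    )


def mean_participant_cc(ccset: PairwiseCCSet) -> list[ParticipantCC]:
    """Per-participant mean over all pairs containing that participant."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for a, b, cc in ccset.pairs:
        for pid in (a, b):
            sums[pid] = sums.get(pid, 0.0) + cc
            counts[pid] = counts.get(pid, 0) + 1
    return [
        ParticipantCC(pid, ccset.method, sums[pid] / counts[pid], counts[pid])
        for pid in sums
    ]


def _cohens_d_paired(diff: np.ndarray) -> float:
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else 0.0


def _cohens_d_pooled(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def compare_methods(
    cc_a: PairwiseCCSet, cc_b: PairwiseCCSet, test_kind: str = "paired"
) -> MethodComparison:
    """Compare two registration methods' CC distributions on one group.

    ``paired`` (default) tests the per-pair CC differences (df = n_pairs−1);
    ``two_sample_pooled`` treats the two CC samples as independent with a
    pooled-variance t-test (df = 2·n_pairs − 2). Undefined pairs are
    dropped listwise in paired mode.
    """
    if test_kind == "paired":
        b_by_key = {frozenset((x, y)): cc for x, y, cc in cc_b.pairs}
        aligned = [
            (cc, b_by_key[frozenset((x, y))])
            for x, y, cc in cc_a.pairs
            if frozenset((x, y)) in b_by_key
        ]
        if len(aligned) != cc_a.n_pairs or len(aligned) != cc_b.n_pairs:
            if not aligned:
                raise ValueError("pair sets do not overlap; cannot pair")
            logger.info("paired comparison on %d shared pairs", len(aligned))
        a = np.array([x for x, _ in aligned])
        b = np.array([y for _, y in aligned])
        diff = a - b
        t, p = stats.ttest_rel(a, b)
        if np.isnan(t):  # zero-variance differences (identical CC sets)
            t, p = 0.0, 1.0
        return MethodComparison(
            cc_a.method, cc_b.method, float(t), len(diff) - 1, float(p),
            _cohens_d_paired(diff), "paired",
        )
    if test_kind == "two_sample_pooled":
        a, b = cc_a.values, cc_b.values
        t, p = stats.ttest_ind(a, b, equal_var=True)
        if np.isnan(t):
            t, p = 0.0, 1.0
        return MethodComparison(
            cc_a.method, cc_b.method, float(t), len(a) + len(b) - 2, float(p),
            _cohens_d_pooled(a, b), "two_sample_pooled",
        )
    raise ValueError(f"unknown test_kind {test_kind!r}")


def compare_groups_mean_cc(
    participants_a: list[ParticipantCC], participants_b: list[ParticipantCC]
) -> MethodComparison:
    """Pooled two-sample t-test on participant mean CCs between two groups
    (df = n_a + n_b − 2)."""
    if len(participants_a) < 2 or len(participants_b) < 2:
        raise ValueError("need >= 2 participants per group")
    a = np.array([p.mean_cc for p in participants_a])
    b = np.array([p.mean_cc for p in participants_b])
    t, p = stats.ttest_ind(a, b, equal_var=True)
    method = participants_a[0].method if participants_a else ""
    return MethodComparison(
        method, method, float(t), len(a) + len(b) - 2, float(p),
        _cohens_d_pooled(a, b), "two_sample_pooled",
    )
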