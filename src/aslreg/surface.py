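"""GM–WM boundary surface, surface sampling, and ROI machinery.

The boundary surface lives in T1w world coordinates with outward unit
normals pointing from white matter into gray matter. Volumetric CBF is
sampled at vertices displaced a small distance along the normal (mid-GM),
mapped into CBF space through the inverse of the estimated registration.

The cortical parcellation is a deterministic farthest-point partition of
the mesh vertices into a fixed number of parcels (219 by default, the
cardinality of the Lausanne125 cortical labels). Because every phantom in
a cohort shares the same mesh topology, parcel ids correspond across
participants by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .transforms import AffineTransform
from .volume import Volume

logger = logging.getLogger(__name__)

GM_LABEL = 2  # tissue-label convention: 0 bg, 1 CSF, 2 GM, 3 WM
WM_LABEL = 3
CSF_LABEL = 1


@dataclass
class BoundarySurface:
    """Triangulated GM–WM interface in world mm."""

    vertices: np.ndarray  # (V, 3)
    normals: np.ndarray  # (V, 3) unit, outward (WM -> GM)
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.normals = np.asarray(self.normals, float)
        self.faces = np.asarray(self.faces, int)
        if self.vertices.shape != self.normals.shape:
            raise ValueError("vertices and normals must have matching shapes")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def save(self, path) -> None:
        """Plain-text surface: vertex count, vertices+normals, then faces."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_vertices} {len(self.faces)}\n")
            for v, n in zip(self.vertices, self.normals):
                fh.write(" ".join(f"{x:.9g}" for x in (*v, *n)) + "\n")
            for f in self.faces:
                fh.write(f"{f[0]} {f[1]} {f[2]}\n")

    @classmethod
    def load(cls, path) -> "BoundarySurface":
        with open(path) as fh:
            nv, nf = (int(x) for x in fh.readline().split())
            rows = np.array(
                [[float(x) for x in fh.readline().split()] for _ in range(nv)]
            )
            faces = np.array(
                [[int(x) for x in fh.readline().split()] for _ in range(nf)]
            )
        return cls(rows[:, :3], rows[:, 3:], faces)


@dataclass
class SurfaceMap:
    """Per-vertex scalar field (CBF, mL/100g/min) for one participant/method."""

    values: np.ndarray
    valid_mask: np.ndarray
    method: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.valid_mask = np.asarray(self.valid_mask, bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must align")


@dataclass
class Parcellation:
    """Per-vertex parcel labels in 1..n_parcels, all parcels nonempty."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        ids = np.unique(self.labels)
        self._n = len(ids)
        if ids.min() < 1 or ids.max() != self._n:
            raise ValueError("parcel ids must be contiguous starting at 1")
        if not self.names:
            self.names = {i: f"parcel_{i:03d}" for i in range(1, self._n + 1)}

    @property
    def n_parcels(self) -> int:
        return self._n

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.arange(1, self._n + 1)


def project_to_surface(
    cbf: Volume,
    transform: AffineTransform,
    boundary: BoundarySurface,
    projection_offset: float = 1.0,
    method: str = "",
    participant_id: str = "",
) -> SurfaceMap:
    """Sample a volumetric CBF map at GM-interior surface points.

    Each vertex is displaced ``projection_offset`` mm along its outward
    normal (default +1 mm, i.e. mid-GM), mapped into CBF (moving) space
    through ``transform.inverse()``, and trilinearly sampled. Vertices
    whose sample point falls outside the volume are marked invalid.
    """
    pts_t1w = boundary.vertices + projection_offset * boundary.normals
    pts_moving = transform.inverse().apply_points(pts_t1w)
    vals, inside = cbf.sample_world(pts_moving)
    if not inside.any():
        raise ValueError("all vertices project outside the CBF volume")
    return SurfaceMap(vals, inside, method=method, participant_id=participant_id)


def build_parcellation(
    boundary: BoundarySurface, n_parcels: int = 219, seed: int = 0
) -> Parcellation:
    """Deterministic farthest-point partition of mesh vertices.

    The first seed vertex is drawn from ``seed``; subsequent seeds maximize
    the minimum chord distance to existing seeds (ties -> lowest index).
    Vertices are then assigned to their nearest seed, which guarantees
    exactly ``n_parcels`` nonempty parcels.
    """
    verts = boundary.vertices
    nv = len(verts)
    if n_parcels > nv:
        raise ValueError(f"n_parcels={n_parcels} exceeds vertex count {nv}")
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(nv))]
    mind = np.linalg.norm(verts - verts[seeds[0]], axis=1)
    for _ in range(n_parcels - 1):
        nxt = int(np.argmax(mind))
        seeds.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(verts - verts[nxt], axis=1))
    tree = cKDTree(verts[seeds])
    _, assign = tree.query(verts)
    return Parcellation(assign + 1)


def roi_mean_cbf(surface_map: SurfaceMap, parcellation: Parcellation) -> pd.DataFrame:
    """Mean CBF over valid vertices per parcel; empty parcels -> NaN.

    Returns a DataFrame with one row per parcel id (columns ``parcel``,
    ``mean_cbf``, ``n_vertices``).
    """
    if len(surface_map.values) != len(parcellation.labels):
        raise ValueError("surface map and parcellation sizes differ")
    ids = parcellation.parcel_ids
    valid = surface_map.valid_mask
    lab = parcellation.labels[valid]
    val = surface_map.values[valid]
    sums = np.bincount(lab, weights=val, minlength=len(ids) + 1)[1:]
    counts = np.bincount(lab, minlength=len(ids) + 1)[1:]
    means = np.divide(sums, counts, out=np.full(len(ids), np.nan), where=counts > 0)
    if (counts == 0).any():
        logger.info(
            "%d parcels have no valid vertex and are reported missing",
            int((counts == 0).sum()),
        )
    return pd.DataFrame({"parcel": ids, "mean_cbf": means, "n_vertices": counts})


def roi_volume(
    tissue_labels: Volume, parcellation: Parcellation, boundary: BoundarySurface
) -> pd.DataFrame:
    """GM volume (mm^3) per parcel.

    Each GM voxel is assigned to the parcel of its nearest boundary vertex;
    parcel volume is voxel count times voxel volume, so total GM volume is
    conserved across the assignment.
    """
    gm = tissue_labels.data == GM_LABEL
    if not gm.any():
        raise ValueError("GM mask is empty")
    idx = np.argwhere(gm).astype(float)
    world = tissue_labels.voxel_to_world(idx)
    tree = cKDTree(boundary.vertices)
    _, nearest = tree.query(world)
    parcels = parcellation.labels[nearest]
    counts = np.bincount(parcels, minlength=parcellation.n_parcels + 1)[1:]
    return pd.DataFrame(
        {
            "parcel": parcellation.parcel_ids,
            "volume_mm3": counts * tissue_labels.voxel_volume,
            "n_voxels": counts,
        }
    )
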