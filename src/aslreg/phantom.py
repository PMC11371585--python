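"""Digital brain phantom: nested-shell head with WM core, GM ribbon, CSF
shell, ventricle-like cavities, and an analytic GM–WM boundary mesh.

The shells are radially-modulated ellipsoids: an ellipsoid whose radius is
scaled by a fixed smooth angular undulation (a mild "pseudo-gyrification").
The interface keeps a closed-form implicit function — mesh vertices lie on
it exactly and normals follow its gradient — so surface correctness is
provable, while the undulation gives the boundary the angular structure a
folded cortex has. That structure is what makes head rotation observable:
on a perfectly smooth quadric, rotating the boundary slides sample points
tangentially along the surface and both intensity and boundary-contrast
registration costs are blind to it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .surface import CSF_LABEL, GM_LABEL, WM_LABEL, BoundarySurface
from .volume import Volume, centered_affine

DEFAULT_TISSUE_INTENSITIES = {"wm": 1000.0, "gm": 700.0, "csf": 250.0}


@dataclass
class PhantomSpec:
    """Geometry, contrast, and noise parameters of one phantom participant.

    The ASL grid defaults reproduce a 64x64 matrix of 34 slices at 3.75 mm
    isotropic. T1w-like tissue contrast is WM > GM > CSF. Baseline CBF
    defaults (GM 60, WM 20 mL/100g/min) follow physiological convention.
    """

    structural_shape: tuple[int, int, int] = (64, 64, 54)
    structural_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    asl_shape: tuple[int, int, int] = (64, 64, 34)
    asl_spacing: tuple[float, float, float] = (3.75, 3.75, 3.75)
    tissue_intensities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_INTENSITIES)
    )
    gm_cbf_baseline: float = 60.0
    wm_cbf_baseline: float = 20.0
    noise_sd: float = 1.0
    ringing_amplitude: float = 0.1
    seed: int = 0
    # geometry knobs (mm); wm_semi_axes_mm=None scales with the FOV.
    # The three default axis fractions are deliberately distinct so the
    # head has no rotational symmetry and rigid pose is identifiable.
    wm_semi_axes_mm: tuple[float, float, float] | None = None
    wm_axis_fractions: tuple[float, float, float] = (0.70, 0.60, 0.55)
    cortical_thickness_mm: float = 4.0
    csf_thickness_mm: float = 3.0
    boundary_bump_amplitude: float = 0.06
    cbf_pattern_amplitude: float = 0.15
    include_ventricles: bool = True
    mesh_subdivisions: int = 4

    def __post_init__(self) -> None:
        for name, shape in (("structural", self.structural_shape), ("asl", self.asl_shape)):
            if min(shape) < 16:
                raise ValueError(
                    f"{name}_shape {shape} is degenerate: every axis needs >= 16 voxels"
                )
        if min(self.structural_spacing) <= 0 or min(self.asl_spacing) <= 0:
            raise ValueError("spacings must be positive")
        if not (self.gm_cbf_baseline > self.wm_cbf_baseline >= 0):
            raise ValueError("need gm_cbf_baseline > wm_cbf_baseline >= 0")
        ti = self.tissue_intensities
        if not (ti["wm"] > ti["gm"] > ti["csf"]):
            raise ValueError("T1w-like contrast requires WM > GM > CSF intensity")
        if not 0.0 <= self.ringing_amplitude <= 1.0:
            raise ValueError("ringing_amplitude must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    # ---- derived geometry ---------------------------------------------------

    @property
    def structural_affine(self) -> np.ndarray:
        return centered_affine(self.structural_shape, self.structural_spacing)

    @property
    def asl_affine(self) -> np.ndarray:
        return centered_affine(self.asl_shape, self.asl_spacing)

    def asl_grid(self) -> Volume:
        """Empty companion volume carrying the ASL acquisition geometry."""
        return Volume(np.zeros(self.asl_shape), self.asl_affine)

    def wm_axes(self) -> np.ndarray:
        if self.wm_semi_axes_mm is not None:
            return np.asarray(self.wm_semi_axes_mm, float)
        half_fov = (
            np.asarray(self.structural_shape, float)
            * np.asarray(self.structural_spacing, float)
            / 2.0
        )
        return np.asarray(self.wm_axis_fractions, float) * half_fov

    def gm_axes(self, thinning_mm: float = 0.0) -> np.ndarray:
        thickness = self.cortical_thickness_mm - thinning_mm
        if thickness <= 0:
            raise ValueError("atrophy thinning exceeds cortical thickness")
        return self.wm_axes() + thickness

    def csf_axes(self, thinning_mm: float = 0.0) -> np.ndarray:
        return self.gm_axes(thinning_mm) + self.csf_thickness_mm


def ellipsoid_implicit(points: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """Level-set value f(p) = sum((p_i/a_i)^2) - 1 (zero on the surface)."""
    points = np.atleast_2d(points)
    return np.sum((points / semi_axes) ** 2, axis=1) - 1.0


def _bump(u: np.ndarray) -> np.ndarray:
    """Fixed smooth angular undulation on the unit sphere, |bump| <~ 1.5.

    Deliberately without any rotational or mirror symmetry, so every head
    pose produces a distinct boundary geometry.
    """
    u = np.atleast_2d(u)
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    return np.sin(3.0 * x + 5.0 * y) * np.cos(4.0 * z) + 0.5 * x * y * z


def shell_implicit(
    points: np.ndarray, semi_axes: np.ndarray, amplitude: float
) -> np.ndarray:
    """Implicit function of a radially-modulated ellipsoid shell.

    g(p) = rho(p) − s(u(p)) with rho the elliptical radius
    sqrt(sum((p_i/a_i)^2)), u the unit direction of p/a, and
    s(u) = 1 + amplitude·bump(u). Zero on the surface, negative inside;
    for amplitude 0 this is a monotone transform of the plain ellipsoid
    level set.
    """
    points = np.atleast_2d(points)
    scaled = points / np.asarray(semi_axes, float)
    rho = np.linalg.norm(scaled, axis=1)
    u = scaled / np.maximum(rho, 1e-12)[:, None]
    return rho - (1.0 + amplitude * _bump(u))


def shell_signed_distance(
    points: np.ndarray, semi_axes: np.ndarray, amplitude: float
) -> np.ndarray:
    """First-order signed distance (mm) to the shell surface: g / |grad g|."""
    points = np.atleast_2d(points)
    g = shell_implicit(points, semi_axes, amplitude)
    grad = _shell_gradient(points, semi_axes, amplitude)
    return g / np.maximum(np.linalg.norm(grad, axis=1), 1e-12)


def ellipsoid_signed_distance(points: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """First-order signed distance (mm) to a plain ellipsoid: f / |grad f|."""
    points = np.atleast_2d(points)
    f = ellipsoid_implicit(points, semi_axes)
    grad = 2.0 * points / np.asarray(semi_axes, float) ** 2
    return f / np.maximum(np.linalg.norm(grad, axis=1), 1e-12)


def _shell_gradient(
    points: np.ndarray, semi_axes: np.ndarray, amplitude: float, h: float = 1e-4
) -> np.ndarray:
    """Central-difference gradient of the shell implicit (mm^-1)."""
    points = np.atleast_2d(points)
    grad = np.empty_like(points)
    for i in range(3):
        dp = np.zeros(3)
        dp[i] = h
        grad[:, i] = (
            shell_implicit(points + dp, semi_axes, amplitude)
            - shell_implicit(points - dp, semi_axes, amplitude)
        ) / (2.0 * h)
    return grad


def make_boundary_mesh(
    semi_axes: np.ndarray, amplitude: float = 0.0, subdivisions: int = 4
) -> BoundarySurface:
    """Icosphere mapped onto the WM–GM interface.

    Vertices are constructed as s(u)·(a∘u) for unit directions u, so they
    lie on the implicit surface exactly; outward normals (WM -> GM) follow
    the normalized implicit gradient.
    """
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(sphere.vertices, float)
    scale = 1.0 + amplitude * _bump(u)
    verts = scale[:, None] * u * np.asarray(semi_axes, float)
    normals = _shell_gradient(verts, semi_axes, amplitude)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return BoundarySurface(verts, normals, np.asarray(sphere.faces, int))


def ventricle_geometry(wm_axes: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Two lateral-ventricle-like CSF cavities deep in the WM core, as
    (center, semi_axes) pairs. Asymmetric placement breaks any residual
    near-symmetry of the smooth head for intensity-based registration."""
    a = np.asarray(wm_axes, float)
    return [
        (np.array([0.30, -0.10, 0.08]) * a, np.array([0.16, 0.32, 0.18]) * a),
        (np.array([-0.30, -0.02, 0.08]) * a, np.array([0.14, 0.26, 0.16]) * a),
    ]


def tissue_label_map(spec: PhantomSpec, thinning_mm: float = 0.0) -> Volume:
    """Voxelwise tissue labels (0 bg, 1 CSF, 2 GM, 3 WM) on the structural grid."""
    grid = Volume(np.zeros(spec.structural_shape), spec.structural_affine)
    pts = grid.world_grid()
    amp = spec.boundary_bump_amplitude
    labels = np.zeros(len(pts), dtype=float)
    labels[shell_implicit(pts, spec.csf_axes(thinning_mm), amp) <= 0] = CSF_LABEL
    labels[shell_implicit(pts, spec.gm_axes(thinning_mm), amp) <= 0] = GM_LABEL
    labels[shell_implicit(pts, spec.wm_axes(), amp) <= 0] = WM_LABEL
    if spec.include_ventricles:
        for center, axes in ventricle_geometry(spec.wm_axes()):
            labels[ellipsoid_implicit(pts - center, axes) <= 0] = CSF_LABEL
    return Volume(labels.reshape(spec.structural_shape), spec.structural_affine)


def generate_phantom(
    spec: PhantomSpec, thinning_mm: float = 0.0, seed: int | None = None
) -> tuple[Volume, Volume, BoundarySurface]:
    """Build one phantom head: (structural T1w-like, tissue labels, boundary).

    ``thinning_mm`` shrinks the GM ribbon (cortical atrophy) without moving
    the WM–GM interface, so the boundary mesh is shared across participants.
    Deterministic given the seed (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = tissue_label_map(spec, thinning_mm)
    intensity = np.zeros(labels.shape)
    intensity[labels.data == CSF_LABEL] = spec.tissue_intensities["csf"]
    intensity[labels.data == GM_LABEL] = spec.tissue_intensities["gm"]
    intensity[labels.data == WM_LABEL] = spec.tissue_intensities["wm"]
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, labels.shape)
    structural = Volume(intensity, spec.structural_affine)
    boundary = make_boundary_mesh(
        spec.wm_axes(), spec.boundary_bump_amplitude, spec.mesh_subdivisions
    )
    return structural, labels, boundary


def _cbf_pattern(u: np.ndarray) -> np.ndarray:
    """Fixed smooth angular perfusion topography on the unit sphere, ~±1.4.

    Distinct from the boundary undulation so perfusion structure and
    boundary geometry are not confounded.
    """
    u = np.atleast_2d(u)
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    return np.cos(2.0 * x + 3.0 * y) * np.sin(3.0 * z + 1.0) + 0.5 * np.sin(4.0 * x) * np.cos(2.0 * z)


def baseline_cbf_map(spec: PhantomSpec, tissue_labels: Volume) -> Volume:
    """Ground-truth CBF: GM/WM baselines with a regional GM topography.

    GM CBF is the baseline modulated by a fixed smooth angular pattern
    (amplitude ``cbf_pattern_amplitude``), shared across the cohort —
    emulating the regional perfusion structure that makes inter-subject
    perfusion maps correlate when well registered. WM is uniform; CSF and
    background are 0.
    """
    cbf = np.zeros(tissue_labels.shape)
    gm = tissue_labels.data == GM_LABEL
    if gm.any():
        idx = np.argwhere(gm).astype(float)
        pts = tissue_labels.voxel_to_world(idx)
        scaled = pts / spec.wm_axes()
        u = scaled / np.maximum(
            np.linalg.norm(scaled, axis=1), 1e-12
        )[:, None]
        modulation = 1.0 + spec.cbf_pattern_amplitude * _cbf_pattern(u)
        cbf[gm] = np.maximum(spec.gm_cbf_baseline * modulation, 0.0)
    cbf[tissue_labels.data == WM_LABEL] = spec.wm_cbf_baseline
    return Volume(cbf, tissue_labels.affine.copy())
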