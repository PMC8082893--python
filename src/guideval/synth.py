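"""Synthetic study inputs: bone phantoms, saw guides, placements, scans.

No cadaveric data ship with this package; every input the validation
pipeline consumes is generated here, deterministically from an explicit
seed:

* **Bone phantoms** — tubular long-bone volumes with cortical, medullary
  and soft-tissue intensity classes. The cross-section is a superellipse
  with an eccentricity parameter (distal ulna: near-circular; radius: more
  eccentric), flaring toward the joint ends. Two modality mappings exist:
  ``ct_like`` (clean, well-separated HU classes) and ``sct_like`` (heavier
  noise, optional low-frequency intensity inhomogeneity near the bone
  ends, and an optional false-positive calcified-tendon blob adjacent to
  the cortex). The analytic surface, tessellated directly from the
  cross-section profile, plays the role a micro-CT ground-truth model
  plays for real specimens.
* **Saw guides** — 40 mm half-cylinder shells conforming to the local bone
  surface, each carrying a 20 x 5 x 10 mm reference box whose local frame
  follows the anatomical convention: z along the proximal direction,
  y away from the bone, x completing the right-handed frame.
* **Observer placements** — zero-mean per-axis Gaussian translation and
  rotation noise in the planned box's local frame, rotations acting about
  the box centroid, with the along-bone (z) components dominant.
* **Optical scans** — a resampled, vertex-jittered copy of a mesh under an
  unknown rigid offset (retained on the returned object so tests can use
  it as a registration oracle), emulating a ~0.1 mm structured-light
  scanner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .mesh import SurfaceQuery
from .placement import DEFAULT_BOX_DIMS, BoxPose
from .transforms import RigidTransform
from .volume import VolumeImage

__all__ = [
    "PhantomSpec",
    "BonePhantom",
    "GuideDesign",
    "ObserverErrorModel",
    "ScanNoiseModel",
    "OpticalScan",
    "generate_bone_phantom",
    "design_saw_guide",
    "simulate_placement",
    "simulate_optical_scan",
]

# tissue label codes in the phantom label map
LABEL_SOFT = 0
LABEL_CORTICAL = 1
LABEL_MEDULLARY = 2
LABEL_TENDON = 3

GUIDE_LENGTH_MM = 40.0
_SUPERELLIPSE_P = 2.5


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and artifact description of one bone phantom."""

    bone_length: float = 120.0
    shaft_outer_radius: float = 8.0
    cortical_thickness: float = 3.0
    canal_radius: float = 4.0
    end_flare_factor: float = 1.5
    proximal_flare_fraction: float = 0.5
    shaft_bow: float = 3.0
    cross_section_eccentricity: float = 0.15
    voxel_spacing: tuple = (0.6, 0.6, 0.6)
    intensity_means: dict = field(
        default_factory=lambda: {
            LABEL_SOFT: 40.0, LABEL_CORTICAL: 1200.0,
            LABEL_MEDULLARY: -50.0, LABEL_TENDON: 700.0,
        }
    )
    intensity_sds: dict = field(
        default_factory=lambda: {
            LABEL_SOFT: 20.0, LABEL_CORTICAL: 60.0,
            LABEL_MEDULLARY: 25.0, LABEL_TENDON: 60.0,
        }
    )
    modality: str = "ct_like"
    tendon_blob: bool = False
    end_inhomogeneity: bool = False
    sct_noise_scale: float = 2.5
    end_bias_amplitude: float = 300.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "voxel_spacing", tuple(self.voxel_spacing))
        if self.canal_radius + self.cortical_thickness > self.shaft_outer_radius:
            raise ValueError(
                "invalid geometry: canal_radius + cortical_thickness "
                f"({self.canal_radius} + {self.cortical_thickness}) exceeds "
                f"shaft_outer_radius ({self.shaft_outer_radius})"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.bone_length <= 2 * GUIDE_LENGTH_MM:
            raise ValueError(
                f"bone_length ({self.bone_length}) must exceed twice the guide "
                f"length ({2 * GUIDE_LENGTH_MM}) so proximal and distal guides fit"
            )
        if not 0 <= self.cross_section_eccentricity < 1:
            raise ValueError("cross_section_eccentricity must be in [0, 1)")
        if self.end_flare_factor < 1:
            raise ValueError("end_flare_factor must be >= 1")
        if self.modality not in ("ct_like", "sct_like"):
            raise ValueError(f"unknown modality {self.modality!r}")

    # -- analytic cross-section profile ------------------------------------
    # Long bones are neither straight nor end-symmetric: the shaft is bowed
    # laterally and the two joint ends flare differently. Both features are
    # modelled explicitly (and they also remove the rotational symmetries a
    # plain tube would have, which no real bone possesses).
    def _flare(self, z):
        """Axial scale factor: 1 mid-shaft, rising toward the joint ends.

        The distal end (z = 0) flares by ``end_flare_factor``; the proximal
        end by the configured fraction of that flare."""
        ramp = 15.0  # mm over which the joint-end flare develops
        z = np.asarray(z, float)
        s_d = np.clip(1.0 - z / ramp, 0.0, 1.0)
        s_p = np.clip(1.0 - (self.bone_length - z) / ramp, 0.0, 1.0)
        gain = self.end_flare_factor - 1.0
        return (
            1.0
            + gain * s_d * s_d * (3 - 2 * s_d)
            + gain * self.proximal_flare_fraction * s_p * s_p * (3 - 2 * s_p)
        )

    def bow_offset(self, z):
        """Lateral (x) offset of the cross-section centre along the shaft."""
        z = np.asarray(z, float)
        return self.shaft_bow * np.sin(np.pi * z / self.bone_length)

    def outer_semi_axes(self, z):
        a = self.shaft_outer_radius * self._flare(z)
        return a, a * (1.0 - self.cross_section_eccentricity)

    def canal_semi_axes(self, z):
        """Canal cross-section; tapers closed 10 mm before each bone end."""
        taper = 10.0
        z = np.asarray(z, float)
        d = np.minimum(z, self.bone_length - z) - taper
        s = np.clip(d / taper, 0.0, 1.0)
        a = self.canal_radius * s * s * (3 - 2 * s)
        return a, a * (1.0 - self.cross_section_eccentricity)


@dataclass
class BonePhantom:
    volume: VolumeImage
    ground_truth_mesh: trimesh.Trimesh
    tissue_label_map: np.ndarray
    spec: PhantomSpec


@dataclass(frozen=True)
class ObserverErrorModel:
    """Per-axis Gaussian placement noise in the planned box's local frame.

    Defaults are calibrated so simulated absolute-error summaries land in
    the range reported for trained human observers placing conforming
    guides on dissected bones: the along-bone (z) components dominate both
    translation and rotation.
    """

    translation_sd: tuple = (1.0, 0.5, 2.6)  # mm per local axis
    rotation_sd: tuple = (0.8, 0.6, 4.4)  # degrees per local axis
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "translation_sd", tuple(self.translation_sd))
        object.__setattr__(self, "rotation_sd", tuple(self.rotation_sd))
        if any(s < 0 for s in self.translation_sd) or any(s < 0 for s in self.rotation_sd):
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class ScanNoiseModel:
    """Optical-scan emulation: vertex jitter, resampling, unknown offset."""

    vertex_jitter_sd: float = 0.1  # mm, per coordinate
    resample_density: float = 3.0  # target vertices per mm^2
    offset_translation_mm: float = 5.0
    offset_rotation_deg: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.vertex_jitter_sd < 0:
            raise ValueError("vertex_jitter_sd must be >= 0")


@dataclass
class OpticalScan:
    """An emulated optical scan and (for oracles only) the rigid offset
    that was applied; registration back to the source should recover its
    inverse."""

    mesh: trimesh.Trimesh
    true_offset: RigidTransform


@dataclass
class GuideDesign:
    guide_mesh: trimesh.Trimesh
    planned_box_pose: BoxPose
    location: str  # proximal | distal
    bone_side: str  # radius | ulna
    guide_length: float = GUIDE_LENGTH_MM
    box_dims: tuple = DEFAULT_BOX_DIMS


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _superellipse_inside(X, Y, a, b, p=_SUPERELLIPSE_P):
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (np.abs(X) / a) ** p + (np.abs(Y) / b) ** p
    return np.where(a > 0, v <= 1.0, False)


def _superellipse_ring(theta, a, b, p=_SUPERELLIPSE_P):
    """(x, y) boundary points of the superellipse at parameter angles."""
    c, s = np.cos(theta), np.sin(theta)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / p)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / p)
    return x, y


def _closed_tube(z_rings, ring_xy_fn, n_theta, invert=False):
    """Watertight tube: rings along z closed with apex fans at both ends.

    ``ring_xy_fn(z, theta) -> (x, y)``. Windings give outward normals
    (CCW rings, +z up); ``invert=True`` flips them (for cavity walls,
    where out-of-material points toward the axis).
    """
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    verts = []
    for z in z_rings:
        x, y = ring_xy_fn(z, theta)
        verts.append(np.column_stack([x, y, np.full(n_theta, z)]))
    verts = np.vstack(verts)
    n_z = len(z_rings)
    apex_lo = len(verts)
    apex_hi = apex_lo + 1
    verts = np.vstack([verts, [0.0, 0.0, z_rings[0]], [0.0, 0.0, z_rings[-1]]])

    faces = []
    for k in range(n_z - 1):
        for j in range(n_theta):
            a = k * n_theta + j
            b = k * n_theta + (j + 1) % n_theta
            c = (k + 1) * n_theta + (j + 1) % n_theta
            d = (k + 1) * n_theta + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([apex_lo, jn, j])
        faces.append([apex_hi, (n_z - 1) * n_theta + j, (n_z - 1) * n_theta + jn])
    faces = np.asarray(faces)
    if invert:
        faces = faces[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _ground_truth_mesh(spec: PhantomSpec, n_z=121, n_theta=48) -> trimesh.Trimesh:
    """Analytic cortical-bone surface: outer shell plus canal wall.

    Two watertight components, both wound with normals pointing out of the
    bone material (the canal wall's point toward the axis), so signed
    distances are positive outside the material everywhere.
    """
    z_outer = np.linspace(0.0, spec.bone_length, n_z)

    def outer_xy(z, theta):
        a, b = spec.outer_semi_axes(z)
        x, y = _superellipse_ring(theta, a, b)
        return x + spec.bow_offset(z), y

    outer = _closed_tube(z_outer, outer_xy, n_theta)

    # canal spans where its radius is positive; shrink rings to a tiny
    # positive radius at the end rings so apex fans close the wall cleanly
    taper = 10.0
    z0, z1 = taper, spec.bone_length - taper
    z_canal = np.linspace(z0 + 1e-3, z1 - 1e-3, max(2, int(n_z * 0.8)))

    def canal_xy(z, theta):
        a, b = spec.canal_semi_axes(z)
        x, y = _superellipse_ring(theta, max(a, 1e-4), max(b, 1e-4))
        return x + spec.bow_offset(z), y

    canal = _closed_tube(z_canal, canal_xy, max(16, n_theta // 2), invert=True)
    return trimesh.util.concatenate([outer, canal])


def generate_bone_phantom(spec: PhantomSpec) -> BonePhantom:
    """Rasterize a phantom volume plus its analytic ground-truth surface.

    Deterministic for a fixed spec (including its seed). The tendon blob,
    when enabled, is assigned only to voxels that are soft tissue, so it
    is disjoint from the bone classes by construction.
    """
    rng = np.random.default_rng(spec.seed)
    sx, sy, sz = spec.voxel_spacing
    max_a = spec.shaft_outer_radius * spec.end_flare_factor
    margin_xy = 6.0 + spec.shaft_bow + (4.0 if spec.tendon_blob else 0.0)
    half_extent = max_a + margin_xy
    margin_z = 5.0
    nx = int(np.ceil(2 * half_extent / sx)) + 1
    ny = int(np.ceil(2 * half_extent / sy)) + 1
    nz = int(np.ceil((spec.bone_length + 2 * margin_z) / sz)) + 1
    origin = np.array([-half_extent, -half_extent, -margin_z])

    X = (origin[0] + sx * np.arange(nx))[:, None, None]
    Y = (origin[1] + sy * np.arange(ny))[None, :, None]
    zv = origin[2] + sz * np.arange(nz)
    Z = zv[None, None, :]

    in_bone_z = (zv >= 0.0) & (zv <= spec.bone_length)
    ao, bo = spec.outer_semi_axes(zv)
    ac, bc = spec.canal_semi_axes(zv)
    Xc = X - spec.bow_offset(zv)[None, None, :]
    inside_outer = _superellipse_inside(Xc, Y, ao[None, None, :], bo[None, None, :])
    inside_outer &= in_bone_z[None, None, :]
    inside_canal = _superellipse_inside(Xc, Y, ac[None, None, :], bc[None, None, :])
    inside_canal &= inside_outer

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[inside_outer] = LABEL_CORTICAL
    labels[inside_canal] = LABEL_MEDULLARY

    if spec.tendon_blob:
        # calcified-tendon false positive: an elongated blob lying next to
        # (never touching) the cortex
        zb = 0.35 * spec.bone_length
        ab_z = spec.outer_semi_axes(zb)[0]
        center = np.array([spec.bow_offset(zb) + ab_z + 0.8 + 2.5, 0.0, zb])
        radii = np.array([2.5, 2.0, 9.0])
        blob = (
            ((X - center[0]) / radii[0]) ** 2
            + ((Y - center[1]) / radii[1]) ** 2
            + ((Z - center[2]) / radii[2]) ** 2
        ) <= 1.0
        labels[blob & (labels == LABEL_SOFT)] = LABEL_TENDON

    means = np.zeros(4)
    sds = np.zeros(4)
    for lab in range(4):
        means[lab] = spec.intensity_means.get(lab, 0.0)
        sds[lab] = spec.intensity_sds.get(lab, 0.0)
    if spec.modality == "sct_like":
        sds = sds * spec.sct_noise_scale

    intensities = means[labels] + sds[labels] * rng.standard_normal(labels.shape)

    if spec.modality == "sct_like" and spec.end_inhomogeneity:
        # low-frequency negative bias where the network saw little training
        # data: near the axial ends of the bone
        d_end = np.minimum(np.abs(zv - 0.0), np.abs(zv - spec.bone_length))
        w = np.clip(1.0 - d_end / 12.0, 0.0, 1.0) ** 2
        phase = rng.uniform(0, 2 * np.pi)
        g = 0.5 + 0.5 * np.cos(2 * np.pi * X / 25.0 + np.pi * Y / 20.0 + phase)
        intensities -= spec.end_bias_amplitude * w[None, None, :] * g

    volume = VolumeImage(
        intensities=intensities, voxel_spacing=np.array([sx, sy, sz]), origin=origin
    )
    return BonePhantom(
        volume=volume,
        ground_truth_mesh=_ground_truth_mesh(spec),
        tissue_label_map=labels,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Saw guide design
# ---------------------------------------------------------------------------

def _bone_axis_frame(bone: trimesh.Trimesh):
    """Long axis of the bone (unit, pointing toward +world-z = proximal),
    the centroid, and the projected extent along the axis."""
    verts = bone.vertices.view(np.ndarray)
    centroid = verts.mean(axis=0)
    _, _, Vt = np.linalg.svd(verts - centroid, full_matrices=False)
    axis = Vt[0]
    if axis[2] < 0:
        axis = -axis
    proj = (verts - centroid) @ axis
    return axis, centroid, float(proj.min()), float(proj.max())


def design_saw_guide(
    bone: trimesh.Trimesh,
    location: str,
    side: str = "radius",
    guide_length: float = GUIDE_LENGTH_MM,
    box_dims: tuple = DEFAULT_BOX_DIMS,
    clearance: float = 0.15,
    thickness: float = 3.0,
    coverage_deg: float = 160.0,
    n_axial: int = 17,
    n_circ: int = 21,
) -> GuideDesign:
    """Design a half-cylinder saw guide conforming to the bone surface.

    The guide is the region between two offset copies of the local bone
    surface (inner offset = ``clearance``, outer = clearance + thickness),
    bounded by two planes perpendicular to the bone axis (the axial extent)
    and two angular cuts (the cylinder halves). The inner surface is probed
    by bisecting the bone's signed distance field along radial rays, so it
    conforms to the actual surface, not to an idealized cylinder.

    The planned reference box sits on top of the guide at its axial
    midpoint; its local z points proximally (along the bone axis), local y
    away from the bone, local x completes the right-handed frame.
    """
    if location not in ("proximal", "distal"):
        raise ValueError(f"location must be proximal or distal, got {location!r}")
    if any(d <= 0 for d in box_dims):
        raise ValueError("box dims must be positive")
    axis, centroid, lo, hi = _bone_axis_frame(bone)
    length = hi - lo
    frac = 0.70 if location == "proximal" else 0.30
    center_s = lo + frac * length
    s0, s1 = center_s - guide_length / 2.0, center_s + guide_length / 2.0
    end_margin = 0.12 * length  # keep off the flared joint ends
    if s0 < lo + end_margin or s1 > hi - end_margin:
        raise ValueError(
            f"guide segment [{s0:.1f}, {s1:.1f}] mm extends past the usable "
            f"shaft [{lo + end_margin:.1f}, {hi - end_margin:.1f}] mm"
        )

    # local frame around the axis: e_y is the "away from bone" direction
    world_y = np.array([0.0, 1.0, 0.0])
    e_y = world_y - (world_y @ axis) * axis
    if np.linalg.norm(e_y) < 1e-6:
        e_y = np.array([1.0, 0.0, 0.0]) - (axis[0]) * axis
    e_y /= np.linalg.norm(e_y)
    e_x = np.cross(e_y, axis)

    query = SurfaceQuery(bone)
    s_grid = np.linspace(s0, s1, n_axial)
    half = np.radians(coverage_deg / 2.0)
    t_grid = np.linspace(-half, half, n_circ)
    S, T = np.meshgrid(s_grid, t_grid, indexing="ij")
    dirs = (
        np.cos(T.ravel())[:, None] * e_y[None, :]
        + np.sin(T.ravel())[:, None] * e_x[None, :]
    )
    bases = centroid[None, :] + S.ravel()[:, None] * axis[None, :]

    # bisect the surface crossing along each radial ray
    r_lo = np.zeros(len(bases))
    r_hi = np.full(len(bases), float(np.ptp(bone.vertices, axis=0).max()))
    for _ in range(22):
        mid = 0.5 * (r_lo + r_hi)
        sd = query.signed_distance(bases + mid[:, None] * dirs)
        inside = sd < 0
        r_lo = np.where(inside, mid, r_lo)
        r_hi = np.where(inside, r_hi, mid)
    r_surf = (0.5 * (r_lo + r_hi)).reshape(n_axial, n_circ)

    r_in = r_surf + clearance
    r_out = r_surf + clearance + thickness
    grid_dirs = dirs.reshape(n_axial, n_circ, 3)
    grid_base = bases.reshape(n_axial, n_circ, 3)
    inner = grid_base + r_in[..., None] * grid_dirs
    outer = grid_base + r_out[..., None] * grid_dirs
    guide_mesh = _shell_between_sheets(inner, outer)

    mid_i = n_axial // 2
    r_top = r_out[mid_i, n_circ // 2]
    box_origin = centroid + center_s * axis + (r_top + box_dims[1] / 2.0) * e_y
    box_axes = np.column_stack([np.cross(e_y, axis), e_y, axis])
    pose = BoxPose(origin=box_origin, axes=box_axes, dims=tuple(box_dims))
    return GuideDesign(
        guide_mesh=guide_mesh,
        planned_box_pose=pose,
        location=location,
        bone_side=side,
        guide_length=guide_length,
        box_dims=tuple(box_dims),
    )


def _shell_between_sheets(inner: np.ndarray, outer: np.ndarray) -> trimesh.Trimesh:
    """Closed shell between two (n, m, 3) open sheets sharing a grid."""
    n, m, _ = inner.shape
    verts = np.vstack([inner.reshape(-1, 3), outer.reshape(-1, 3)])
    off = n * m

    def vid(sheet, i, j):
        return sheet * off + i * m + j

    faces = []

    def quad(a, b, c, d):
        faces.append([a, b, c])
        faces.append([a, c, d])

    for i in range(n - 1):
        for j in range(m - 1):
            # inner sheet: normals toward the bone (down the radial dirs)
            quad(vid(0, i, j), vid(0, i, j + 1), vid(0, i + 1, j + 1), vid(0, i + 1, j))
            # outer sheet: opposite winding
            quad(vid(1, i, j), vid(1, i + 1, j), vid(1, i + 1, j + 1), vid(1, i, j + 1))
    for j in range(m - 1):  # axial end walls
        quad(vid(0, 0, j), vid(1, 0, j), vid(1, 0, j + 1), vid(0, 0, j + 1))
        quad(vid(0, n - 1, j), vid(0, n - 1, j + 1), vid(1, n - 1, j + 1), vid(1, n - 1, j))
    for i in range(n - 1):  # angular edge walls
        quad(vid(0, i, 0), vid(0, i + 1, 0), vid(1, i + 1, 0), vid(1, i, 0))
        quad(vid(0, i, m - 1), vid(1, i, m - 1), vid(1, i + 1, m - 1), vid(0, i + 1, m - 1))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# Placement and scan simulation
# ---------------------------------------------------------------------------

def simulate_placement(
    planned: BoxPose,
    model: ObserverErrorModel,
    rng: np.random.Generator | None = None,
) -> BoxPose:
    """One simulated observer placement of a guide.

    Perturbs the planned pose by independent per-axis Gaussian translation
    (in the planned box's local frame) and rotation about the box centroid
    (fixed-axes X-Y-Z angles). With all SDs zero the planned pose is
    returned unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    t_local = rng.normal(0.0, model.translation_sd)
    angles = rng.normal(0.0, model.rotation_sd)
    noise = RigidTransform.from_euler_xyz(angles, t_local)
    return BoxPose(
        origin=planned.origin + planned.axes @ noise.translation,
        axes=planned.axes @ noise.rotation,
        dims=planned.dims,
    )


def simulate_optical_scan(
    mesh: trimesh.Trimesh,
    model: ScanNoiseModel,
    rng: np.random.Generator | None = None,
) -> OpticalScan:
    """Emulate an optical 3D scan of a mesh.

    The mesh is resampled (subdivided until the vertex density reaches the
    model's target), vertices are jittered with isotropic Gaussian noise,
    and an unknown rigid offset is applied. The offset is retained on the
    returned object purely as a test oracle.
    """
    if len(mesh.vertices) == 0:
        raise ValueError("cannot scan an empty mesh")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    scan = mesh.copy()
    if model.resample_density > 0 and scan.area > 0:
        for _ in range(3):
            if len(scan.vertices) / scan.area >= model.resample_density:
                break
            scan = scan.subdivide()
    if model.vertex_jitter_sd > 0:
        scan.vertices = scan.vertices + rng.normal(
            0.0, model.vertex_jitter_sd, size=scan.vertices.shape
        )
    if model.offset_rotation_deg > 0 or model.offset_translation_mm > 0:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        t_dir = rng.standard_normal(3)
        t_dir /= np.linalg.norm(t_dir)
        from scipy.spatial.transform import Rotation

        offset = RigidTransform(
            rotation=Rotation.from_rotvec(
                np.radians(model.offset_rotation_deg) * axis
            ).as_matrix(),
            translation=model.offset_translation_mm * t_dir,
        )
    else:
        offset = RigidTransform.identity()
    scan.apply_transform(offset.matrix)
    return OpticalScan(mesh=scan, true_offset=offset)
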