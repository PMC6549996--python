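"""Synthetic morphable face space: procedural face population, PCA model, synthesis.

A face is represented by a fixed-topology triangle mesh (shape) and a square
RGB texture map (reflectance).  The face space is the classic morphable-model
construction: a mean face plus a weighted sum of principal-component offset
vectors, fitted independently for shape and reflectance.  Each offset row is
scaled so that a coefficient of 1 moves the face by one training-population
standard deviation along that component.

The procedural template replaces a commercial face generator: a head-shaped
mesh with named, compactly supported displacement fields (eye size, nose size,
jaw width, mouth width, gender) and a skin texture with colour modulation
maps.  It is a stand-in with the same algebraic structure, not a photoreal
model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import linalg

__all__ = [
    "SemanticFaceParams",
    "FaceGeometry",
    "FaceTemplate",
    "FaceSpaceModel",
    "FaceCoefficients",
    "make_template",
    "generate_semantic_face",
    "sample_population",
    "fit_face_space",
    "synthesize",
    "project",
    "save_model",
    "load_model",
    "export_obj",
    "export_texture_png",
]

SEMANTIC_SHAPE_PARAMS = ("eye_size", "nose_size", "jaw_width", "mouth_width")
SEMANTIC_COLOR_PARAMS = ("skin_lightness", "skin_redness", "skin_yellowness")


@dataclass(frozen=True)
class SemanticFaceParams:
    """Human-interpretable face controls, all z-scaled deformation weights.

    ``gender_control`` runs from -4 (extremely masculine) to +4 (extremely
    feminine); its sign determines the sex label.  The remaining parameters
    weight localized displacement fields (shape) or colour modulation maps
    (reflectance) of the template.
    """

    gender_control: float = 0.0
    eye_size: float = 0.0
    nose_size: float = 0.0
    jaw_width: float = 0.0
    mouth_width: float = 0.0
    skin_lightness: float = 0.0
    skin_redness: float = 0.0
    skin_yellowness: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gender_control", *SEMANTIC_SHAPE_PARAMS, *SEMANTIC_COLOR_PARAMS):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite semantic parameter {name!r}: {v}")

    @property
    def sex(self) -> str:
        return "male" if self.gender_control < 0 else "female"


@dataclass
class FaceGeometry:
    """One face: vertex positions, shared triangle topology, RGB texture in [0, 1]."""

    vertices: np.ndarray  # (N_s, 3) float
    faces: np.ndarray  # (M, 3) int
    texture: np.ndarray  # (T, T, 3) float, row-major, origin top-left

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int32)
        self.texture = np.asarray(self.texture, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.texture.ndim != 3 or self.texture.shape[0] != self.texture.shape[1]:
            raise ValueError("texture must be a square (T, T, 3) grid")
        if not np.isfinite(self.vertices).all():
            raise ValueError("NaN/inf vertex coordinates")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def texture_size(self) -> int:
        return self.texture.shape[0]


@dataclass
class FaceCoefficients:
    """A face's position in the PCA face space.

    ``shape_coeffs`` and ``reflectance_coeffs`` are in per-PC standard
    deviation units (a value of 1 = one training-population s.d. along that
    component).  ``gender_control`` is a separate dial, not one of the PCs.
    """

    shape_coeffs: np.ndarray
    reflectance_coeffs: np.ndarray
    sex: str | None = None
    gender_control: float = 0.0

    def __post_init__(self) -> None:
        self.shape_coeffs = np.asarray(self.shape_coeffs, dtype=float)
        self.reflectance_coeffs = np.asarray(self.reflectance_coeffs, dtype=float)
        if not (
            np.isfinite(self.shape_coeffs).all()
            and np.isfinite(self.reflectance_coeffs).all()
            and np.isfinite(self.gender_control)
        ):
            raise ValueError("non-finite face coefficients")

    def concat(self) -> np.ndarray:
        """Concatenated (shape, reflectance) coefficient vector."""
        return np.concatenate([self.shape_coeffs, self.reflectance_coeffs])

    def copy(self) -> "FaceCoefficients":
        return FaceCoefficients(
            self.shape_coeffs.copy(),
            self.reflectance_coeffs.copy(),
            sex=self.sex,
            gender_control=self.gender_control,
        )


# ---------------------------------------------------------------------------
# Procedural template
# ---------------------------------------------------------------------------


@dataclass
class FaceTemplate:
    """Procedural base head with named displacement fields and colour maps."""

    base_vertices: np.ndarray  # (N, 3)
    faces: np.ndarray  # (M, 3) int
    uv: np.ndarray  # (N, 2)
    base_texture: np.ndarray  # (T, T, 3)
    shape_fields: dict  # name -> (N, 3) displacement field
    color_maps: dict  # name -> (T, T, 3) modulation map
    idio_shape_fields: np.ndarray  # (n_idio, N, 3)
    idio_texture_fields: np.ndarray  # (n_idio, T, T, 3)
    landmarks: dict  # name -> unit direction on the head sphere
    seed: int = 0

    @property
    def n_vertices(self) -> int:
        return self.base_vertices.shape[0]

    @property
    def texture_size(self) -> int:
        return self.base_texture.shape[0]

    def landmark_region(self, name: str, radius: float) -> np.ndarray:
        """Boolean vertex mask within ``radius`` (radians) of a landmark."""
        d = _unit(self.base_vertices)
        c = self.landmarks[name]
        ang = np.arccos(np.clip(d @ c, -1.0, 1.0))
        return ang < radius


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _sphere_dir(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [np.sin(theta) * np.sin(phi), np.cos(theta), np.sin(theta) * np.cos(phi)]
    )


def _bump(directions: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Compactly supported smooth weight around a spherical landmark."""
    ang = np.arccos(np.clip(directions @ center, -1.0, 1.0))
    w = np.zeros(len(directions))
    inside = ang < radius
    w[inside] = (1.0 - (ang[inside] / radius) ** 2) ** 2
    return w


def _smooth_sphere_field(rng: np.random.Generator, directions: np.ndarray) -> np.ndarray:
    """Random smooth scalar field on the sphere (sum of low-frequency waves)."""
    f = np.zeros(len(directions))
    for _ in range(6):
        d = _unit(rng.normal(size=3))
        omega = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        f += rng.normal() * np.cos(omega * (directions @ d) + phase)
    return f / np.sqrt(6.0)


def _smooth_grid_field(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random smooth scalar field on a size x size grid (low-frequency cosines)."""
    yy, xx = np.meshgrid(
        np.linspace(0, 1, size), np.linspace(0, 1, size), indexing="ij"
    )
    f = np.zeros((size, size))
    for _ in range(6):
        kx, ky = rng.integers(0, 4, size=2)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        f += rng.normal() * np.cos(2 * np.pi * kx * xx + px) * np.cos(
            2 * np.pi * ky * yy + py
        )
    return f / np.sqrt(6.0)


def make_template(
    n_lat: int = 12,
    n_lon: int = 12,
    texture_size: int = 64,
    n_idio_shape: int = 48,
    n_idio_texture: int = 48,
    seed: int = 0,
) -> FaceTemplate:
    """Build the procedural head template.

    The mesh is a latitude/longitude sphere grid (``n_lat * n_lon + 2``
    vertices including poles) deformed into a head shape: the face looks
    along +z, +y is up.  The default 12 x 12 grid gives 146 vertices; a
    13 x 157 grid gives the full-resolution 2043.
    """
    rng = np.random.default_rng(seed)

    thetas = np.pi * (np.arange(1, n_lat + 1)) / (n_lat + 1)
    phis = 2 * np.pi * np.arange(n_lon) / n_lon
    dirs = [np.array([0.0, 1.0, 0.0])]
    uv = [np.array([0.5, 1.0])]
    for th in thetas:
        for ph in phis:
            dirs.append(_sphere_dir(th, ph))
            uv.append(np.array([ph / (2 * np.pi), 1.0 - th / np.pi]))
    dirs.append(np.array([0.0, -1.0, 0.0]))
    uv.append(np.array([0.5, 0.0]))
    directions = np.array(dirs)
    uv = np.array(uv)

    # head shape: ellipsoid, tapered toward the chin
    theta_v = np.arccos(np.clip(directions[:, 1], -1, 1))
    taper = 1.0 - 0.25 * np.clip((theta_v - np.pi / 2) / (np.pi / 2), 0, 1) ** 2
    radii = np.array([0.80, 1.00, 0.85])
    base_vertices = directions * radii * taper[:, None]

    faces = []
    idx = lambda i, j: 1 + i * n_lon + (j % n_lon)  # noqa: E731
    for j in range(n_lon):  # top cap
        faces.append([0, idx(0, j), idx(0, j + 1)])
    for i in range(n_lat - 1):
        for j in range(n_lon):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j), idx(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    south = 1 + n_lat * n_lon
    for j in range(n_lon):  # bottom cap
        faces.append([south, idx(n_lat - 1, j + 1), idx(n_lat - 1, j)])
    faces = np.array(faces, dtype=np.int32)

    lm = {
        "left_eye": _sphere_dir(0.40 * np.pi, +0.28),
        "right_eye": _sphere_dir(0.40 * np.pi, -0.28),
        "nose": _sphere_dir(0.58 * np.pi, 0.0),
        "left_mouth": _sphere_dir(0.70 * np.pi, +0.20),
        "right_mouth": _sphere_dir(0.70 * np.pi, -0.20),
        "left_jaw": _sphere_dir(0.80 * np.pi, +0.55),
        "right_jaw": _sphere_dir(0.80 * np.pi, -0.55),
        "brow": _sphere_dir(0.30 * np.pi, 0.0),
        "chin": _sphere_dir(0.92 * np.pi, 0.0),
    }

    normal = directions  # radial outward
    lateral = np.zeros_like(directions)
    lateral[:, 0] = np.sign(directions[:, 0])

    def radial(*names, radius):
        w = sum(_bump(directions, lm[n], radius) for n in names)
        return w[:, None] * normal

    def sideways(*names, radius):
        w = sum(_bump(directions, lm[n], radius) for n in names)
        return w[:, None] * lateral

    shape_fields = {
        "eye_size": 0.05 * radial("left_eye", "right_eye", radius=0.24),
        "nose_size": 0.05 * radial("nose", radius=0.22),
        "jaw_width": 0.05 * sideways("left_jaw", "right_jaw", radius=0.28),
        "mouth_width": 0.04 * sideways("left_mouth", "right_mouth", radius=0.16),
        # feminine direction: softer brow/chin, slightly larger eyes
        "gender_control": (
            -0.015 * radial("brow", radius=0.30)
            - 0.015 * radial("chin", radius=0.30)
            + 0.008 * radial("left_eye", "right_eye", radius=0.24)
        ),
    }

    # skin: base tone plus deterministic low-frequency mottling
    base_tone = np.array([0.80, 0.62, 0.50])
    T = texture_size
    mottle = _smooth_grid_field(rng, T)
    base_texture = np.clip(base_tone + 0.015 * mottle[:, :, None], 0.0, 1.0)

    cheeks = np.zeros((T, T))
    yy, xx = np.meshgrid(np.linspace(0, 1, T), np.linspace(0, 1, T), indexing="ij")
    for cx in (0.3, 0.7):
        cheeks += np.exp(-(((xx - cx) / 0.18) ** 2 + ((yy - 0.45) / 0.22) ** 2))
    cheeks = 0.5 + 0.5 * cheeks / cheeks.max()
    color_maps = {
        "skin_lightness": 0.03 * np.ones((T, T, 1)) * np.ones(3),
        "skin_redness": 0.03 * cheeks[:, :, None] * np.array([1.0, -0.3, -0.3]),
        "skin_yellowness": 0.03 * cheeks[:, :, None] * np.array([0.7, 0.7, -1.0]),
    }

    idio_shape = np.empty((n_idio_shape, len(directions), 3))
    for j in range(n_idio_shape):
        idio_shape[j] = 0.02 * _smooth_sphere_field(rng, directions)[:, None] * normal
    idio_tex = np.empty((n_idio_texture, T, T, 3))
    for j in range(n_idio_texture):
        for c in range(3):
            idio_tex[j, :, :, c] = 0.02 * _smooth_grid_field(rng, T)

    return FaceTemplate(
        base_vertices=base_vertices,
        faces=faces,
        uv=uv,
        base_texture=base_texture,
        shape_fields=shape_fields,
        color_maps=color_maps,
        idio_shape_fields=idio_shape,
        idio_texture_fields=idio_tex,
        landmarks=lm,
        seed=seed,
    )


def generate_semantic_face(
    params: SemanticFaceParams, template: FaceTemplate
) -> FaceGeometry:
    """Deterministically synthesize a face from semantic controls.

    Geometry is the base mesh plus the weighted sum of the template's named
    displacement fields; the texture is the base skin plus the weighted
    colour modulation maps, clipped to the physical [0, 1] channel bounds.
    """
    v = template.base_vertices.copy()
    v += params.gender_control * template.shape_fields["gender_control"]
    for name in SEMANTIC_SHAPE_PARAMS:
        v += getattr(params, name) * template.shape_fields[name]
    t = template.base_texture.copy()
    for name in SEMANTIC_COLOR_PARAMS:
        t += getattr(params, name) * template.color_maps[name]
    return FaceGeometry(v, template.faces, np.clip(t, 0.0, 1.0))


def sample_population(
    template: FaceTemplate,
    n: int,
    seed: int,
    semantic_sd: float = 1.0,
    idio_sd: float = 1.0,
    gender_control: float = 0.0,
) -> list[FaceGeometry]:
    """Draw a random face population for face-space fitting.

    Each face combines standard-normal semantic parameters with standard-
    normal weights on the template's idiosyncratic smooth shape and texture
    fields, so the population spans many more directions than the handful of
    semantic dials.  ``gender_control`` is held fixed (default neutral) so
    the fitted principal components stay orthogonal to the gender dial.
    """
    rng = np.random.default_rng(seed)
    faces = []
    for _ in range(n):
        sem = {
            name: semantic_sd * rng.normal()
            for name in (*SEMANTIC_SHAPE_PARAMS, *SEMANTIC_COLOR_PARAMS)
        }
        g = generate_semantic_face(
            SemanticFaceParams(gender_control=gender_control, **sem), template
        )
        zs = idio_sd * rng.normal(size=len(template.idio_shape_fields))
        g.vertices = g.vertices + np.tensordot(zs, template.idio_shape_fields, axes=1)
        zt = idio_sd * rng.normal(size=len(template.idio_texture_fields))
        g.texture = np.clip(
            g.texture + np.tensordot(zt, template.idio_texture_fields, axes=1), 0.0, 1.0
        )
        faces.append(g)
    return faces


# ---------------------------------------------------------------------------
# PCA face space
# ---------------------------------------------------------------------------


@dataclass
class FaceSpaceModel:
    """PCA face space: mean face plus per-s.d. principal offset rows.

    ``shape_basis`` row i is the shape offset produced by moving one training
    s.d. along shape PC i; likewise ``reflectance_basis``.  Rows are mutually
    orthogonal with squared norm equal to the corresponding ``per_pc_sd**2``.
    """

    mean_shape: np.ndarray  # (3 N_s,)
    mean_reflectance: np.ndarray  # (3 N_t,)
    shape_basis: np.ndarray  # (K_s, 3 N_s)
    reflectance_basis: np.ndarray  # (K_r, 3 N_t)
    per_pc_sd: np.ndarray  # (K_s + K_r,)
    topology: np.ndarray  # (M, 3) int32
    texture_size: int
    metadata: dict = field(default_factory=dict)

    @property
    def k_shape(self) -> int:
        return self.shape_basis.shape[0]

    @property
    def k_reflectance(self) -> int:
        return self.reflectance_basis.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.mean_shape.size // 3


def _pca_block(x: np.ndarray, k: int, what: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k PCA of rows of x; returns (mean, sd-scaled basis, per-PC sd)."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = linalg.svd(xc, full_matrices=False)
    sd = s / np.sqrt(n - 1)
    if sd[0] <= 1e-12:
        raise ValueError(f"zero-variance population: no principal {what} directions")
    if len(sd) < k or sd[k - 1] <= 1e-10 * sd[0]:
        raise ValueError(
            f"population rank below k={k} for {what}; add more varied faces"
        )
    vt = vt[:k]
    # deterministic sign: largest-magnitude loading positive
    signs = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    vt = vt * signs[:, None]
    return mean, sd[:k, None] * vt, sd[:k]


def fit_face_space(
    population: list[FaceGeometry], k_shape: int, k_reflectance: int
) -> FaceSpaceModel:
    """Fit independent shape and reflectance PCA spaces to a face population.

    Offsets are scaled so that the training population's coefficients have
    unit standard deviation on every component.
    """
    if len(population) <= max(k_shape, k_reflectance):
        raise ValueError("population must be larger than the requested rank")
    ref = population[0]
    for g in population[1:]:
        if g.n_vertices != ref.n_vertices or not np.array_equal(g.faces, ref.faces):
            raise ValueError("mismatched mesh topology in population")
        if g.texture.shape != ref.texture.shape:
            raise ValueError("mismatched texture grids in population")
    shapes = np.array([g.vertices.ravel() for g in population])
    textures = np.array([g.texture.ravel() for g in population])
    mean_s, basis_s, sd_s = _pca_block(shapes, k_shape, "shape")
    mean_t, basis_t, sd_t = _pca_block(textures, k_reflectance, "reflectance")
    return FaceSpaceModel(
        mean_shape=mean_s,
        mean_reflectance=mean_t,
        shape_basis=basis_s,
        reflectance_basis=basis_t,
        per_pc_sd=np.concatenate([sd_s, sd_t]),
        topology=ref.faces.astype(np.int32),
        texture_size=ref.texture_size,
        metadata={"population_size": len(population)},
    )


def synthesize(
    model: FaceSpaceModel, coeffs: FaceCoefficients, clip_texture: bool = True
) -> FaceGeometry:
    """Mean face plus the coefficient-weighted sum of PC offsets.

    Texture channels are clipped to [0, 1] after the linear sum (physical
    bounds); shape is never clipped.
    """
    if coeffs.shape_coeffs.size != model.k_shape:
        raise ValueError("shape coefficient dimension does not match model")
    if coeffs.reflectance_coeffs.size != model.k_reflectance:
        raise ValueError("reflectance coefficient dimension does not match model")
    shape = model.mean_shape + coeffs.shape_coeffs @ model.shape_basis
    refl = model.mean_reflectance + coeffs.reflectance_coeffs @ model.reflectance_basis
    if clip_texture:
        refl = np.clip(refl, 0.0, 1.0)
    T = model.texture_size
    return FaceGeometry(
        shape.reshape(-1, 3), model.topology, refl.reshape(T, T, 3)
    )


def project(model: FaceSpaceModel, geometry: FaceGeometry) -> FaceCoefficients:
    """Least-squares coefficients of a geometry in the face space.

    For in-space geometry this inverts :func:`synthesize` exactly (before
    texture clipping); otherwise it returns the closest in-space
    approximation, with residual orthogonal to every basis row.
    """
    if geometry.n_vertices != model.n_vertices or not np.array_equal(
        geometry.faces, model.topology
    ):
        raise ValueError("geometry topology does not match model")
    if geometry.texture_size != model.texture_size:
        raise ValueError("texture grid does not match model")
    sd = model.per_pc_sd
    xs = geometry.vertices.ravel() - model.mean_shape
    xt = geometry.texture.ravel() - model.mean_reflectance
    ks = model.k_shape
    alpha = (model.shape_basis @ xs) / sd[:ks] ** 2
    tau = (model.reflectance_basis @ xt) / sd[ks:] ** 2
    return FaceCoefficients(alpha, tau)


# ---------------------------------------------------------------------------
# Container and export formats
# ---------------------------------------------------------------------------

_ARRAYS = {
    "mean_shape": "<f8",
    "mean_reflectance": "<f8",
    "shape_basis": "<f8",
    "reflectance_basis": "<f8",
    "per_pc_sd": "<f8",
    "topology": "<i4",
}


def save_model(model: FaceSpaceModel, path: str | Path) -> Path:
    """Write the model container: JSON manifest + flat little-endian arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "facevector-model-v1",
        "n_vertices": model.n_vertices,
        "texture_size": model.texture_size,
        "k_shape": model.k_shape,
        "k_reflectance": model.k_reflectance,
        "metadata": model.metadata,
        "arrays": {},
    }
    for name, dtype in _ARRAYS.items():
        arr = getattr(model, name)
        np.ascontiguousarray(arr, dtype=dtype).tofile(path / f"{name}.bin")
        manifest["arrays"][name] = {
            "file": f"{name}.bin",
            "dtype": dtype,
            "shape": list(arr.shape),
        }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_model(path: str | Path) -> FaceSpaceModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    arrays = {}
    for name, info in manifest["arrays"].items():
        arr = np.fromfile(path / info["file"], dtype=info["dtype"])
        arrays[name] = arr.reshape(info["shape"])
    return FaceSpaceModel(
        mean_shape=arrays["mean_shape"],
        mean_reflectance=arrays["mean_reflectance"],
        shape_basis=arrays["shape_basis"],
        reflectance_basis=arrays["reflectance_basis"],
        per_pc_sd=arrays["per_pc_sd"],
        topology=arrays["topology"].astype(np.int32),
        texture_size=manifest["texture_size"],
        metadata=manifest.get("metadata", {}),
    )


def export_obj(
    geometry: FaceGeometry, path: str | Path, uv: np.ndarray | None = None
) -> Path:
    """Export a face as Wavefront OBJ (with texture coordinates when given)."""
    import trimesh

    path = Path(path)
    visual = None
    if uv is not None:
        from trimesh.visual import TextureVisuals

        img = Image.fromarray(
            np.round(geometry.texture * 255).astype(np.uint8), mode="RGB"
        )
        visual = TextureVisuals(uv=uv, image=img)
    mesh = trimesh.Trimesh(
        vertices=geometry.vertices,
        faces=geometry.faces,
        visual=visual,
        process=False,
    )
    mesh.export(path)
    return path


def export_texture_png(geometry: FaceGeometry, path: str | Path) -> Path:
    """Export the reflectance map as an 8-bit RGB PNG."""
    path = Path(path)
    img = Image.fromarray(np.round(geometry.texture * 255).astype(np.uint8), mode="RGB")
    img.save(path)
    return path
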