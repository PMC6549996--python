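"""Estimating and applying the attractiveness direction in face space.

The core of the data-driven model.  With F the K x n matrix whose columns
are the rated faces' PC coefficients (as shown to raters) and r the vector of
mean standardized ratings, the attractiveness vector is

    t = F . r,        t_hat = t / ||t||

computed independently for the shape block and the reflectance block, per
sex.  Any face is made more or less attractive by moving its coefficients
along the unit direction:

    alpha' = alpha + delta * t_hat

where delta is in per-PC standard-deviation units.  Three manipulation modes
mirror the validation design: shape-and-reflectance, shape-only (reflectance
held at 0 s.d. change) and reflectance-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morphable import FaceCoefficients, FaceSpaceModel
from . import sampling

__all__ = [
    "AttractivenessVector",
    "ManipulationSpec",
    "MODES",
    "DEFAULT_DELTAS",
    "fit_attractiveness_vector",
    "manipulate",
    "build_validation_set",
    "save_vector",
    "load_vector",
]

MODES = ("shape_and_reflectance", "shape_only", "reflectance_only")
DEFAULT_DELTAS = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)


@dataclass
class AttractivenessVector:
    """Per-sex attractiveness direction: raw t and unit t_hat per block."""

    sex: str
    t_shape: np.ndarray
    t_reflectance: np.ndarray
    t_hat_shape: np.ndarray
    t_hat_reflectance: np.ndarray
    n_faces: int = 0
    model_ref: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t_hat_shape", "t_hat_reflectance"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a unit vector")

    def t_hat_joint(self) -> np.ndarray:
        """Unit vector over the concatenated 100-D space (alternative norm)."""
        t = np.concatenate([self.t_shape, self.t_reflectance])
        return t / np.linalg.norm(t)


@dataclass(frozen=True)
class ManipulationSpec:
    """How far (delta, in s.d. units) and in which mode to move a face.

    ``combined_normalization`` selects how the shape-and-reflectance mode
    scales the step: ``per_block`` (default) applies delta times each
    block's own unit vector (total displacement delta*sqrt(2)); ``joint``
    uses a single unit vector over the concatenated 100-D space.
    """

    delta: float
    mode: str
    combined_normalization: str = "per_block"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.combined_normalization not in ("per_block", "joint"):
            raise ValueError("combined_normalization must be 'per_block' or 'joint'")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")


def fit_attractiveness_vector(
    faces: list[FaceCoefficients], r, sex: str
) -> AttractivenessVector:
    """Estimate t = F.r and its unit direction from rated faces.

    ``faces`` are the stimuli as shown to raters (i.e. after any coefficient
    scaling); ``r`` is the face-aligned vector of mean standardized ratings.
    The shape and reflectance blocks are fitted independently and each
    normalized to a unit vector.
    """
    r = np.asarray(r, dtype=float).ravel()
    if len(faces) < 2:
        raise ValueError("need at least 2 rated faces")
    if len(r) != len(faces):
        raise ValueError(f"r has length {len(r)} but there are {len(faces)} faces")
    if not np.isfinite(r).all():
        raise ValueError("non-finite ratings")
    if np.all(r == 0):
        raise ValueError("r is all zeros: attractiveness direction undefined")
    for f in faces:
        if f.sex is not None and f.sex != sex:
            raise ValueError(f"face of sex {f.sex!r} in a {sex!r} fit")
    f_shape = np.column_stack([f.shape_coeffs for f in faces])  # K_s x n
    f_refl = np.column_stack([f.reflectance_coeffs for f in faces])  # K_r x n
    t_shape = f_shape @ r
    t_refl = f_refl @ r
    ns, nr = np.linalg.norm(t_shape), np.linalg.norm(t_refl)
    if ns == 0 or nr == 0:
        raise ValueError("||t|| = 0 in a block: direction undefined")
    return AttractivenessVector(
        sex=sex,
        t_shape=t_shape,
        t_reflectance=t_refl,
        t_hat_shape=t_shape / ns,
        t_hat_reflectance=t_refl / nr,
        n_faces=len(faces),
        metadata={"norm_shape": float(ns), "norm_reflectance": float(nr)},
    )


def manipulate(
    coeffs: FaceCoefficients, vector: AttractivenessVector, spec: ManipulationSpec
) -> FaceCoefficients:
    """Move a face delta s.d. along the attractiveness direction.

    shape_only changes only the shape block, reflectance_only only the
    reflectance block; shape_and_reflectance changes both.  The gender dial
    is never modified.
    """
    if coeffs.sex is not None and coeffs.sex != vector.sex:
        raise ValueError(
            f"face sex {coeffs.sex!r} does not match vector sex {vector.sex!r}"
        )
    if coeffs.shape_coeffs.size != vector.t_hat_shape.size:
        raise ValueError("shape coefficient dimension mismatch")
    if coeffs.reflectance_coeffs.size != vector.t_hat_reflectance.size:
        raise ValueError("reflectance coefficient dimension mismatch")
    out = coeffs.copy()
    d = spec.delta
    if spec.mode == "shape_only":
        out.shape_coeffs = out.shape_coeffs + d * vector.t_hat_shape
    elif spec.mode == "reflectance_only":
        out.reflectance_coeffs = out.reflectance_coeffs + d * vector.t_hat_reflectance
    elif spec.combined_normalization == "per_block":
        out.shape_coeffs = out.shape_coeffs + d * vector.t_hat_shape
        out.reflectance_coeffs = out.reflectance_coeffs + d * vector.t_hat_reflectance
    else:  # joint unit vector over the concatenated space
        joint = vector.t_hat_joint()
        ks = out.shape_coeffs.size
        out.shape_coeffs = out.shape_coeffs + d * joint[:ks]
        out.reflectance_coeffs = out.reflectance_coeffs + d * joint[ks:]
    return out


def build_validation_set(
    model: FaceSpaceModel,
    vector: AttractivenessVector,
    n_faces: int = 10,
    deltas=DEFAULT_DELTAS,
    seed: int = 0,
    scale_factor: float = 0.5,
    modes=MODES,
    combined_normalization: str = "per_block",
) -> list[tuple[str, float, str, FaceCoefficients]]:
    """Novel random base faces crossed with manipulation levels and modes.

    Returns one record (face_id, delta, mode, coefficients) per stimulus:
    with the defaults, 10 base faces x 7 levels (-3..+3) x 3 modes = 210
    stimuli for the vector's sex.  Base faces get the same coefficient
    scaling as training stimuli before manipulation.
    """
    deltas = tuple(deltas)
    if not deltas:
        raise ValueError("deltas must be non-empty")
    pool = sampling.sample_candidates(model, vector.sex, n_faces, seed)
    pool = sampling.scale_pool(pool, scale_factor)
    records = []
    for i, base in enumerate(pool.candidates):
        fid = f"{vector.sex}_val_{i:03d}"
        for delta in deltas:
            for mode in modes:
                spec = ManipulationSpec(
                    delta=delta, mode=mode, combined_normalization=combined_normalization
                )
                records.append((fid, float(delta), mode, manipulate(base, vector, spec)))
    return records


def save_vector(vector: AttractivenessVector, path: str | Path) -> Path:
    """Serialize as a JSON manifest plus flat float64 binary arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = ("t_shape", "t_reflectance", "t_hat_shape", "t_hat_reflectance")
    manifest = {
        "sex": vector.sex,
        "n_faces": vector.n_faces,
        "model_ref": vector.model_ref,
        "metadata": vector.metadata,
        "arrays": {},
    }
    for name in names:
        arr = getattr(vector, name)
        np.ascontiguousarray(arr, dtype="<f8").tofile(path / f"{name}.bin")
        manifest["arrays"][name] = {"file": f"{name}.bin", "shape": list(arr.shape)}
    (path / "vector.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_vector(path: str | Path) -> AttractivenessVector:
    path = Path(path)
    manifest = json.loads((path / "vector.json").read_text())
    arrays = {
        name: np.fromfile(path / info["file"], dtype="<f8").reshape(info["shape"])
        for name, info in manifest["arrays"].items()
    }
    return AttractivenessVector(
        sex=manifest["sex"],
        n_faces=manifest["n_faces"],
        model_ref=manifest.get("model_ref", ""),
        metadata=manifest.get("metadata", {}),
        **arrays,
    )
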