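"""Candidate face generation, maximum-diversity selection, coefficient scaling.

The stimulus-construction recipe: draw a large pool of random faces per sex
(independent standard-normal PC coefficients, a uniform gender-control value
in the sex's range), keep the subset that is maximally distinct by average
Euclidean distance in coefficient space, then shrink all PC coefficients by a
constant factor (default 0.5) to pull the stimuli toward the average face
while preserving their relative differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .morphable import FaceCoefficients, FaceSpaceModel

__all__ = [
    "CandidatePool",
    "GENDER_CONTROL_RANGES",
    "sample_candidates",
    "select_distinct",
    "scale_coefficients",
    "scale_pool",
    "pool_to_csv",
    "pool_from_csv",
]

# gender dial ranges per sex: negative = masculine, positive = feminine
GENDER_CONTROL_RANGES = {"male": (-4.0, -1.0), "female": (1.0, 4.0)}


@dataclass
class CandidatePool:
    """A set of same-sex candidate faces drawn from one face-space model."""

    sex: str
    candidates: list  # list[FaceCoefficients]
    seed: int | None = None
    model_ref: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.candidates)

    def coefficient_matrix(self) -> np.ndarray:
        """(n, K_s + K_r) matrix of concatenated PC coefficients."""
        return np.array([c.concat() for c in self.candidates])


def sample_candidates(
    model: FaceSpaceModel, sex: str, n: int, seed: int
) -> CandidatePool:
    """Draw ``n`` random candidate faces of one sex.

    Every PC coefficient is independent standard normal (one unit = one
    training s.d.); the gender control is uniform in the sex's range and is
    not part of the PC draw.
    """
    if sex not in GENDER_CONTROL_RANGES:
        raise ValueError(f"unknown sex label {sex!r}; expected 'male' or 'female'")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = GENDER_CONTROL_RANGES[sex]
    shape = rng.standard_normal((n, model.k_shape))
    refl = rng.standard_normal((n, model.k_reflectance))
    gender = rng.uniform(lo, hi, size=n)
    candidates = [
        FaceCoefficients(shape[i], refl[i], sex=sex, gender_control=gender[i])
        for i in range(n)
    ]
    return CandidatePool(
        sex=sex,
        candidates=candidates,
        seed=seed,
        model_ref=str(model.metadata.get("model_ref", "")),
        metadata={"n": n},
    )


def average_distances(pool: CandidatePool, chunk: int = 512) -> np.ndarray:
    """Average Euclidean distance from each candidate to all the others.

    Distances are taken in the concatenated PC coefficient space; the gender
    control is excluded (it is not one of the PCs).
    """
    x = pool.coefficient_matrix()
    n = len(x)
    sums = np.empty(n)
    for start in range(0, n, chunk):
        d = cdist(x[start : start + chunk], x)
        sums[start : start + chunk] = d.sum(axis=1)
    return sums / max(n - 1, 1)


def select_distinct(
    pool: CandidatePool, k: int, method: str = "average_distance"
) -> CandidatePool:
    """Select the ``k`` most distinctive candidates.

    ``average_distance`` (default) ranks every candidate by its average
    Euclidean distance to all other pool members and keeps the top ``k``;
    ties go to the lower original index.  ``greedy`` instead grows the
    subset by repeatedly adding the candidate farthest (max-min distance)
    from those already chosen — a classic max-diversity heuristic, exposed
    as an alternative reading of "greatest differences".
    """
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    if method == "average_distance":
        avg = average_distances(pool)
        order = np.argsort(-avg, kind="stable")  # stable: lower index wins ties
        chosen = order[:k]
    elif method == "greedy":
        x = pool.coefficient_matrix()
        avg = average_distances(pool)
        first = int(np.argmax(avg))
        chosen = [first]
        mind = np.linalg.norm(x - x[first], axis=1)
        mind[first] = -np.inf
        for _ in range(k - 1):
            nxt = int(np.argmax(mind))
            chosen.append(nxt)
            d = np.linalg.norm(x - x[nxt], axis=1)
            np.minimum(mind, d, out=mind)
            mind[nxt] = -np.inf
        chosen = np.array(chosen)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return CandidatePool(
        sex=pool.sex,
        candidates=[pool.candidates[i] for i in chosen],
        seed=pool.seed,
        model_ref=pool.model_ref,
        metadata={
            **pool.metadata,
            "selection_method": method,
            "selected_from": len(pool),
            "selected_indices": [int(i) for i in chosen],
        },
    )


def scale_coefficients(coeffs: FaceCoefficients, factor: float) -> FaceCoefficients:
    """Multiply every PC coefficient by ``factor``; the gender dial is untouched."""
    if not np.isfinite(factor):
        raise ValueError("scale factor must be finite")
    return FaceCoefficients(
        coeffs.shape_coeffs * factor,
        coeffs.reflectance_coeffs * factor,
        sex=coeffs.sex,
        gender_control=coeffs.gender_control,
    )


def scale_pool(pool: CandidatePool, factor: float) -> CandidatePool:
    return CandidatePool(
        sex=pool.sex,
        candidates=[scale_coefficients(c, factor) for c in pool.candidates],
        seed=pool.seed,
        model_ref=pool.model_ref,
        metadata={**pool.metadata, "scale_factor": factor},
    )


def pool_to_csv(pool: CandidatePool, path: str | Path) -> Path:
    """Serialize a pool as CSV plus a JSON sidecar with provenance."""
    path = Path(path)
    x = pool.coefficient_matrix()
    cols = {"face_id": np.arange(len(pool)), "sex": pool.sex}
    df = pd.DataFrame(cols)
    df["gender_control"] = [c.gender_control for c in pool.candidates]
    k_shape = pool.candidates[0].shape_coeffs.size if len(pool) else 0
    for j in range(x.shape[1]):
        df[f"pc_{j + 1:03d}"] = x[:, j]
    df.to_csv(path, index=False)
    sidecar = {
        "seed": pool.seed,
        "model_ref": pool.model_ref,
        "k_shape": k_shape,
        "metadata": pool.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def pool_from_csv(path: str | Path) -> CandidatePool:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pc_cols = [c for c in df.columns if c.startswith("pc_")]
    k_shape = sidecar["k_shape"]
    candidates = []
    for _, row in df.iterrows():
        vec = row[pc_cols].to_numpy(dtype=float)
        candidates.append(
            FaceCoefficients(
                vec[:k_shape],
                vec[k_shape:],
                sex=row["sex"],
                gender_control=float(row["gender_control"]),
            )
        )
    return CandidatePool(
        sex=df["sex"].iloc[0] if len(df) else "male",
        candidates=candidates,
        seed=sidecar.get("seed"),
        model_ref=sidecar.get("model_ref", ""),
        metadata=sidecar.get("metadata", {}),
    )
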