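"""Generalized Procrustes Analysis and vector-method dimorphism scoring.

The sexual-dimorphism score of a face is its position along the line
joining the mean female and mean male shape in Procrustes-aligned shape
space ("vector method").  All configurations — sex references and target
faces — are superimposed in a single joint GPA, the per-sex mean shapes
m_F and m_M are taken, and each target x is projected:

    raw(x) = (x - m_F) . (m_M - m_F) / ||m_M - m_F||^2

so the female mean scores 0, the male mean scores 1, and higher scores
are more male-like.  A z-scored version across the target sample is
provided for use with standardized regression downstream.

Superimposition is partial Procrustes: translation and centroid size are
removed, rotation is optimised, reflections are disallowed (faces have
handedness; a mirrored landmarking must not alias as shape change).  No
tangent-space projection or semilandmark sliding is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landmarks import LandmarkConfiguration

__all__ = [
    "AlignedSample",
    "DimorphismAxis",
    "DimorphismScores",
    "align_pair",
    "gpa",
    "dimorphism_axis",
    "score_faces",
    "dimorphism_pipeline",
]


def _as_matrix(shape) -> np.ndarray:
    if isinstance(shape, LandmarkConfiguration):
        return np.asarray(shape.points, dtype=float)
    arr = np.asarray(shape, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"shape must be (n, 2), got {arr.shape}")
    return arr


def _center_scale(X: np.ndarray) -> np.ndarray:
    """Remove translation and centroid size (unit-size centered form)."""
    Xc = X - X.mean(axis=0)
    size = np.sqrt((Xc**2).sum())
    if size <= 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return Xc / size


def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||X @ R - target||_F.

    Kabsch solution restricted to proper rotations: SVD of the
    cross-covariance with the smallest singular direction sign-flipped
    when the unconstrained optimum is a reflection.
    """
    H = X.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def align_pair(A, B) -> tuple[np.ndarray, float]:
    """Partial Procrustes superimposition of two configurations.

    Centers both, scales each to unit centroid size, and rotates A onto
    B without reflection.  Returns the rotation matrix and the residual
    root-summed-square (partial Procrustes) distance.
    """
    Xa, Xb = _as_matrix(A), _as_matrix(B)
    if Xa.shape != Xb.shape:
        raise ValueError(
            f"point counts differ: {Xa.shape[0]} vs {Xb.shape[0]}"
        )
    if Xa.shape[0] < 3:
        raise ValueError("need >= 3 landmarks")
    Za, Zb = _center_scale(Xa), _center_scale(Xb)
    R = _optimal_rotation(Za, Zb)
    dist = float(np.sqrt(((Za @ R - Zb) ** 2).sum()))
    return R, dist


@dataclass(frozen=True)
class AlignedSample:
    """Result of a joint GPA: aligned shapes plus their consensus.

    Every aligned shape has centroid (0, 0) and unit centroid size; the
    consensus is the coordinate-wise mean at convergence.
    """

    shapes: np.ndarray = field(repr=False)  # (n_shapes, n_points, 2)
    consensus: np.ndarray = field(repr=False)  # (n_points, 2)
    ids: tuple[str, ...]
    n_iterations: int

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Shapes flattened to (n_shapes, 2 * n_points) row vectors."""
        return self.shapes.reshape(self.n_shapes, -1)

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        """Flattened shapes for the given ids, in the given order."""
        index = {fid: i for i, fid in enumerate(self.ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise KeyError(f"ids not in aligned sample: {missing[:5]}")
        return self.flat()[[index[f] for f in ids]]


def gpa(
    configs: Sequence,
    ids: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes Analysis of two or more configurations.

    Iterates: rotate every centered, unit-size shape to the current
    consensus, recompute the consensus, renormalise it to unit size —
    until the consensus moves by less than ``tol`` (root-summed-square).

    Raises
    ------
    ValueError
        On fewer than 2 shapes, heterogeneous point counts, or failure
        to converge within ``max_iter`` iterations.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if ids is None:
        ids = tuple(
            c.face_id if isinstance(c, LandmarkConfiguration) else str(i)
            for i, c in enumerate(configs)
        )
    ids = tuple(ids)
    mats = [_as_matrix(c) for c in configs]
    n_points = mats[0].shape[0]
    for i, m in enumerate(mats):
        if m.shape[0] != n_points:
            raise ValueError(
                f"configuration {ids[i]!r} has {m.shape[0]} points, "
                f"expected {n_points}"
            )
    X = np.stack([_center_scale(m) for m in mats])

    # the rotation target; scaling the target does not change the
    # optimal rotation, so the plain mean serves as consensus
    consensus = X[0].copy()
    for iteration in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        shift = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if shift < tol:
            return AlignedSample(
                shapes=X, consensus=consensus, ids=ids, n_iterations=iteration
            )
    raise ValueError(
        f"GPA did not converge in {max_iter} iterations "
        f"(last consensus shift {shift:.3e}, tol {tol:.1e})"
    )


@dataclass(frozen=True)
class DimorphismAxis:
    """Female mean, male mean, and their difference in flat shape space."""

    female_mean: np.ndarray = field(repr=False)
    male_mean: np.ndarray = field(repr=False)

    @property
    def axis(self) -> np.ndarray:
        return self.male_mean - self.female_mean

    @property
    def norm_sq(self) -> float:
        return float(self.axis @ self.axis)


@dataclass(frozen=True)
class DimorphismScores:
    """Per-face projection scores; higher = more male-like."""

    ids: tuple[str, ...]
    raw: np.ndarray
    scaled: np.ndarray | None  # z-scores; None if not requested


def dimorphism_axis(female_shapes, male_shapes) -> DimorphismAxis:
    """Axis from mean female to mean male shape.

    Both inputs are flattened aligned shapes from one common GPA,
    ``(n, 2 * n_points)``.  Swapping the sex labels negates the axis.
    """
    F = np.atleast_2d(np.asarray(female_shapes, dtype=float))
    M = np.atleast_2d(np.asarray(male_shapes, dtype=float))
    if F.shape[0] < 1 or M.shape[0] < 1:
        raise ValueError("need at least one shape per sex")
    if F.shape[1] != M.shape[1]:
        raise ValueError("female and male shapes have different dimensions")
    ax = DimorphismAxis(female_mean=F.mean(axis=0), male_mean=M.mean(axis=0))
    if ax.norm_sq <= 0:
        raise ValueError("degenerate dimorphism axis: female mean == male mean")
    return ax


def score_faces(
    targets,
    axis: DimorphismAxis,
    ids: Sequence[str] | None = None,
    scale: bool = True,
) -> DimorphismScores:
    """Project aligned target shapes onto the dimorphism axis.

    raw_i = (x_i - m_F) . v / ||v||^2 with v = m_M - m_F, so the female
    mean maps to 0 and the male mean to 1.  ``scaled`` is the z-score of
    raw across the targets (orientation preserved).
    """
    X = np.atleast_2d(np.asarray(targets, dtype=float))
    if axis.norm_sq <= 0:
        raise ValueError("degenerate dimorphism axis")
    if X.shape[1] != axis.axis.shape[0]:
        raise ValueError("targets not in the same shape space as the axis")
    if ids is None:
        ids = tuple(str(i) for i in range(X.shape[0]))
    raw = (X - axis.female_mean) @ axis.axis / axis.norm_sq
    scaled = None
    if scale:
        if X.shape[0] < 2:
            raise ValueError("z-scoring needs at least 2 targets")
        sd = raw.std(ddof=1)
        if sd <= 0:
            raise ValueError("all raw scores identical; z-scores undefined")
        scaled = (raw - raw.mean()) / sd
    return DimorphismScores(ids=tuple(ids), raw=raw, scaled=scaled)


def dimorphism_pipeline(
    targets: Sequence[LandmarkConfiguration],
    ref_female: Sequence[LandmarkConfiguration],
    ref_male: Sequence[LandmarkConfiguration],
    scale: bool = True,
) -> DimorphismScores:
    """Joint GPA of references + targets, axis, and target scores.

    One call covering the full scoring workflow: all shapes are aligned
    together (one shape space), the axis is computed from the reference
    sexes, and the targets are projected onto it.
    """
    all_configs = list(ref_female) + list(ref_male) + list(targets)
    nf, nm = len(ref_female), len(ref_male)
    # face_ids may repeat across groups; use positional ids internally
    aligned = gpa(all_configs, ids=[str(i) for i in range(len(all_configs))])
    flat = aligned.flat()
    axis = dimorphism_axis(flat[:nf], flat[nf : nf + nm])
    target_ids = [t.face_id for t in targets]
    return score_faces(
        flat[nf + nm :], axis, ids=target_ids, scale=scale
    )
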