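"""Procrustes superimposition machinery.

Implements the size measure and alignments underlying the ontogenetic
analysis: centroid size, ordinary (two-shape) Procrustes analysis via the
Kabsch/SVD solution with reflections forbidden, generalized Procrustes
analysis (GPA) with scaling to unit centroid size, and a three-landmark
"baseline" superimposition that gives different landmark subsets parallel
axes so their regression vectors can be compared in a common frame.

Embryo heads are chiral, so every rotation here is proper (determinant +1):
the smallest singular-vector pair is sign-flipped whenever the unconstrained
optimum would be a reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateShapeError, NumericalError


@dataclass
class ShapeMatrix:
    """A k-landmark 3D configuration with its landmark labels."""

    coords: np.ndarray
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (k, 3), got {self.coords.shape}")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels length must match number of landmarks")
        self.labels = tuple(int(x) for x in self.labels)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def take(self, labels: Sequence[int]) -> "ShapeMatrix":
        idx = [self.labels.index(l) for l in labels]
        return ShapeMatrix(self.coords[idx], tuple(labels))


def as_shape(x, labels: Sequence[int] | None = None) -> ShapeMatrix:
    if isinstance(x, ShapeMatrix):
        return x
    arr = np.asarray(x, dtype=float)
    if labels is None:
        labels = tuple(range(arr.shape[0]))
    return ShapeMatrix(arr, tuple(labels))


def centroid_size(shape) -> float:
    """Centroid size: sqrt of summed squared distances from the centroid.

    The standard geometric-morphometrics size measure, in the units of the
    input coordinates (mm here); used throughout as the proxy for
    developmental age.
    """
    coords = shape.coords if isinstance(shape, ShapeMatrix) else np.asarray(shape, float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


@dataclass
class OPAResult:
    """Least-squares similarity alignment of a source shape onto a target.

    ``aligned = scale * (source - source centroid) @ rotation + translation``
    """

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residual: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        centered = coords - self._source_centroid
        return self.scale * centered @ self.rotation + self.translation

    _source_centroid: np.ndarray = field(default=None, repr=False)  # type: ignore


def _kabsch(x_c: np.ndarray, y_c: np.ndarray) -> tuple[np.ndarray, float]:
    """Proper rotation R maximizing trace(R^T X^T Y) and the attained trace."""
    h = x_c.T @ y_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    flip = np.ones(3)
    flip[-1] = d
    rotation = u @ np.diag(flip) @ vt
    return rotation, float(s[0] + s[1] + d * s[2])


def ordinary_procrustes(source, target, allow_scale: bool = True) -> OPAResult:
    """Align ``source`` onto ``target`` by translation, proper rotation and
    (optionally) scale, minimizing the summed squared landmark distances.

    Returns the transform parameters and the residual
    ``sqrt(sum ||aligned - target||^2)``.  Reflections are never used, so a
    mirror-image target of a chiral shape leaves a strictly positive
    residual.
    """
    src = as_shape(source)
    tgt = as_shape(target)
    if src.labels != tgt.labels:
        raise ValueError("source and target must share landmark labels")
    if src.k < 3:
        raise DegenerateShapeError("need at least 3 landmarks for 3D alignment")
    x = src.coords
    y = tgt.coords
    x_bar = x.mean(axis=0)
    y_bar = y.mean(axis=0)
    x_c = x - x_bar
    y_c = y - y_bar
    ssx = float((x_c**2).sum())
    if ssx == 0.0:
        raise DegenerateShapeError("source landmarks all coincide")
    rotation, trace = _kabsch(x_c, y_c)
    scale = trace / ssx if allow_scale else 1.0
    translation = y_bar
    aligned = scale * x_c @ rotation + translation
    residual = float(np.sqrt(((aligned - y) ** 2).sum()))
    result = OPAResult(rotation, float(scale), translation, residual)
    result._source_centroid = x_bar
    return result


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance: both shapes centered and scaled to unit
    centroid size, optimally rotated (no reflection), then the root summed
    squared difference."""
    sa = as_shape(a)
    sb = as_shape(b)
    x = sa.coords - sa.coords.mean(axis=0)
    y = sb.coords - sb.coords.mean(axis=0)
    nx = np.sqrt((x**2).sum())
    ny = np.sqrt((y**2).sum())
    if nx == 0 or ny == 0:
        raise DegenerateShapeError("degenerate shape in distance computation")
    x = x / nx
    y = y / ny
    rotation, _ = _kabsch(x, y)
    return float(np.sqrt(((x @ rotation - y) ** 2).sum()))


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes analysis.

    Aligned shapes are centered at the origin and scaled to unit centroid
    size (full GPA); the raw centroid sizes are kept separately so size can
    enter downstream regressions as its own variable.
    """

    aligned: np.ndarray  # (n, k, 3)
    consensus: np.ndarray  # (k, 3)
    centroid_sizes: np.ndarray  # (n,) in mm
    labels: tuple[int, ...]
    iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def aligned_shape(self, i: int) -> ShapeMatrix:
        return ShapeMatrix(self.aligned[i], self.labels)

    def tangent_projected(self) -> np.ndarray:
        """Aligned shapes orthogonally projected onto the tangent plane at
        the consensus (removes the component along the consensus direction).
        Differences from the raw aligned shapes are tiny for low-dispersion
        samples like these."""
        c = self.consensus.ravel()
        c = c / np.linalg.norm(c)
        flat = self.aligned.reshape(self.n, -1)
        proj = flat - np.outer(flat @ c - 1.0, c)
        return proj.reshape(self.aligned.shape)


def gpa(
    shapes: Sequence,
    labels: Sequence[int] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Generalized Procrustes analysis of two or more configurations.

    Each shape is centered and scaled to unit centroid size, then rotated
    onto the running consensus; the consensus (mean of aligned shapes,
    itself centered and unit-scaled) is recomputed until its root mean
    square change falls below ``tol``.  The first consensus is the first
    shape after centering and scaling; order dependence of the result is
    limited to a global rotation of the whole fit.
    """
    mats = [as_shape(s, labels) for s in shapes]
    if len(mats) < 2:
        raise ValueError("gpa requires at least 2 shapes")
    lab = mats[0].labels
    for m in mats[1:]:
        if m.labels != lab:
            raise ValueError("all shapes must share landmark labels")
    sizes = np.array([centroid_size(m) for m in mats])
    if np.any(sizes == 0):
        raise DegenerateShapeError("a shape has zero centroid size")
    scaled = np.stack(
        [(m.coords - m.coords.mean(axis=0)) / s for m, s in zip(mats, sizes)]
    )
    consensus = scaled[0].copy()
    aligned = scaled.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(mats)):
            rotation, _ = _kabsch(scaled[i], consensus)
            aligned[i] = scaled[i] @ rotation
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus**2).sum())
        if norm == 0:
            raise NumericalError("consensus collapsed to a point")
        new_consensus /= norm
        rms_change = float(
            np.sqrt(((new_consensus - consensus) ** 2).mean())
        )
        consensus = new_consensus
        if rms_change < tol:
            converged = True
            break
    return ProcrustesFit(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        labels=lab,
        iterations=iterations,
        converged=converged,
    )


def baseline_superimpose(
    shapes: Sequence,
    anchor_ids: Sequence[int],
    labels: Sequence[int] | None = None,
    scale_to_unit_cs: bool = False,
) -> list[ShapeMatrix]:
    """Register shapes to the frame defined by three anchor landmarks.

    The first anchor maps to the origin, the second onto the +x axis, and
    the third into the xy-plane with positive y.  Subsets that share the
    anchors therefore end up with parallel axes, which is what makes their
    per-landmark regression vectors comparable.  With ``scale_to_unit_cs``
    each shape is additionally divided by its full centroid size.
    """
    if len(anchor_ids) != 3:
        raise ValueError("exactly 3 anchor landmarks are required")
    mats = [as_shape(s, labels) for s in shapes]
    out: list[ShapeMatrix] = []
    for m in mats:
        missing = [a for a in anchor_ids if a not in m.labels]
        if missing:
            raise ValueError(f"anchors {missing} not present in shape labels")
        idx = [m.labels.index(a) for a in anchor_ids]
        coords = m.coords.copy()
        if scale_to_unit_cs:
            coords = coords / centroid_size(coords)
        a1, a2, a3 = coords[idx[0]], coords[idx[1]], coords[idx[2]]
        v1 = a2 - a1
        n1 = np.linalg.norm(v1)
        if n1 == 0:
            raise DegenerateShapeError("first two anchors coincide")
        e1 = v1 / n1
        v2 = a3 - a1
        v2_perp = v2 - (v2 @ e1) * e1
        n2 = np.linalg.norm(v2_perp)
        if n2 / max(n1, np.linalg.norm(v2)) < 1e-12:
            raise DegenerateShapeError("anchor landmarks are collinear")
        e2 = v2_perp / n2
        e3 = np.cross(e1, e2)
        basis = np.column_stack([e1, e2, e3])  # orthonormal, det +1
        out.append(ShapeMatrix((coords - a1) @ basis, m.labels))
    return out
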