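"""Ontogenetic allometry: multivariate regression of shape on centroid size.

Procrustes shape coordinates of per-specimen mean configurations are
regressed, coordinate by coordinate, on centroid size (the proxy for
developmental age across E10.5-E12.5).  The fitted slope vector defines

* a **regression score** per specimen — the projection of its centered
  shape vector onto the unit-normalized coefficient vector, the standard
  univariate summary of allometric shape;
* the **percent variance explained** — 100 x (predicted sum of squares) /
  (total sum of squares) over all shape coordinates;
* **ontogenetic vectors** — per-landmark displacements ``slope * delta_CS``
  drawn from the mean shape, summarising the direction of shape change with
  growth.

The subset-removal experiment repeats the regression after dropping each
named landmark group (trouble, nasal, maxillary/mandibular, non-facial),
registering every subset on three shared anchor landmarks so the resulting
vectors live on parallel axes and can be compared angle by angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, NumericalError
from .procrustes import (
    ProcrustesFit,
    ShapeMatrix,
    baseline_superimpose,
    centroid_size,
    gpa,
    ordinary_procrustes,
)
from .scheme import (
    MAXMAND,
    NASAL,
    NONFACIAL,
    LandmarkScheme,
    TrialDataset,
)

#: default anchor landmarks for the parallel-axes baseline registration:
#: the three non-trouble, non-facial landmarks (1, left 8, 22), which are
#: present in every subset except the one that removes non-facial landmarks
DEFAULT_ANCHORS: tuple[int, int, int] = (1, 8, 22)

#: canonical subset names for the removal experiment
SUBSET_NAMES = ("all", "minus_trouble", "minus_nasal", "minus_maxmand", "minus_nonfacial")


@dataclass
class AllometryFit:
    """A fitted shape-on-centroid-size regression."""

    labels: tuple[int, ...]
    coefficients: np.ndarray  # (k, 3) slope per landmark axis, per mm CS
    intercepts: np.ndarray  # (k, 3)
    mean_shape: np.ndarray  # (k, 3)
    mean_cs: float
    centroid_sizes: np.ndarray  # (n,)
    regression_scores: np.ndarray  # (n,)
    pct_variance: float
    specimen_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert -1e-9 <= self.pct_variance <= 100 + 1e-9

    @property
    def coefficient_vector(self) -> np.ndarray:
        return self.coefficients.ravel()


def _fit_regression(
    shapes_flat: np.ndarray,
    sizes: np.ndarray,
    labels: tuple[int, ...],
    specimen_ids: tuple[str, ...] = (),
) -> AllometryFit:
    n, p = shapes_flat.shape
    if n < 3:
        raise NumericalError("need at least 3 specimens for the regression")
    x = sizes - sizes.mean()
    sxx = float((x**2).sum())
    if sxx == 0.0:
        raise NumericalError("centroid size is constant; regression undefined")
    y_mean = shapes_flat.mean(axis=0)
    y_c = shapes_flat - y_mean
    beta = (x @ y_c) / sxx  # (p,)
    intercept = y_mean - beta * sizes.mean()
    ss_pred = float((beta**2).sum() * sxx)
    ss_tot = float((y_c**2).sum())
    pct = 100.0 * ss_pred / ss_tot if ss_tot > 0 else 0.0
    beta_norm = np.linalg.norm(beta)
    if beta_norm > 0:
        scores = y_c @ (beta / beta_norm)
    else:
        scores = np.zeros(n)
    k = p // 3
    return AllometryFit(
        labels=labels,
        coefficients=beta.reshape(k, 3),
        intercepts=intercept.reshape(k, 3),
        mean_shape=y_mean.reshape(k, 3),
        mean_cs=float(sizes.mean()),
        centroid_sizes=np.asarray(sizes, dtype=float),
        regression_scores=scores,
        pct_variance=min(pct, 100.0),
        specimen_ids=tuple(specimen_ids),
    )


def regress_shape_on_size(
    fit: ProcrustesFit,
    tangent: bool = False,
    specimen_ids: Sequence[str] = (),
) -> AllometryFit:
    """Regress the aligned coordinates of a GPA fit on its centroid sizes.

    With ``tangent`` the aligned shapes are first orthogonally projected
    onto the tangent plane at the consensus (MorphoJ-style); at the low
    shape dispersions typical here the difference is negligible.
    """
    shapes = fit.tangent_projected() if tangent else fit.aligned
    return _fit_regression(
        shapes.reshape(fit.n, -1),
        fit.centroid_sizes,
        fit.labels,
        tuple(specimen_ids),
    )


def regression_score(fitted: AllometryFit, shape: np.ndarray | ShapeMatrix) -> float:
    """Projection of a centered shape onto the fit's unit coefficient vector.

    The shape must already be aligned in the fit's coordinate frame.
    """
    coords = shape.coords if isinstance(shape, ShapeMatrix) else np.asarray(shape, float)
    beta = fitted.coefficient_vector
    norm = np.linalg.norm(beta)
    if norm == 0:
        raise NumericalError("zero coefficient vector; score undefined")
    return float((coords - fitted.mean_shape).ravel() @ (beta / norm))


def ontogenetic_vectors(fitted: AllometryFit, delta_cs: float) -> pd.DataFrame:
    """Per-landmark displacement vectors for a centroid-size change of
    ``delta_cs`` mm: start at the mean shape, end at mean + slope*delta_cs."""
    start = fitted.mean_shape
    end = start + fitted.coefficients * float(delta_cs)
    return pd.DataFrame(
        {
            "landmark_id": fitted.labels,
            "x0": start[:, 0],
            "y0": start[:, 1],
            "z0": start[:, 2],
            "x1": end[:, 0],
            "y1": end[:, 1],
            "z1": end[:, 2],
        }
    )


def ontogenetic_regression(
    dataset: TrialDataset,
    observers: Sequence[str] | None = None,
    tangent: bool = False,
) -> tuple[ProcrustesFit, AllometryFit]:
    """Convenience: GPA of per-specimen mean shapes (all ages pooled) and
    the shape-on-size regression.  Specimen shapes are means over the given
    observers' trial means (default: all observers in the dataset)."""
    specs = dataset.specimens
    shapes = [
        dataset.specimen_mean_shape(age, spec, observers) for age, spec in specs
    ]
    fit = gpa(shapes, labels=dataset.scheme.ids)
    allo = regress_shape_on_size(
        fit, tangent=tangent, specimen_ids=tuple(s for _, s in specs)
    )
    return fit, allo


def default_subsets(scheme: LandmarkScheme) -> dict[str, tuple[int, ...]]:
    """Landmark ids retained by each canonical subset of the removal
    experiment (the trouble subset removes the scheme's 7 flagged labels)."""
    all_ids = set(scheme.ids)
    removed = {
        "all": set(),
        "minus_trouble": set(scheme.trouble_ids),
        "minus_nasal": set(scheme.subset_ids(NASAL)),
        "minus_maxmand": set(scheme.subset_ids(MAXMAND)),
        "minus_nonfacial": set(scheme.subset_ids(NONFACIAL)),
    }
    return {
        name: tuple(i for i in scheme.ids if i in (all_ids - gone))
        for name, gone in removed.items()
    }


@dataclass
class SubsetComparison:
    """Allometric regressions over landmark subsets on a common frame."""

    fits: dict[str, AllometryFit]
    vectors: dict[str, pd.DataFrame]
    angles: pd.DataFrame  # columns subset, landmark_id, angle_deg
    pct_variance: dict[str, float]
    anchor_ids: tuple[int, ...]
    delta_cs: float

    def max_angle(self, subset: str) -> float:
        sel = self.angles[self.angles["subset"] == subset]["angle_deg"]
        return float(sel.max())


def _vector_angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (u * v).sum(axis=1) / (nu * nv)
    cosang = np.clip(cosang, -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    out[(nu < 1e-15) | (nv < 1e-15)] = np.nan
    return out


def subset_experiment(
    dataset: TrialDataset,
    observers: Sequence[str] | None = None,
    subsets: Mapping[str, Sequence[int]] | None = None,
    anchor_ids: Sequence[int] = DEFAULT_ANCHORS,
    on_missing_anchors: str = "align",
    tangent: bool = False,
    min_rel_norm: float = 0.1,
) -> SubsetComparison:
    """Repeat the shape-on-size regression for each landmark subset.

    Each subset's per-specimen mean shapes are scaled to unit centroid size
    (of the subset configuration) and registered on the three anchor
    landmarks so all subsets share parallel axes; the regression uses the
    subset's own raw centroid size as regressor.  A subset that lacks an
    anchor (the non-facial removal, under the default anchors) is instead
    superimposed by GPA and rotated onto the all-landmark fit over its
    shared landmarks (``on_missing_anchors="align"``), or rejected
    (``"error"``).

    To compare fits across frames, each fit's predicted configurations at
    its smallest and largest centroid size are registered onto the
    all-landmark fit's predictions by ordinary Procrustes over the shared
    landmarks; per-landmark angles between the registered displacement
    vectors are reported in degrees (NaN where the reference displacement
    is too short — below ``min_rel_norm`` of the median — for a direction
    to be meaningful).
    """
    if on_missing_anchors not in ("align", "error"):
        raise ConfigError("on_missing_anchors must be 'align' or 'error'")
    scheme = dataset.scheme
    anchor_ids = tuple(anchor_ids)
    subset_map = (
        {k: tuple(v) for k, v in subsets.items()}
        if subsets is not None
        else default_subsets(scheme)
    )
    if "all" not in subset_map:
        raise ConfigError("subset map must include an 'all' reference subset")
    if any(a not in subset_map["all"] for a in anchor_ids):
        raise ConfigError("anchors must be present in the 'all' subset")

    specs = dataset.specimens
    mean_shapes = {
        (age, s): dataset.specimen_mean_shape(age, s, observers) for age, s in specs
    }

    fits: dict[str, AllometryFit] = {}
    for name, keep_ids in subset_map.items():
        sub_scheme = scheme.subscheme(keep_ids)
        labels = sub_scheme.ids
        idx = [scheme.ids.index(i) for i in labels]
        raw = [mean_shapes[key][idx] for key in specs]
        sizes = np.array([centroid_size(r) for r in raw])
        have_anchors = all(a in labels for a in anchor_ids)
        if have_anchors:
            framed = baseline_superimpose(
                raw, anchor_ids, labels=labels, scale_to_unit_cs=True
            )
            flat = np.stack([f.coords.ravel() for f in framed])
            fits[name] = _fit_regression(
                flat, sizes, labels, tuple(s for _, s in specs)
            )
        else:
            if on_missing_anchors == "error":
                raise ConfigError(
                    f"subset {name!r} removes anchor landmarks {anchor_ids}"
                )
            g = gpa(raw, labels=labels)
            shapes = g.tangent_projected() if tangent else g.aligned
            fit = _fit_regression(
                shapes.reshape(g.n, -1), sizes, labels, tuple(s for _, s in specs)
            )
            fits[name] = fit

    ref = fits["all"]
    ref_idx = {lm: i for i, lm in enumerate(ref.labels)}
    all_sizes = ref.centroid_sizes
    delta_cs = float(all_sizes.max() - all_sizes.min())

    # Each fit lives in its own superimposition frame, so raw slope vectors
    # are not directly comparable.  For comparison and plotting, each fit's
    # predicted configurations at its smallest and largest centroid size are
    # registered onto the reference fit's predictions (over the shared
    # landmarks) by ordinary Procrustes; the registered displacement per
    # landmark is the frame-independent ontogenetic vector, drawn from the
    # all-landmark mean shape.
    def _predict(fit: AllometryFit, cs: float, rows: Sequence[int]) -> np.ndarray:
        return (fit.mean_shape + fit.coefficients * (cs - fit.mean_cs))[rows]

    vectors: dict[str, pd.DataFrame] = {}
    disp: dict[str, tuple[list[int], np.ndarray]] = {}
    for name, fit in fits.items():
        common = [lm for lm in fit.labels if lm in ref_idx]
        ci = [fit.labels.index(lm) for lm in common]
        ri = [ref_idx[lm] for lm in common]
        lo, hi = float(fit.centroid_sizes.min()), float(fit.centroid_sizes.max())
        ref_lo = _predict(ref, float(all_sizes.min()), ri)
        ref_hi = _predict(ref, float(all_sizes.max()), ri)
        if name == "all":
            aligned_lo, aligned_hi = ref_lo, ref_hi
        else:
            opa_lo = ordinary_procrustes(
                ShapeMatrix(_predict(fit, lo, ci), tuple(common)),
                ShapeMatrix(ref_lo, tuple(common)),
            )
            opa_hi = ordinary_procrustes(
                ShapeMatrix(_predict(fit, hi, ci), tuple(common)),
                ShapeMatrix(ref_hi, tuple(common)),
            )
            aligned_lo = opa_lo.transform(_predict(fit, lo, ci))
            aligned_hi = opa_hi.transform(_predict(fit, hi, ci))
        d = aligned_hi - aligned_lo
        disp[name] = (common, d)
        start = ref.mean_shape[ri]
        vectors[name] = pd.DataFrame(
            {
                "landmark_id": common,
                "x0": start[:, 0],
                "y0": start[:, 1],
                "z0": start[:, 2],
                "x1": (start + d)[:, 0],
                "y1": (start + d)[:, 1],
                "z1": (start + d)[:, 2],
            }
        )

    # A direction is only meaningful for vectors of appreciable length:
    # angles are undefined (NaN) where the reference displacement is below
    # ``min_rel_norm`` of the median reference displacement (this also
    # covers frame-anchor landmarks, whose displacement is identically 0).
    ref_common, ref_disp = disp["all"]
    ref_disp_by_lm = {lm: ref_disp[i] for i, lm in enumerate(ref_common)}
    norm_floor = min_rel_norm * float(
        np.median(np.linalg.norm(ref_disp, axis=1))
    )
    angle_rows = []
    for name, (common, d) in disp.items():
        if name == "all":
            continue
        v_ref = np.stack([ref_disp_by_lm[lm] for lm in common])
        angs = _vector_angles_deg(d, v_ref)
        angs[np.linalg.norm(v_ref, axis=1) < norm_floor] = np.nan
        for lm, ang in zip(common, angs):
            angle_rows.append((name, lm, ang))
    angles = pd.DataFrame(angle_rows, columns=["subset", "landmark_id", "angle_deg"])
    return SubsetComparison(
        fits=fits,
        vectors=vectors,
        angles=angles,
        pct_variance={name: f.pct_variance for name, f in fits.items()},
        anchor_ids=anchor_ids,
        delta_cs=delta_cs,
    )
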