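"""Shape-on-size regression, regression scores, vectors, subset robustness."""

import numpy as np
import pytest

from embryomorph import (
    NumericalError,
    ProcrustesFit,
    SimParams,
    default_allometry_vector,
    ontogenetic_regression,
    ontogenetic_vectors,
    regress_shape_on_size,
    regression_score,
    simulate_dataset,
    subset_experiment,
)
from embryomorph.allometry import _fit_regression, default_subsets
from conftest import EXPERIENCED


def _linear_fit_input(rng, n=12, k=8, noise=0.0):
    """Shapes exactly (or nearly) mean + beta * (CS - mean CS)."""
    cs = np.linspace(4.0, 9.0, n)
    mean = rng.normal(size=(k, 3))
    beta = 0.01 * rng.normal(size=(k, 3))
    shapes = np.stack(
        [mean + beta * (c - cs.mean()) + noise * rng.normal(size=(k, 3)) for c in cs]
    )
    fit = ProcrustesFit(
        aligned=shapes,
        consensus=mean,
        centroid_sizes=cs,
        labels=tuple(range(k)),
        iterations=1,
        converged=True,
    )
    return fit, beta, cs


def test_noiseless_linear_case_is_fully_explained(rng):
    fit, beta, cs = _linear_fit_input(rng)
    allo = regress_shape_on_size(fit)
    assert abs(allo.pct_variance - 100.0) < 1e-6
    assert np.abs(allo.coefficients - beta).max() < 1e-9
    # regression score vs CS exactly linear
    r = np.corrcoef(allo.regression_scores, cs)[0, 1]
    assert abs(abs(r) - 1.0) < 1e-9


def test_pure_noise_explains_little(rng):
    n, k = 29, 36
    cs = np.repeat([5.0, 6.5, 8.5], [10, 9, 10])
    shapes = 0.01 * rng.normal(size=(n, k, 3))
    fit = ProcrustesFit(shapes, shapes.mean(axis=0), cs, tuple(range(k)), 1, True)
    allo = regress_shape_on_size(fit)
    assert allo.pct_variance < 15.0


def test_pct_variance_matches_projection_oracle(rng):
    fit, _, cs = _linear_fit_input(rng, n=9, k=4, noise=0.02)
    allo = regress_shape_on_size(fit)
    y = fit.aligned.reshape(9, -1)
    x = np.column_stack([np.ones(9), cs])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    pred = x @ beta
    ss_pred = ((pred - y.mean(axis=0)) ** 2).sum()
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum()
    assert abs(allo.pct_variance - 100 * ss_pred / ss_tot) < 1e-9


def test_constant_size_raises(rng):
    fit, _, _ = _linear_fit_input(rng)
    fit.centroid_sizes = np.full_like(fit.centroid_sizes, 5.0)
    with pytest.raises(NumericalError):
        regress_shape_on_size(fit)


def test_regression_score_identities(rng):
    fit, beta, _ = _linear_fit_input(rng)
    allo = regress_shape_on_size(fit)
    assert regression_score(allo, allo.mean_shape) == 0.0
    bnorm = np.linalg.norm(allo.coefficient_vector)
    got = regression_score(allo, allo.mean_shape + allo.coefficients)
    assert abs(got - bnorm) < 1e-12
    # invariant to adding a vector orthogonal to beta
    ortho = rng.normal(size=allo.coefficients.shape)
    flat = ortho.ravel()
    flat -= (flat @ allo.coefficient_vector) / bnorm**2 * allo.coefficient_vector
    shape = allo.mean_shape + 0.3 * allo.coefficients + flat.reshape(ortho.shape)
    base = regression_score(allo, allo.mean_shape + 0.3 * allo.coefficients)
    assert abs(regression_score(allo, shape) - base) < 1e-9


def test_slope_estimates_unbiased_over_seeds():
    errors = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        fit, beta, _ = _linear_fit_input(rng, n=10, k=5, noise=0.01)
        allo = regress_shape_on_size(fit)
        errors.append((allo.coefficients - beta).ravel())
    errors = np.asarray(errors)
    mean_err = errors.mean()
    se = errors.std(ddof=1) / np.sqrt(errors.size)
    assert abs(mean_err) < 2 * se + 1e-12


def test_ontogenetic_vectors_linearity(rng):
    fit, _, _ = _linear_fit_input(rng)
    allo = regress_shape_on_size(fit)
    v0 = ontogenetic_vectors(allo, 0.0)
    assert np.allclose(v0[["x0", "y0", "z0"]], v0[["x1", "y1", "z1"]])
    v1 = ontogenetic_vectors(allo, 1.5)
    v2 = ontogenetic_vectors(allo, 3.0)
    d1 = v1[["x1", "y1", "z1"]].to_numpy() - v1[["x0", "y0", "z0"]].to_numpy()
    d2 = v2[["x1", "y1", "z1"]].to_numpy() - v2[["x0", "y0", "z0"]].to_numpy()
    assert np.allclose(2 * d1, d2)


def test_noiseless_simulation_recovers_injected_direction(scheme):
    """The fitted slope field points along the injected ontogenetic trend."""
    p = SimParams(
        sigma_specimen=0.0,
        sigma_trial=(0.0,) * 4,
        observer_bias_scale=0.0,
        size_cv=0.0,
        trouble_inflation=1.0,
        allometry_slope=0.5,
        seed=0,
    )
    ds, truth = simulate_dataset(p)
    _, allo = ontogenetic_regression(ds, observers=EXPERIENCED)
    b = allo.coefficient_vector
    cos = abs(b @ truth.allometry_vector) / np.linalg.norm(b)
    assert cos > 0.95
    # mm displacements scale as (CS - mean)/CS in shape space, so the
    # score-size relation is close to, but not exactly, linear
    assert np.corrcoef(allo.regression_scores, allo.centroid_sizes)[0, 1] ** 2 > 0.95


def test_injected_explained_fraction_recovered(scheme):
    """Injected 80% allometric share recovered within a few points."""
    pcts = []
    for seed in range(20):
        ds, _ = simulate_dataset(SimParams(seed=seed))
        _, allo = ontogenetic_regression(ds, observers=EXPERIENCED)
        pcts.append(allo.pct_variance)
    assert abs(np.mean(pcts) - 80.0) < 7.0
    assert all(abs(p - 80.0) < 7.0 for p in pcts)


def test_subset_identical_to_reference_has_zero_angle(default_sim, scheme):
    ds, _ = default_sim
    subsets = {"all": scheme.ids, "again": scheme.ids}
    comp = subset_experiment(ds, observers=EXPERIENCED, subsets=subsets)
    assert comp.max_angle("again") < 1e-5


def test_all_subset_fits_agree_with_reference(default_sim):
    ds, _ = default_sim
    comp = subset_experiment(ds, observers=EXPERIENCED)
    assert set(comp.fits) == {
        "all", "minus_trouble", "minus_nasal", "minus_maxmand", "minus_nonfacial"
    }
    for name in comp.fits:
        if name != "all":
            assert comp.max_angle(name) < 15.0
    for pct in comp.pct_variance.values():
        assert 0.0 <= pct <= 100.0


def test_removing_signal_carrying_subset_lowers_explained(scheme):
    """When the allometric signal lives mostly on non-facial landmarks,
    removing them weakens the regression."""
    from embryomorph.scheme import NONFACIAL

    v = default_allometry_vector(scheme).reshape(scheme.count, 3).copy()
    nonfacial = set(scheme.subset_ids(NONFACIAL))
    for i, lm in enumerate(scheme):
        if lm.id not in nonfacial:
            v[i] *= 0.15
    flat = v.ravel()
    flat -= np.tile(v.mean(axis=0), scheme.count)  # zero mean per axis
    flat /= np.linalg.norm(flat)
    p = SimParams(allometry_vector=flat, seed=2)
    ds, _ = simulate_dataset(p)
    comp = subset_experiment(ds, observers=EXPERIENCED)
    assert comp.pct_variance["minus_nonfacial"] < comp.pct_variance["all"] - 5


def test_anchorless_subset_requires_alignment_policy(default_sim):
    from embryomorph import ConfigError

    ds, _ = default_sim
    with pytest.raises(ConfigError):
        subset_experiment(
            ds, observers=EXPERIENCED, on_missing_anchors="error"
        )


def test_default_subsets_drop_expected_counts(scheme):
    subs = default_subsets(scheme)
    assert len(subs["all"]) == 36
    assert len(subs["minus_trouble"]) == 36 - 13
    assert len(subs["minus_nasal"]) == 36 - 17
    assert len(subs["minus_maxmand"]) == 36 - 10
    assert len(subs["minus_nonfacial"]) == 36 - 9
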