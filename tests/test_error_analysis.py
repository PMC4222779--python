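"""Observer-error statistics and the placement ANOVA against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from embryomorph import (
    DesignError,
    SimParams,
    TroubleThresholds,
    deviation_from_mean,
    flag_trouble,
    interobserver_error,
    intraobserver_error,
    placement_anova,
    placement_anova_by_age,
    simulate_dataset,
    summarize_error,
)
from embryomorph.scheme import Configuration, TrialDataset
from conftest import EXPERIENCED


# ---------------------------------------------------------------- helpers


def _dataset_from_arrays(scheme, arrays):
    """arrays: dict (age, spec, obs, trial) -> (k, 3)."""
    cfgs = [
        Configuration.from_array(scheme, arr, spec, age, obs, trial)
        for (age, spec, obs, trial), arr in arrays.items()
    ]
    return TrialDataset(scheme, cfgs)


def anova_sequential_oracle(table, order=("specimen", "landmark_id", "observer")):
    """Sequential sums of squares from explicit least-squares projections."""
    y = table["distance"].to_numpy(float)
    n = y.size
    blocks = [np.ones((n, 1))]
    ss = {}
    prev_fit = np.full(n, y.mean())
    prev_ss = 0.0
    for factor in order:
        dummies = pd.get_dummies(table[factor].astype(str)).to_numpy(float)
        blocks.append(dummies)
        x = np.hstack(blocks)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fit = x @ beta
        ss_model = float(((fit - y.mean()) ** 2).sum())
        ss[factor] = ss_model - prev_ss
        prev_ss = ss_model
        prev_fit = fit
    ss["residual"] = float(((y - prev_fit) ** 2).sum())
    return ss


# ------------------------------------------------------------ intraobserver


def test_identical_trials_give_zero_distance(scheme, rng):
    arr = rng.normal(size=(36, 3))
    ds = _dataset_from_arrays(
        scheme,
        {("E10.5", "s1", "o1", 1): arr, ("E10.5", "s1", "o1", 2): arr},
    )
    tab = intraobserver_error(ds)
    assert (tab["distance"] == 0).all()


def test_unit_displacement_shows_only_at_shifted_landmark(scheme, rng):
    arr = rng.normal(size=(36, 3))
    arr2 = arr.copy()
    idx5 = scheme.ids.index(5)
    arr2[idx5] += [0.1, 0.0, 0.0]
    ds = _dataset_from_arrays(
        scheme,
        {("E10.5", "s1", "o1", 1): arr, ("E10.5", "s1", "o1", 2): arr2},
    )
    tab = intraobserver_error(ds)
    at5 = tab[tab["landmark_id"] == 5]["distance"]
    assert np.allclose(at5, 0.1)
    assert tab[tab["landmark_id"] != 5]["distance"].max() == 0.0


def test_pooled_bilateral_labels(scheme, rng):
    arr = rng.normal(size=(36, 3))
    ds = _dataset_from_arrays(
        scheme,
        {("E10.5", "s1", "o1", 1): arr, ("E10.5", "s1", "o1", 2): arr},
    )
    pooled = intraobserver_error(ds, pool_bilateral=True)
    assert set(pooled["landmark"]) == set(scheme.pair_labels)
    assert (pooled["landmark"] == "7/24").sum() == 2  # both sides kept
    unpooled = intraobserver_error(ds, pool_bilateral=False)
    assert len(unpooled) == len(pooled) == 36


def test_wrong_trial_count_raises(scheme, rng):
    arr = rng.normal(size=(36, 3))
    ds = _dataset_from_arrays(scheme, {("E10.5", "s1", "o1", 1): arr})
    with pytest.raises(DesignError):
        intraobserver_error(ds)


# ------------------------------------------------------------ interobserver


def test_coincident_observers_give_zero_cs(scheme, rng):
    arr = rng.normal(size=(36, 3))
    arrays = {
        ("E10.5", "s1", o, t): arr for o in ("o1", "o2", "o3") for t in (1, 2)
    }
    tab = interobserver_error(_dataset_from_arrays(scheme, arrays), ("o1", "o2", "o3"))
    assert np.allclose(tab["centroid_size"], 0.0)


def test_collinear_three_observer_case_matches_formula(scheme, rng):
    d = 0.05
    base = rng.normal(size=(36, 3))
    offsets = {"o1": [-d, 0, 0], "o2": [0, 0, 0], "o3": [d, 0, 0]}
    arrays = {
        ("E10.5", "s1", o, t): base + np.asarray(off)
        for o, off in offsets.items()
        for t in (1, 2)
    }
    tab = interobserver_error(_dataset_from_arrays(scheme, arrays), ("o1", "o2", "o3"))
    assert np.allclose(tab["centroid_size"], d * np.sqrt(2))


def test_interobserver_matches_bruteforce_definition(scheme, rng):
    arrays = {
        ("E10.5", f"s{s}", o, t): rng.normal(size=(36, 3))
        for s in range(3)
        for o in ("o1", "o2", "o3")
        for t in (1, 2)
    }
    ds = _dataset_from_arrays(scheme, arrays)
    tab = interobserver_error(ds, ("o1", "o2", "o3"))
    for s in range(3):
        spec = f"s{s}"
        for i, lm_id in enumerate(scheme.ids):
            pts = []
            for o in ("o1", "o2", "o3"):
                m = 0.5 * (
                    arrays[("E10.5", spec, o, 1)][i] + arrays[("E10.5", spec, o, 2)][i]
                )
                pts.append(m)
            pts = np.asarray(pts)
            cs = np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum())
            got = tab[
                (tab["specimen"] == spec) & (tab["landmark_id"] == lm_id)
            ]["centroid_size"].iloc[0]
            assert abs(got - cs) < 1e-12


def test_interobserver_invariances(scheme, rng):
    arrays = {
        ("E10.5", "s1", o, t): rng.normal(size=(36, 3))
        for o in ("o1", "o2", "o3")
        for t in (1, 2)
    }
    ds = _dataset_from_arrays(scheme, arrays)
    t1 = interobserver_error(ds, ("o1", "o2", "o3"))
    t2 = interobserver_error(ds, ("o3", "o1", "o2"))  # relabel order
    assert np.allclose(t1["centroid_size"], t2["centroid_size"])
    shifted = {k: v + np.array([1.0, -2.0, 3.0]) for k, v in arrays.items()}
    t3 = interobserver_error(_dataset_from_arrays(scheme, shifted), ("o1", "o2", "o3"))
    assert np.allclose(t1["centroid_size"], t3["centroid_size"])


# -------------------------------------------------------- deviation + ANOVA


def test_single_observer_deviations_are_zero(scheme, rng):
    arrays = {("E10.5", "s1", "o1", t): rng.normal(size=(36, 3)) for t in (1, 2)}
    tab = deviation_from_mean(_dataset_from_arrays(scheme, arrays), ("o1",))
    assert (tab["distance"] == 0).all()


def test_two_observer_symmetric_split(scheme, rng):
    base = rng.normal(size=(36, 3))
    arrays = {}
    for o, off in (("o1", [0.05, 0, 0]), ("o2", [-0.05, 0, 0])):
        for t in (1, 2):
            arrays[("E10.5", "s1", o, t)] = base + np.asarray(off)
    tab = deviation_from_mean(_dataset_from_arrays(scheme, arrays))
    assert np.allclose(tab["distance"], 0.05)


def test_deviation_matches_bruteforce(scheme, rng):
    arrays = {
        ("E10.5", f"s{s}", o, t): rng.normal(size=(36, 3))
        for s in range(3)
        for o in ("o1", "o2", "o3")
        for t in (1, 2)
    }
    ds = _dataset_from_arrays(scheme, arrays)
    tab = deviation_from_mean(ds)
    for _, row in tab.sample(30, random_state=0).iterrows():
        i = scheme.ids.index(row.landmark_id)
        per_obs = {
            o: 0.5
            * (
                arrays[("E10.5", row.specimen, o, 1)][i]
                + arrays[("E10.5", row.specimen, o, 2)][i]
            )
            for o in ("o1", "o2", "o3")
        }
        mean = np.mean(list(per_obs.values()), axis=0)
        expected = np.linalg.norm(per_obs[row.observer] - mean)
        assert abs(row.distance - expected) < 1e-12


def _toy_table(rng, n_spec=3, n_lm=4, n_obs=2, age="E10.5"):
    rows = []
    for s in range(n_spec):
        for l in range(n_lm):
            for o in range(n_obs):
                rows.append((age, f"s{s}", l + 1, f"o{o}", rng.gamma(2.0, 0.02)))
    return pd.DataFrame(
        rows, columns=["age", "specimen", "landmark_id", "observer", "distance"]
    )


def test_anova_matches_projection_oracle_on_toy_design(rng):
    table = _toy_table(rng)
    result = placement_anova(table)
    oracle = anova_sequential_oracle(table)
    assert abs(result.sum_sq["Specimen"] - oracle["specimen"]) < 1e-10
    assert abs(result.sum_sq["Landmark"] - oracle["landmark_id"]) < 1e-10
    assert abs(result.sum_sq["Observer"] - oracle["observer"]) < 1e-10
    assert abs(result.sum_sq["Residual"] - oracle["residual"]) < 1e-10
    assert result.df == {"Specimen": 2, "Landmark": 3, "Observer": 1, "Residual": 17}
    # F from the oracle's mean squares
    f_spec = (oracle["specimen"] / 2) / (oracle["residual"] / 17)
    assert abs(result.f_value["Specimen"] - f_spec) < 1e-10


def test_anova_sequential_ss_order_invariant_under_balance(rng):
    table = _toy_table(rng)
    oracle = {}
    for order in itertools.permutations(("specimen", "landmark_id", "observer")):
        ss = anova_sequential_oracle(table, order)
        for f, v in ss.items():
            oracle.setdefault(f, []).append(v)
    for f, vals in oracle.items():
        assert max(vals) - min(vals) < 1e-9


def test_anova_decomposition_and_df_sum(default_sim):
    ds, _ = default_sim
    dev = deviation_from_mean(ds)
    for age, t in placement_anova_by_age(dev).items():
        n = {"E10.5": 1440, "E11.5": 1296, "E12.5": 1440}[age]
        assert sum(t.df.values()) == n - 1
        y = dev[dev["age"] == age]["distance"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert np.isclose(sum(t.sum_sq.values()), total, rtol=1e-9)


def test_anova_design_degrees_of_freedom(default_sim):
    """The balanced design fixes Specimen df 9/8/9 and Residual 1392/1249/1392."""
    ds, _ = default_sim
    tables = placement_anova_by_age(deviation_from_mean(ds))
    assert tables["E10.5"].df == {
        "Specimen": 9, "Landmark": 35, "Observer": 3, "Residual": 1392
    }
    assert tables["E11.5"].df["Specimen"] == 8
    assert tables["E11.5"].residual_df == 1249
    assert tables["E12.5"].residual_df == 1392


def test_anova_constant_response_degenerates_cleanly(rng):
    table = _toy_table(rng)
    table["distance"] = 0.25
    result = placement_anova(table)
    assert all(ss < 1e-20 for ss in result.sum_sq.values())
    assert result.p_value["Observer"] is None


def test_anova_rejects_unbalanced_table(rng):
    table = _toy_table(rng).iloc[:-1]
    with pytest.raises(DesignError):
        placement_anova(table)


# ------------------------------------------------------- summaries + flags


def test_summarize_error_order_statistics(rng):
    tab = pd.DataFrame(
        {
            "landmark": ["a"] * 5 + ["b"],
            "observer": ["o1"] * 6,
            "distance": [1.0, 2.0, 3.0, 4.0, 5.0, 7.0],
        }
    )
    out = summarize_error(tab)
    row_a = out[out["landmark"] == "a"].iloc[0]
    assert row_a["median"] == 3.0 and row_a["q1"] == 2.0 and row_a["q3"] == 4.0
    row_b = out[out["landmark"] == "b"].iloc[0]
    assert row_b["median"] == row_b["q1"] == row_b["q3"] == 7.0
    assert row_b["n"] == 1


def test_summarize_matches_independent_order_statistics(default_sim):
    ds, _ = default_sim
    intra = intraobserver_error(ds)
    out = summarize_error(intra, ["age", "observer", "landmark"])
    probe = out.sample(10, random_state=1)
    for _, row in probe.iterrows():
        sel = intra[
            (intra["age"] == row["age"])
            & (intra["observer"] == row["observer"])
            & (intra["landmark"] == row["landmark"])
        ]["distance"].to_numpy()
        assert np.isclose(row["median"], np.median(sel))
        assert row["n"] == sel.size


def test_flag_trouble_threshold_behaviour(default_sim):
    ds, _ = default_sim
    intra = intraobserver_error(ds)
    intra = intra[intra["observer"].isin(EXPERIENCED)]
    inter = interobserver_error(ds, EXPERIENCED)
    # raising thresholds above the global maxima empties the set
    high = TroubleThresholds(intra_mm=1e6, inter_floor_mm=1e6)
    assert flag_trouble(intra, inter, high) == set()
    # uniformly low error (no inflation, small noise) flags nothing
    quiet, _ = simulate_dataset(
        SimParams(trouble_inflation=1.0, observer_bias_scale=0.01, seed=4)
    )
    qi = intraobserver_error(quiet)
    qi = qi[qi["observer"].isin(EXPERIENCED)]
    assert flag_trouble(qi, interobserver_error(quiet, EXPERIENCED)) == set()


def test_flag_trouble_recovers_engineered_inflation(scheme):
    from embryomorph import REMOVAL_LABELS

    sch = scheme.with_trouble(REMOVAL_LABELS)
    ds, _ = simulate_dataset(SimParams(trouble_inflation=3.0, seed=21), scheme=sch)
    intra = intraobserver_error(ds)
    intra = intra[intra["observer"].isin(EXPERIENCED)]
    inter = interobserver_error(ds, EXPERIENCED)
    assert flag_trouble(intra, inter) == set(REMOVAL_LABELS)
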