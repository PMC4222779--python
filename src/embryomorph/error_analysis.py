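"""Landmark placement error statistics.

Quantifies how repeatably observers place landmarks:

* **Intraobserver error** — the Euclidean distance (mm) between the same
  observer's placements of one landmark in trials 1 and 2.  Left and right
  members of a bilateral pair show similar error, so their values are pooled
  under the pair label (``7/24``) by default.
* **Interobserver error** — for each specimen and landmark instance, the
  centroid size of the observers' mean placements (mean of the two trials),
  computed separately for the left and right side.
* **Placement ANOVA** — for each age, an additive main-effects linear model
  of the deviation distances (each observer's trial-mean placement vs the
  across-observer specimen mean) on specimen, landmark and observer
  identity, with sequential sums of squares (order-invariant because the
  design is balanced).
* **Trouble flagging** — landmarks whose median intraobserver error exceeds
  0.1 mm (the reference placement-error level) at any age for any included
  observer, or whose median interobserver centroid size is extreme.

The ANOVA deliberately includes all four observers and averages each
observer's two trials into one observation per (specimen, landmark,
observer) cell: with 10/9/10 specimens, 36 landmark instances and 4
observers that yields residual degrees of freedom 1392/1249/1392.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import DesignError, ParameterError
from .procrustes import centroid_size
from .scheme import AGES, TrialDataset

#: landmark pair labels recommended for removal (high, unfixable error)
from .scheme import REMOVAL_LABELS, TROUBLE_LABELS  # re-exported for convenience

INTRA_REFERENCE_MM = 0.1  # reference placement-error level shown on boxplots


def intraobserver_error(
    dataset: TrialDataset, pool_bilateral: bool = True
) -> pd.DataFrame:
    """Trial-1-to-trial-2 distance per (age, observer, specimen, landmark).

    Returns a table with columns ``age, observer, specimen, landmark_id,
    side, landmark, distance`` where ``landmark`` is the pooled pair label
    when ``pool_bilateral`` (values are kept per side; only the label is
    merged) and the plain id otherwise.
    """
    trials = dataset.trials
    if len(trials) != 2:
        raise DesignError(
            f"intraobserver error requires exactly 2 trials, found {trials}"
        )
    t1, t2 = trials
    scheme = dataset.scheme
    rows = []
    for age, spec in dataset.specimens:
        for obs in dataset.observers:
            a = dataset.get(age, spec, obs, t1).array(scheme)
            b = dataset.get(age, spec, obs, t2).array(scheme)
            dist = np.linalg.norm(a - b, axis=1)
            for i, lm in enumerate(scheme):
                label = lm.pair_label if pool_bilateral else str(lm.id)
                rows.append((age, obs, spec, lm.id, lm.side, label, dist[i]))
    return pd.DataFrame(
        rows,
        columns=[
            "age",
            "observer",
            "specimen",
            "landmark_id",
            "side",
            "landmark",
            "distance",
        ],
    )


def interobserver_error(
    dataset: TrialDataset, observers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Centroid size of the observers' mean placements per landmark instance.

    For each (specimen, landmark id): average each included observer's two
    trials, then take the centroid size of those observer-mean points.  Left
    and right instances are kept separate.  ``observers`` defaults to all
    observers in the dataset; analyses normally pass the experienced subset.
    """
    obs = tuple(observers) if observers is not None else dataset.observers
    if len(obs) < 2:
        raise ParameterError("interobserver error requires at least 2 observers")
    unknown = set(obs) - set(dataset.observers)
    if unknown:
        raise ParameterError(f"unknown observers {sorted(unknown)}")
    scheme = dataset.scheme
    rows = []
    for age, spec in dataset.specimens:
        means = np.stack(
            [dataset.observer_mean_shape(age, spec, o) for o in obs]
        )  # (n_obs, k, 3)
        centered = means - means.mean(axis=0, keepdims=True)
        cs = np.sqrt((centered**2).sum(axis=(0, 2)))  # per landmark
        for i, lm in enumerate(scheme):
            rows.append((age, lm.id, lm.side, lm.pair_label, spec, cs[i]))
    return pd.DataFrame(
        rows,
        columns=["age", "landmark_id", "side", "landmark", "specimen", "centroid_size"],
    )


def deviation_from_mean(
    dataset: TrialDataset, observers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Distance of each observer's trial-mean placement from the specimen
    mean (the average of the included observers' trial means)."""
    obs = tuple(observers) if observers is not None else dataset.observers
    unknown = set(obs) - set(dataset.observers)
    if unknown:
        raise ParameterError(f"unknown observers {sorted(unknown)}")
    scheme = dataset.scheme
    rows = []
    for age, spec in dataset.specimens:
        means = np.stack([dataset.observer_mean_shape(age, spec, o) for o in obs])
        spec_mean = means.mean(axis=0)
        for o, m in zip(obs, means):
            dist = np.linalg.norm(m - spec_mean, axis=1)
            for i, lm_id in enumerate(scheme.ids):
                rows.append((age, spec, lm_id, o, dist[i]))
    return pd.DataFrame(
        rows, columns=["age", "specimen", "landmark_id", "observer", "distance"]
    )


@dataclass
class AnovaTable:
    """Main-effects ANOVA of placement deviation for one age.

    Factors in order: Specimen, Landmark, Observer, Residual.  ``p_value``
    is ``None`` for the residual row and for degenerate (zero-variance)
    responses.
    """

    age: str
    df: dict[str, int]
    sum_sq: dict[str, float]
    f_value: dict[str, float | None]
    p_value: dict[str, float | None]

    FACTORS = ("Specimen", "Landmark", "Observer")

    def __post_init__(self) -> None:
        n = sum(self.df.values()) + 1
        total = sum(self.sum_sq.values())
        for factor, ss in self.sum_sq.items():
            if ss < -1e-12 * max(total, 1.0):
                raise AssertionError(f"negative sum of squares for {factor}")
        # decomposition identity: factor dfs must sum to N - 1
        assert sum(self.df.values()) == n - 1

    @property
    def residual_df(self) -> int:
        return self.df["Residual"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for factor in (*self.FACTORS, "Residual"):
            rows.append(
                (
                    self.age,
                    factor,
                    self.df[factor],
                    self.sum_sq[factor],
                    self.f_value.get(factor),
                    self.p_value.get(factor),
                )
            )
        return pd.DataFrame(
            rows, columns=["age", "factor", "df", "sum_sq", "f_value", "p_value"]
        )


def _check_balanced(table: pd.DataFrame) -> None:
    counts = table.groupby(["specimen", "landmark_id", "observer"], sort=False).size()
    n_spec = table["specimen"].nunique()
    n_lm = table["landmark_id"].nunique()
    n_obs = table["observer"].nunique()
    if len(counts) != n_spec * n_lm * n_obs or counts.nunique() != 1 or counts.iloc[0] != 1:
        raise DesignError(
            "placement ANOVA requires exactly one observation per "
            "(specimen, landmark, observer) cell"
        )


def placement_anova(deviation_table: pd.DataFrame) -> AnovaTable:
    """Fit ``distance ~ specimen + landmark + observer`` for a single age.

    Sums of squares are sequential (type I); under the balanced design they
    are identical for every factor ordering.  F statistics and p-values are
    taken against the residual mean square.
    """
    ages = deviation_table["age"].unique()
    if len(ages) != 1:
        raise DesignError(
            f"placement_anova expects a single-age table, got ages {list(ages)}; "
            "use placement_anova_by_age"
        )
    age = str(ages[0])
    _check_balanced(deviation_table)
    df = deviation_table.copy()
    df["specimen"] = df["specimen"].astype(str)
    df["landmark_id"] = df["landmark_id"].astype(str)
    df["observer"] = df["observer"].astype(str)
    response = df["distance"].to_numpy()
    degenerate = float(np.ptp(response)) == 0.0

    model = smf.ols(
        "distance ~ C(specimen) + C(landmark_id) + C(observer)", data=df
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on zero-SS F tests
        anova = sm.stats.anova_lm(model, typ=1)
    name_map = {
        "C(specimen)": "Specimen",
        "C(landmark_id)": "Landmark",
        "C(observer)": "Observer",
        "Residual": "Residual",
    }
    dfs: dict[str, int] = {}
    ss: dict[str, float] = {}
    fv: dict[str, float | None] = {}
    pv: dict[str, float | None] = {}
    for raw, name in name_map.items():
        row = anova.loc[raw]
        dfs[name] = int(row["df"])
        ss[name] = max(float(row["sum_sq"]), 0.0)
        if name == "Residual" or degenerate or not np.isfinite(row["F"]):
            fv[name] = None
            pv[name] = None
        else:
            fv[name] = float(row["F"])
            pv[name] = float(row["PR(>F)"])
    table = AnovaTable(age=age, df=dfs, sum_sq=ss, f_value=fv, p_value=pv)
    total = float(((response - response.mean()) ** 2).sum())
    if not np.isclose(sum(ss.values()), total, rtol=1e-9, atol=1e-12):
        raise AssertionError("ANOVA sums of squares do not decompose the total")
    return table


def placement_anova_by_age(deviation_table: pd.DataFrame) -> dict[str, AnovaTable]:
    return {
        age: placement_anova(deviation_table[deviation_table["age"] == age])
        for age in AGES
        if (deviation_table["age"] == age).any()
    }


def summarize_error(
    table: pd.DataFrame,
    group_by: Sequence[str] = ("landmark", "observer"),
    value: str = "distance",
) -> pd.DataFrame:
    """Boxplot statistics (median, quartiles, Tukey whiskers, n) per group.

    Empty groups are dropped with a warning.  The 0.1 mm reference level is
    attached as the ``reference_mm`` attribute of the returned frame.
    """
    group_by = list(group_by)
    rows = []
    for key, grp in table.groupby(group_by, sort=False, dropna=False):
        vals = grp[value].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"empty group {key}; excluded from summary")
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, med, q1, q3, lo, hi, vals.size))
    out = pd.DataFrame(
        rows,
        columns=[*group_by, "median", "q1", "q3", "whisker_lo", "whisker_hi", "n"],
    )
    out.attrs["reference_mm"] = INTRA_REFERENCE_MM
    return out


@dataclass(frozen=True)
class TroubleThresholds:
    """Cutoffs for flagging landmarks as trouble.

    ``intra_mm``: a landmark is flagged when its median intraobserver error
    exceeds this at any age for any included observer (default the 0.1 mm
    reference level).  ``inter_quantile`` / ``inter_floor_mm``: flagged when
    its median interobserver centroid size at some age exceeds both the
    given quantile of per-landmark medians at that age and the absolute
    floor (the floor keeps uniformly-low-error datasets from flagging their
    top decile).
    """

    intra_mm: float = INTRA_REFERENCE_MM
    inter_quantile: float = 0.9
    inter_floor_mm: float = INTRA_REFERENCE_MM


def flag_trouble(
    intra_table: pd.DataFrame,
    inter_table: pd.DataFrame | None = None,
    thresholds: TroubleThresholds | None = None,
) -> set[str]:
    """Flag landmark pair labels with high intra- or inter-observer error.

    ``intra_table`` should already be restricted to the observers whose
    repeatability matters (normally the experienced ones).
    """
    thr = thresholds or TroubleThresholds()
    flagged: set[str] = set()
    med = (
        intra_table.groupby(["age", "observer", "landmark"], sort=False)["distance"]
        .median()
        .reset_index()
    )
    flagged |= set(med.loc[med["distance"] > thr.intra_mm, "landmark"])
    if inter_table is not None and not inter_table.empty:
        med_cs = (
            inter_table.groupby(["age", "landmark"], sort=False)["centroid_size"]
            .median()
            .reset_index()
        )
        for age, grp in med_cs.groupby("age", sort=False):
            cut = max(
                float(grp["centroid_size"].quantile(thr.inter_quantile)),
                thr.inter_floor_mm,
            )
            flagged |= set(grp.loc[grp["centroid_size"] > cut, "landmark"])
    return flagged
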