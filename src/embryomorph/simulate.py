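"""Synthetic ontogenetic landmark datasets.

No raw embryo landmark coordinates are publicly deposited for the study
design this package analyses, so this module generates datasets with the
same statistical structure: a balanced design of 10/9/10 specimens at
E10.5/E11.5/E12.5, four observers (three experienced plus one novice), two
placement trials, ontogenetic growth in centroid size, a linear allometric
shape trend, per-observer placement bias and per-trial placement noise.

The generative model for one observed landmark configuration is

    observed = specimen_true + bias(observer, landmark) + trial noise

    specimen_true = CS_i * base_shape
                    + slope * (CS_i - mean CS) * allometry_direction
                    + specimen shape deviation

where ``base_shape`` is a stylized, bilaterally symmetric 36-point embryo
head scaled to unit centroid size, ``CS_i`` the specimen's centroid size
(age growth target with a small lognormal-free multiplicative jitter),
``allometry_direction`` a unit-norm shape direction orthogonal to the
similarity transformations of the base shape, bias a fixed per-(observer,
landmark) 3-vector drawn once per simulation, and trial noise isotropic
Gaussian.  Landmarks flagged as trouble get both their bias and their noise
standard deviation multiplied by ``trouble_inflation``.

The template geometry is hand-placed and stylized — only its topology
(midline vs bilateral, facial vs non-facial placement) and millimetre scale
(head spanning roughly 2-4 mm) are meaningful, not the anatomy.

All randomness flows from a single integer seed through NumPy's PCG64
generator (``numpy.random.default_rng``); identical parameters and seed
reproduce the dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .exceptions import ParameterError
from .scheme import (
    AGES,
    Configuration,
    LandmarkScheme,
    MAXMAND,
    MIDLINE,
    NASAL,
    TrialDataset,
    builtin_scheme,
)

# Hand-placed unit geometry of the 36-landmark head (arbitrary units before
# scaling).  Axes: +x rostral, +y left, +z dorsal; the midsagittal plane is
# y = 0.  Bilateral pairs are listed via the left member; the right member is
# its mirror image in y.
_BASE_POINTS: dict[int, tuple[float, float, float]] = {
    1: (-0.20, 0.0, 1.00),
    2: (0.70, 0.0, 0.80),
    3: (1.00, 0.0, 0.35),
    4: (1.15, 0.0, 0.00),
    5: (1.05, 0.0, -0.30),
    22: (-1.20, 0.0, 0.20),
    6: (0.90, 0.25, 0.55),
    7: (0.80, 0.45, 0.45),
    8: (0.55, 0.60, 0.35),
    9: (0.50, 0.65, 0.05),
    10: (0.25, 0.80, -0.05),
    11: (0.85, 0.50, -0.05),
    12: (0.95, 0.30, -0.25),
    13: (1.00, 0.40, 0.15),
    14: (1.05, 0.18, 0.05),
    15: (1.00, 0.30, 0.30),
    16: (0.55, 0.55, -0.40),
    17: (0.40, 0.85, -0.25),
    18: (-0.50, 0.75, -0.15),
    20: (0.70, 0.20, -0.55),
    21: (-0.10, 0.55, -0.60),
}

#: per-age centroid-size growth targets (mm); strictly increasing with age
DEFAULT_GROWTH: dict[str, float] = {"E10.5": 5.0, "E11.5": 6.5, "E12.5": 8.5}

DEFAULT_N_SPECIMENS: tuple[int, int, int] = (10, 9, 10)


def _base_shape(scheme: LandmarkScheme) -> np.ndarray:
    """Unit-centroid-size symmetric base configuration, (k, 3), scheme order."""
    pts = []
    for lm in scheme:
        if lm.side == "right":
            x, y, z = _BASE_POINTS[lm.pair_id]
            pts.append((x, -y, z))
        else:
            x, y, z = _BASE_POINTS[lm.id]
            pts.append((x, y, z))
    arr = np.asarray(pts, dtype=float)
    arr -= arr.mean(axis=0)
    # re-center shifts the midplane off y=0 only if the y means differ; the
    # construction is mirror symmetric so the y mean is exactly 0
    arr /= np.sqrt((arr**2).sum())
    return arr


def _similarity_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the similarity tangent directions at a
    centered shape: 3 translations, 1 scaling, 3 rotations (7 x 3k)."""
    k = base.shape[0]
    gens = []
    for ax in range(3):
        t = np.zeros((k, 3))
        t[:, ax] = 1.0
        gens.append(t.ravel())
    gens.append(base.ravel())  # scaling direction
    for omega in np.eye(3):
        gens.append(np.cross(np.broadcast_to(omega, (k, 3)), base).ravel())
    basis, _ = np.linalg.qr(np.asarray(gens).T)
    return basis.T


def default_allometry_vector(scheme: LandmarkScheme | None = None) -> np.ndarray:
    """Unit-norm ontogenetic shape direction (3k,), emulating the published
    trend: facial landmarks move rostrally and toward the midline (the ones
    near the midline also ventrally), non-facial landmarks caudally and
    dorsally.  Mirror symmetric, zero mean per axis, and orthogonal to the
    similarity transformations of the base shape so the signal survives
    Procrustes superimposition."""
    scheme = scheme or builtin_scheme()
    base = _base_shape(scheme)
    v = np.zeros_like(base)
    for i, lm in enumerate(scheme):
        y = base[i, 1]
        if lm.subset in (NASAL, MAXMAND):
            v[i, 0] = 1.0  # rostral
            v[i, 1] = -np.sign(y) * 0.8  # toward the midline
            if abs(y) < 0.05:
                v[i, 2] = -0.6  # midline facial landmarks drop ventrally
        else:
            v[i, 0] = -1.0  # caudal
            v[i, 2] = 0.8  # dorsal
    flat = v.ravel()
    basis = _similarity_basis(base)
    flat = flat - basis.T @ (basis @ flat)
    norm = np.linalg.norm(flat)
    if norm == 0:
        raise ParameterError("degenerate allometry direction")
    return flat / norm


@dataclass
class SimParams:
    """Parameters of the synthetic study design.

    Defaults mirror the study's design dimensions (10/9/10 specimens, 4
    observers of whom the last is the novice, 2 trials) with noise levels
    chosen so that experienced observers' median intraobserver error sits
    near 0.05 mm (well under the 0.1 mm reference) and the novice's above
    0.1 mm.
    """

    n_specimens: tuple[int, int, int] = DEFAULT_N_SPECIMENS
    n_observers: int = 4
    n_trials: int = 2
    sigma_specimen: float = 0.05  # mm, per-coordinate specimen shape s.d.
    sigma_trial: tuple[float, ...] = (0.02, 0.02, 0.02, 0.05)  # mm per observer
    # mm, per-coordinate bias s.d.; a scalar applies to every observer, a
    # tuple gives each observer an individual interpretation strength
    observer_bias_scale: float | tuple[float, ...] = 0.03
    trouble_inflation: float = 2.5  # multiplier on trouble landmarks' bias+noise
    growth: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GROWTH))
    size_cv: float = 0.03  # within-age coefficient of variation of CS
    allometry_slope: float | None = None  # None -> slope_for_explained(0.8)
    allometry_vector: np.ndarray | None = None  # None -> default direction
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_specimens = tuple(int(n) for n in self.n_specimens)
        self.sigma_trial = tuple(float(s) for s in self.sigma_trial)
        if len(self.n_specimens) != len(AGES):
            raise ParameterError("n_specimens must give one count per age")
        if any(n < 1 for n in self.n_specimens):
            raise ParameterError("n_specimens must be positive")
        if self.n_observers < 1 or self.n_trials < 1:
            raise ParameterError("need at least one observer and one trial")
        if len(self.sigma_trial) != self.n_observers:
            raise ParameterError(
                "sigma_trial must give one value per observer "
                f"({self.n_observers}), got {len(self.sigma_trial)}"
            )
        if min(self.sigma_trial) < 0 or self.sigma_specimen < 0:
            raise ParameterError("standard deviations must be >= 0")
        if np.isscalar(self.observer_bias_scale):
            self.observer_bias_scale = float(self.observer_bias_scale)
        else:
            self.observer_bias_scale = tuple(
                float(s) for s in self.observer_bias_scale
            )
            if len(self.observer_bias_scale) != self.n_observers:
                raise ParameterError(
                    "observer_bias_scale must be a scalar or give one value "
                    f"per observer ({self.n_observers})"
                )
        if min(self.bias_scales) < 0 or self.size_cv < 0:
            raise ParameterError("scales must be >= 0")
        if self.trouble_inflation < 1:
            raise ParameterError("trouble_inflation must be >= 1")
        targets = [self.growth[a] for a in AGES]
        if not all(b > a > 0 for a, b in zip(targets, targets[1:])):
            raise ParameterError(
                "growth targets must be positive and strictly increasing with age"
            )

    @property
    def bias_scales(self) -> tuple[float, ...]:
        """Per-observer bias standard deviations (scalar broadcast)."""
        if np.isscalar(self.observer_bias_scale):
            return (float(self.observer_bias_scale),) * self.n_observers
        return tuple(self.observer_bias_scale)

    @property
    def observer_ids(self) -> tuple[str, ...]:
        return tuple(f"obs{i + 1}" for i in range(self.n_observers))

    @property
    def experienced_ids(self) -> tuple[str, ...]:
        """All observers but the last, who plays the novice."""
        return self.observer_ids[:-1] if self.n_observers > 1 else self.observer_ids

    @property
    def design(self) -> tuple[tuple[int, int, int], int, int]:
        return (self.n_specimens, self.n_observers, self.n_trials)

    def design_centroid_sizes(self) -> np.ndarray:
        """Nominal per-specimen centroid sizes implied by the growth targets."""
        return np.repeat(
            [self.growth[a] for a in AGES], self.n_specimens
        ).astype(float)

    def slope_for_explained(
        self, explained: float, k: int = 36, n_trouble: int = 13
    ) -> float:
        """Allometric slope making the injected allometric signal account for
        ``explained`` of the total shape variance of per-specimen mean
        shapes at the nominal design sizes.

        The non-allometric variance counts the specimen shape deviation plus
        the measurement error surviving the averaging over the experienced
        observers' trial means: per coordinate
        ``sigma_specimen^2 + w * (bias^2 / m + mean trial var / (m * t))``
        with m experienced observers, t trials and ``w`` the average trouble
        inflation of the variance over the ``n_trouble`` flagged landmark
        instances.
        """
        if not 0 < explained < 1:
            raise ParameterError("explained must be in (0, 1)")
        var_cs = self.design_centroid_sizes().var()
        if var_cs == 0:
            raise ParameterError("growth targets give zero size variance")
        m = max(len(self.experienced_ids), 1)
        t = self.n_trials
        w = (k - n_trouble + n_trouble * self.trouble_inflation**2) / k
        trial_var = float(
            np.mean([s**2 for s in self.sigma_trial[:m]])
        )
        bias_var = float(np.mean([s**2 for s in self.bias_scales[:m]]))
        per_coord = self.sigma_specimen**2 + w * (
            bias_var / m + trial_var / (m * t)
        )
        noise = 3 * k * per_coord
        return float(np.sqrt(explained / (1 - explained) * noise / var_cs))

    def resolved_slope(self, k: int = 36) -> float:
        if self.allometry_slope is not None:
            return float(self.allometry_slope)
        return self.slope_for_explained(0.8, k=k)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["growth"] = dict(self.growth)
        if self.allometry_vector is not None:
            d["allometry_vector"] = np.asarray(self.allometry_vector).tolist()
        d["n_specimens"] = list(self.n_specimens)
        d["sigma_trial"] = list(self.sigma_trial)
        if not np.isscalar(self.observer_bias_scale):
            d["observer_bias_scale"] = list(self.observer_bias_scale)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimParams":
        d = yaml.safe_load(text) or {}
        if "allometry_vector" in d and d["allometry_vector"] is not None:
            d["allometry_vector"] = np.asarray(d["allometry_vector"], dtype=float)
        if isinstance(d.get("observer_bias_scale"), list):
            d["observer_bias_scale"] = tuple(d["observer_bias_scale"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact record of the generative components of one simulated dataset."""

    templates: dict[str, np.ndarray]  # age -> (k, 3) mm
    true_shapes: dict[tuple[str, str], np.ndarray]  # (age, specimen) -> (k, 3)
    centroid_sizes: dict[tuple[str, str], float]  # specimen true CS draw, mm
    biases: dict[tuple[str, int], np.ndarray]  # (observer, landmark id) -> (3,)
    allometry_vector: np.ndarray  # (3k,), unit norm
    allometry_slope: float
    growth: dict[str, float]
    mean_cs: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "templates": {a: t.tolist() for a, t in self.templates.items()},
                "true_shapes": {
                    f"{a}|{s}": m.tolist() for (a, s), m in self.true_shapes.items()
                },
                "centroid_sizes": {
                    f"{a}|{s}": cs for (a, s), cs in self.centroid_sizes.items()
                },
                "biases": {
                    f"{o}|{lm}": b.tolist() for (o, lm), b in self.biases.items()
                },
                "allometry_vector": self.allometry_vector.tolist(),
                "allometry_slope": self.allometry_slope,
                "growth": self.growth,
                "mean_cs": self.mean_cs,
            },
            indent=2,
        )


def make_template(
    age: str, scheme: LandmarkScheme | None = None, growth: Mapping[str, float] | None = None
) -> Configuration:
    """The noise-free bilaterally symmetric head configuration for one age,
    scaled so its centroid size equals the age's growth target."""
    scheme = scheme or builtin_scheme()
    growth = growth or DEFAULT_GROWTH
    if age not in growth:
        raise ParameterError(f"unknown age {age!r}")
    arr = _base_shape(scheme) * float(growth[age])
    return Configuration.from_array(scheme, arr, f"template_{age}", age, "template", 1)


def default_design() -> SimParams:
    """The default study conditions: 10/9/10 specimens, 4 observers (3
    experienced, 1 novice), 2 trials, trouble landmarks inflated."""
    return SimParams()


def simulate_dataset(
    params: SimParams | None = None,
    scheme: LandmarkScheme | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TrialDataset, GroundTruth]:
    """Draw one balanced synthetic dataset plus its generative ground truth.

    ``seed`` overrides ``params.seed``; passing an explicit ``rng`` (used by
    replicate studies) bypasses seeding entirely.
    """
    params = params or default_design()
    scheme = scheme or builtin_scheme()
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    k = scheme.count
    base = _base_shape(scheme)
    if params.allometry_vector is not None:
        v = np.asarray(params.allometry_vector, dtype=float).ravel()
        if v.shape != (3 * k,):
            raise ParameterError(f"allometry_vector must have length {3 * k}")
        if abs(np.linalg.norm(v) - 1.0) > 1e-8:
            raise ParameterError("allometry_vector must have unit norm")
        if np.max(np.abs(v.reshape(k, 3).sum(axis=0))) > 1e-8:
            raise ParameterError("allometry_vector must have zero mean per axis")
    else:
        v = default_allometry_vector(scheme)
    v_mat = v.reshape(k, 3)
    slope = params.resolved_slope(k)
    mean_cs = float(params.design_centroid_sizes().mean())

    trouble = np.array([lm.trouble for lm in scheme])
    inflate = np.where(trouble, params.trouble_inflation, 1.0)[:, None]

    # per-(observer, landmark) bias vectors, fixed for the whole simulation
    biases: dict[tuple[str, int], np.ndarray] = {}
    bias_arr: dict[str, np.ndarray] = {}
    for obs, bias_sd in zip(params.observer_ids, params.bias_scales):
        b = rng.normal(0.0, bias_sd, size=(k, 3)) * inflate
        bias_arr[obs] = b
        for i, lm_id in enumerate(scheme.ids):
            biases[(obs, lm_id)] = b[i].copy()

    templates = {
        age: base * float(params.growth[age]) for age in AGES
    }
    true_shapes: dict[tuple[str, str], np.ndarray] = {}
    cs_draws: dict[tuple[str, str], float] = {}
    configs = []
    for age, n_spec in zip(AGES, params.n_specimens):
        target = float(params.growth[age])
        for s in range(n_spec):
            spec_id = f"{age.replace('.', '')}_s{s + 1:02d}"
            cs_i = target * (1.0 + params.size_cv * rng.standard_normal())
            cs_i = max(cs_i, 0.1 * target)
            shape_dev = rng.normal(0.0, params.sigma_specimen, size=(k, 3))
            true = cs_i * base + slope * (cs_i - mean_cs) * v_mat + shape_dev
            true_shapes[(age, spec_id)] = true
            cs_draws[(age, spec_id)] = cs_i
            for obs, sigma in zip(params.observer_ids, params.sigma_trial):
                for t in range(1, params.n_trials + 1):
                    noise = rng.normal(0.0, sigma, size=(k, 3)) * inflate
                    observed = true + bias_arr[obs] + noise
                    configs.append(
                        Configuration.from_array(scheme, observed, spec_id, age, obs, t)
                    )
    dataset = TrialDataset(scheme, configs)
    dataset.validate()
    truth = GroundTruth(
        templates=templates,
        true_shapes=true_shapes,
        centroid_sizes=cs_draws,
        biases=biases,
        allometry_vector=v,
        allometry_slope=slope,
        growth=dict(params.growth),
        mean_cs=mean_cs,
    )
    return dataset, truth


def expected_intra_distance_mean(sigma: float) -> float:
    """Closed-form mean trial-to-trial distance under isotropic Gaussian
    placement noise: the difference of two N(0, sigma^2 I_3) draws is
    N(0, 2 sigma^2 I_3), whose norm is sigma*sqrt(2) times a chi(3) variate."""
    return float(sigma * np.sqrt(2.0) * stats.chi(3).mean())


def expected_intra_distance_median(sigma: float) -> float:
    """Closed-form median of the trial-to-trial distance (chi(3) median)."""
    return float(sigma * np.sqrt(2.0) * stats.chi(3).median())
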