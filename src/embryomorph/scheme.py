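"""The standard craniofacial surface landmark scheme for E10.5-E12.5 mouse embryos.

The scheme catalogues 36 ectodermal surface landmarks: 6 on the midsagittal
midline and 15 bilateral (left/right) pairs.  Landmark identifiers run from
1 to 38 with 19 and 36 unused; identifiers are opaque labels, never array
indices.  Each landmark belongs to one of three anatomical subsets — Nasal,
Maxillary/Mandibular ("MaxMand") or Non-Facial — and may carry a "trouble"
flag marking landmarks with known high placement error.

Two trouble sets are distinguished:

* :data:`TROUBLE_LABELS` — the seven labels flagged in the scheme itself
  (``2, 7/24, 10/27, 13/30, 17/34, 18/35, 21/38``), used for the
  subset-removal allometry experiment.
* :data:`REMOVAL_LABELS` — the five labels recommended for outright removal
  from the standard set (``2, 7/24, 17/34, 18/35, 21/38``); the remaining
  two (10/27, 13/30) are considered fixable by clarifying their definitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DesignError, SchemaError

AGES: tuple[str, ...] = ("E10.5", "E11.5", "E12.5")

MIDLINE = "midline"
LEFT = "left"
RIGHT = "right"

NASAL = "Nasal"
MAXMAND = "MaxMand"
NONFACIAL = "NonFacial"
SUBSETS: tuple[str, ...] = (NASAL, MAXMAND, NONFACIAL)

#: pair labels flagged as trouble in the scheme table (7 labels, 13 ids)
TROUBLE_LABELS: frozenset[str] = frozenset(
    {"2", "7/24", "10/27", "13/30", "17/34", "18/35", "21/38"}
)

#: pair labels recommended for removal from the standard set (5 labels)
REMOVAL_LABELS: frozenset[str] = frozenset(
    {"2", "7/24", "17/34", "18/35", "21/38"}
)


@dataclass(frozen=True)
class LandmarkDef:
    """A single landmark definition.

    ``pair_id`` is the contralateral landmark's id for bilateral landmarks
    and ``None`` for midline landmarks.
    """

    id: int
    name: str
    side: str
    pair_id: int | None
    subset: str
    trouble: bool

    def __post_init__(self) -> None:
        if not (1 <= self.id <= 38) or self.id in (19, 36):
            raise SchemaError(f"invalid landmark id {self.id}")
        if self.side not in (MIDLINE, LEFT, RIGHT):
            raise SchemaError(f"invalid side {self.side!r}")
        if (self.side == MIDLINE) != (self.pair_id is None):
            raise SchemaError(
                f"landmark {self.id}: side={self.side} inconsistent with "
                f"pair_id={self.pair_id}"
            )
        if self.subset not in SUBSETS:
            raise SchemaError(f"invalid subset {self.subset!r}")

    @property
    def pair_label(self) -> str:
        """Label naming the landmark together with its mirror (e.g. ``7/24``)."""
        if self.pair_id is None:
            return str(self.id)
        lo, hi = sorted((self.id, self.pair_id))
        return f"{lo}/{hi}"


# (id, paired id or None, abbreviated name, subset, trouble)
# Listing order of the scheme table; bilateral rows expand left before right.
_TABLE: tuple[tuple[int, int | None, str, str, bool], ...] = (
    (1, None, "dorsal midline between forebrain and midbrain lobes", NONFACIAL, False),
    (2, None, "dorso-rostral midline extent of forebrain", NONFACIAL, True),
    (3, None, "midline dorsal-most extent of face", NASAL, False),
    (4, None, "midline rostral-most extent of medial nasal processes", NASAL, False),
    (5, None, "ventral midline point on primary palate", NASAL, False),
    (6, 23, "border of medial nasal process and forebrain", NASAL, False),
    (7, 24, "dorsal extent of rostral lateral nasal process", NASAL, True),
    (8, 25, "dorso-caudal-most point of lateral nasal process", NONFACIAL, False),
    (9, 26, "caudal intersection of lateral nasal and maxillary processes", NASAL, False),
    (10, 27, "caudo-lateral projection of dorsal maxillary edge", MAXMAND, True),
    (11, 28, "nasal aperture intersection of lateral nasal and maxillary", MAXMAND, False),
    (12, 29, "rostro-ventral intersection of medial nasal and maxillary", NASAL, False),
    (13, 30, "rostro-caudal extension of lateral nasal prominence", NASAL, True),
    (14, 31, "middle of medial side of nasal aperture", NASAL, False),
    (15, 32, "dorsal-most point of nasal aperture", NASAL, False),
    (16, 33, "corner of developing mouth", MAXMAND, False),
    (17, 34, "lateral extent of center of maxillary process", MAXMAND, True),
    (18, 35, "intersection of trigeminal bulge and pontine flexure", NONFACIAL, True),
    (20, 37, "medial rostral dorsal corner of mandibular process", MAXMAND, False),
    (21, 38, "ventral caudal-most point on forebrain bulge", NONFACIAL, True),
    (22, None, "caudal-most midline point on back of head", NONFACIAL, False),
)


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered, immutable catalogue of landmark definitions."""

    landmarks: tuple[LandmarkDef, ...]
    _by_id: Mapping[int, LandmarkDef] = field(
        default=None, repr=False, compare=False
    )  # type: ignore[assignment]

    def __post_init__(self) -> None:
        by_id = {lm.id: lm for lm in self.landmarks}
        if len(by_id) != len(self.landmarks):
            raise SchemaError("duplicate landmark ids")
        for lm in self.landmarks:
            if lm.pair_id is not None:
                mate = by_id.get(lm.pair_id)
                if mate is None or mate.pair_id != lm.id:
                    raise SchemaError(
                        f"landmark {lm.id}: pairing with {lm.pair_id} is not mutual"
                    )
                if mate.subset != lm.subset or mate.trouble != lm.trouble:
                    raise SchemaError(
                        f"pair {lm.pair_label}: subset/trouble flags disagree"
                    )
        object.__setattr__(self, "_by_id", by_id)

    @property
    def count(self) -> int:
        return len(self.landmarks)

    @property
    def ids(self) -> tuple[int, ...]:
        """Landmark ids in canonical (table listing) order."""
        return tuple(lm.id for lm in self.landmarks)

    def __iter__(self):
        return iter(self.landmarks)

    def __getitem__(self, lm_id: int) -> LandmarkDef:
        try:
            return self._by_id[lm_id]
        except KeyError:
            raise SchemaError(f"unknown landmark id {lm_id}") from None

    def __contains__(self, lm_id: int) -> bool:
        return lm_id in self._by_id

    def pair(self, lm_id: int) -> int | None:
        return self[lm_id].pair_id

    def pair_label(self, lm_id: int) -> str:
        return self[lm_id].pair_label

    @property
    def midline_ids(self) -> tuple[int, ...]:
        return tuple(lm.id for lm in self.landmarks if lm.side == MIDLINE)

    @property
    def pair_labels(self) -> tuple[str, ...]:
        """Unique pair labels in listing order (21 labels for the full scheme)."""
        seen: dict[str, None] = {}
        for lm in self.landmarks:
            seen.setdefault(lm.pair_label, None)
        return tuple(seen)

    def subset_ids(self, subset: str) -> tuple[int, ...]:
        if subset not in SUBSETS:
            raise SchemaError(f"unknown subset {subset!r}")
        return tuple(lm.id for lm in self.landmarks if lm.subset == subset)

    @property
    def trouble_ids(self) -> tuple[int, ...]:
        return tuple(lm.id for lm in self.landmarks if lm.trouble)

    def ids_for_labels(self, labels: Iterable[str]) -> tuple[int, ...]:
        """Expand pair labels (``"7/24"``, ``"2"``) to individual ids."""
        wanted = set(labels)
        known = set(self.pair_labels)
        unknown = wanted - known
        if unknown:
            raise SchemaError(f"unknown pair labels {sorted(unknown)}")
        return tuple(lm.id for lm in self.landmarks if lm.pair_label in wanted)

    def subscheme(self, keep_ids: Iterable[int]) -> "LandmarkScheme":
        """A scheme restricted to ``keep_ids``; bilateral pairs must survive whole."""
        keep = set(keep_ids)
        unknown = keep - set(self.ids)
        if unknown:
            raise SchemaError(f"unknown landmark ids {sorted(unknown)}")
        for lm in self.landmarks:
            if lm.id in keep and lm.pair_id is not None and lm.pair_id not in keep:
                raise SchemaError(
                    f"cannot keep landmark {lm.id} without its mirror {lm.pair_id}"
                )
        return LandmarkScheme(tuple(lm for lm in self.landmarks if lm.id in keep))

    def with_trouble(self, labels: Iterable[str]) -> "LandmarkScheme":
        """A copy of the scheme with the trouble flags replaced by the given
        pair labels (used e.g. to simulate error inflation on a chosen set)."""
        wanted = set(labels)
        unknown = wanted - set(self.pair_labels)
        if unknown:
            raise SchemaError(f"unknown pair labels {sorted(unknown)}")
        return LandmarkScheme(
            tuple(
                LandmarkDef(
                    lm.id, lm.name, lm.side, lm.pair_id, lm.subset,
                    lm.pair_label in wanted,
                )
                for lm in self.landmarks
            )
        )

    def to_json(self) -> str:
        records = [
            {
                "id": lm.id,
                "name": lm.name,
                "side": lm.side,
                "pair_id": lm.pair_id,
                "subset": lm.subset,
                "trouble": lm.trouble,
            }
            for lm in self.landmarks
        ]
        return json.dumps(records, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LandmarkScheme":
        records = json.loads(text)
        return cls(tuple(LandmarkDef(**r) for r in records))


def builtin_scheme() -> LandmarkScheme:
    """The canonical 36-landmark scheme (6 midline + 15 bilateral pairs).

    The first-listed id of each bilateral pair is designated the left
    landmark, its parenthesised mate the right.
    """
    defs: list[LandmarkDef] = []
    for lm_id, mate, name, subset, trouble in _TABLE:
        if mate is None:
            defs.append(LandmarkDef(lm_id, name, MIDLINE, None, subset, trouble))
        else:
            defs.append(LandmarkDef(lm_id, name, LEFT, mate, subset, trouble))
            defs.append(LandmarkDef(mate, name, RIGHT, lm_id, subset, trouble))
    return LandmarkScheme(tuple(defs))


@dataclass
class Configuration:
    """One observer's landmark placements on one specimen in one trial.

    ``coords`` maps landmark id to a length-3 float array in mm.
    """

    specimen_id: str
    age: str
    observer_id: str
    trial: int
    coords: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if self.age not in AGES:
            raise SchemaError(f"unknown age {self.age!r}; expected one of {AGES}")
        if self.trial < 1:
            raise SchemaError(f"trial must be >= 1, got {self.trial}")
        self.coords = {
            int(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.coords.items()
        }

    def validate(self, scheme: LandmarkScheme) -> None:
        present = set(self.coords)
        expected = set(scheme.ids)
        missing = expected - present
        extra = present - expected
        if missing:
            raise SchemaError(
                f"configuration {self.key()}: missing landmark ids {sorted(missing)}"
            )
        if extra:
            raise SchemaError(
                f"configuration {self.key()}: unknown landmark ids {sorted(extra)}"
            )
        for lm_id, xyz in self.coords.items():
            if not np.all(np.isfinite(xyz)):
                raise SchemaError(
                    f"configuration {self.key()}: non-finite coordinates at "
                    f"landmark {lm_id}"
                )

    def key(self) -> tuple[str, str, str, int]:
        return (self.age, self.specimen_id, self.observer_id, self.trial)

    def array(self, scheme: LandmarkScheme) -> np.ndarray:
        """Coordinates as a (k, 3) array in scheme order."""
        return np.array([self.coords[i] for i in scheme.ids], dtype=float)

    @classmethod
    def from_array(
        cls,
        scheme: LandmarkScheme,
        arr: np.ndarray,
        specimen_id: str,
        age: str,
        observer_id: str,
        trial: int,
    ) -> "Configuration":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (scheme.count, 3):
            raise SchemaError(f"expected shape {(scheme.count, 3)}, got {arr.shape}")
        coords = {lm_id: arr[i].copy() for i, lm_id in enumerate(scheme.ids)}
        return cls(specimen_id, age, observer_id, trial, coords)


@dataclass
class TrialDataset:
    """A balanced collection of configurations over specimens, observers, trials."""

    scheme: LandmarkScheme
    configurations: list[Configuration]

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str, str, int], Configuration] = {}
        for cfg in self.configurations:
            key = cfg.key()
            if key in self._index:
                raise DesignError(f"duplicate configuration {key}")
            self._index[key] = cfg

    def validate(self, require_balance: bool = True) -> None:
        for cfg in self.configurations:
            cfg.validate(self.scheme)
        if require_balance:
            missing = self.missing_cells()
            if missing:
                raise DesignError(
                    f"unbalanced design; missing cells: {sorted(missing)[:10]}"
                    + (" ..." if len(missing) > 10 else "")
                )

    def missing_cells(self) -> set[tuple[str, str, str, int]]:
        """Cells absent from the full (specimen, observer, trial) cross."""
        if not self.configurations:
            return set()
        observers = self.observers
        trials = self.trials
        missing: set[tuple[str, str, str, int]] = set()
        for age, spec in self.specimens:
            for obs in observers:
                for t in trials:
                    if (age, spec, obs, t) not in self._index:
                        missing.add((age, spec, obs, t))
        return missing

    def get(
        self, age: str, specimen_id: str, observer_id: str, trial: int
    ) -> Configuration:
        return self._index[(age, specimen_id, observer_id, trial)]

    @property
    def ages(self) -> tuple[str, ...]:
        return tuple(a for a in AGES if any(c.age == a for c in self.configurations))

    @property
    def specimens(self) -> tuple[tuple[str, str], ...]:
        """(age, specimen_id) pairs in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for c in self.configurations:
            seen.setdefault((c.age, c.specimen_id), None)
        return tuple(seen)

    @property
    def observers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.configurations:
            seen.setdefault(c.observer_id, None)
        return tuple(seen)

    @property
    def trials(self) -> tuple[int, ...]:
        return tuple(sorted({c.trial for c in self.configurations}))

    @property
    def design(self) -> tuple[tuple[int, ...], int, int]:
        """(specimens per age, n observers, n trials)."""
        per_age = tuple(
            sum(1 for a, _ in self.specimens if a == age) for age in self.ages
        )
        return per_age, len(self.observers), len(self.trials)

    def subset(
        self,
        ages: Sequence[str] | None = None,
        observers: Sequence[str] | None = None,
    ) -> "TrialDataset":
        keep = [
            c
            for c in self.configurations
            if (ages is None or c.age in ages)
            and (observers is None or c.observer_id in observers)
        ]
        return TrialDataset(self.scheme, keep)

    def restrict_landmarks(self, keep_ids: Iterable[int]) -> "TrialDataset":
        sub = self.scheme.subscheme(keep_ids)
        keep = set(sub.ids)
        cfgs = [
            Configuration(
                c.specimen_id,
                c.age,
                c.observer_id,
                c.trial,
                {i: c.coords[i] for i in keep},
            )
            for c in self.configurations
        ]
        return TrialDataset(sub, cfgs)

    def observer_mean_shape(
        self, age: str, specimen_id: str, observer_id: str
    ) -> np.ndarray:
        """Mean over trials of one observer's placements, (k, 3) in scheme order."""
        arrs = [
            cfg.array(self.scheme)
            for cfg in self.configurations
            if cfg.age == age
            and cfg.specimen_id == specimen_id
            and cfg.observer_id == observer_id
        ]
        if not arrs:
            raise DesignError(
                f"no configurations for ({age}, {specimen_id}, {observer_id})"
            )
        return np.mean(arrs, axis=0)

    def specimen_mean_shape(
        self, age: str, specimen_id: str, observers: Sequence[str] | None = None
    ) -> np.ndarray:
        """Average of the per-observer trial means over ``observers``."""
        obs = tuple(observers) if observers is not None else self.observers
        return np.mean(
            [self.observer_mean_shape(age, specimen_id, o) for o in obs], axis=0
        )
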