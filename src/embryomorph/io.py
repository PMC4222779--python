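"""Reading and writing landmark coordinate files (CSV and TPS dialects).

CSV dialect: UTF-8, comma separated, header row exactly
``specimen,age,observer,trial,landmark,x,y,z``; one row per landmark;
coordinates printed with 12 significant digits (sub-nanometre round-trip at
mm scale).

TPS dialect: 3D ``LM3=`` blocks, one configuration per block; the ``ID=``
key carries ``specimen|age|observer|trial``.  TPS is the de facto exchange
format of landmark morphometrics, so aligned shapes written here can be fed
to standard tools.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, SchemaError
from .scheme import Configuration, LandmarkScheme, TrialDataset, builtin_scheme

CSV_HEADER = "specimen,age,observer,trial,landmark,x,y,z"
FORMATS = ("csv", "tps")


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_dataset(
    dataset: TrialDataset, path: str | os.PathLike, format: str = "csv"
) -> Path:
    """Write a dataset to ``path``; returns the path written."""
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    path = Path(path)
    if format == "csv":
        lines = [CSV_HEADER]
        for cfg in dataset.configurations:
            for lm_id in dataset.scheme.ids:
                x, y, z = cfg.coords[lm_id]
                lines.append(
                    f"{cfg.specimen_id},{cfg.age},{cfg.observer_id},{cfg.trial},"
                    f"{lm_id},{_fmt(x)},{_fmt(y)},{_fmt(z)}"
                )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        blocks = []
        for cfg in dataset.configurations:
            rows = [f"LM3={dataset.scheme.count}"]
            for lm_id in dataset.scheme.ids:
                x, y, z = cfg.coords[lm_id]
                rows.append(f"{_fmt(x)} {_fmt(y)} {_fmt(z)}")
            rows.append(
                f"ID={cfg.specimen_id}|{cfg.age}|{cfg.observer_id}|{cfg.trial}"
            )
            blocks.append("\n".join(rows))
        path.write_text("\n".join(blocks) + "\n", encoding="utf-8")
    return path


def _read_csv(path: Path, scheme: LandmarkScheme) -> list[Configuration]:
    df = pd.read_csv(path)
    expected_cols = CSV_HEADER.split(",")
    if list(df.columns) != expected_cols:
        raise SchemaError(
            f"{path}: expected header {CSV_HEADER!r}, got {list(df.columns)}"
        )
    cfgs: list[Configuration] = []
    if df.empty:
        return cfgs
    for (spec, age, obs, trial), grp in df.groupby(
        ["specimen", "age", "observer", "trial"], sort=False
    ):
        ids = grp["landmark"].astype(int)
        unknown = set(ids) - set(scheme.ids)
        if unknown:
            raise SchemaError(f"{path}: unknown landmark ids {sorted(unknown)}")
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise SchemaError(f"{path}: duplicate landmark ids {dups}")
        coords = {
            int(i): np.array([r.x, r.y, r.z], dtype=float)
            for i, r in zip(ids, grp.itertuples())
        }
        cfg = Configuration(str(spec), str(age), str(obs), int(trial), coords)
        cfg.validate(scheme)
        cfgs.append(cfg)
    return cfgs


def _read_tps(path: Path, scheme: LandmarkScheme) -> list[Configuration]:
    cfgs: list[Configuration] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise SchemaError(f"{path}:{i + 1}: expected 'LM3=' block, got {line!r}")
        k = int(line.split("=", 1)[1])
        pts = []
        i += 1
        for _ in range(k):
            parts = lines[i].split()
            if len(parts) != 3:
                raise SchemaError(f"{path}:{i + 1}: expected 3 coordinates")
            pts.append([float(p) for p in parts])
            i += 1
        ident = None
        while i < len(lines) and "=" in lines[i]:
            key, _, val = lines[i].partition("=")
            if key.strip().upper() == "ID":
                ident = val.strip()
            if key.strip().upper().startswith("LM"):
                break
            i += 1
        if ident is None:
            raise SchemaError(f"{path}: TPS block without ID= key")
        fields = ident.split("|")
        if len(fields) != 4:
            raise SchemaError(
                f"{path}: ID must be 'specimen|age|observer|trial', got {ident!r}"
            )
        spec, age, obs, trial = fields
        if k != scheme.count:
            raise SchemaError(
                f"{path}: block {ident!r} has {k} landmarks, scheme expects "
                f"{scheme.count}"
            )
        arr = np.asarray(pts, dtype=float)
        cfg = Configuration.from_array(scheme, arr, spec, age, obs, int(trial))
        cfg.validate(scheme)
        cfgs.append(cfg)
    return cfgs


def read_dataset(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    format: str = "csv",
    scheme: LandmarkScheme | None = None,
    require_balance: bool = True,
) -> TrialDataset:
    """Read one or more coordinate files into a :class:`TrialDataset`.

    Raises :class:`SchemaError` for malformed files or unknown/missing
    landmark ids and :class:`DesignError` (listing the missing cells) when
    the combined files do not form a balanced design.
    """
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    scheme = scheme or builtin_scheme()
    reader = _read_csv if format == "csv" else _read_tps
    cfgs: list[Configuration] = []
    for p in paths:
        cfgs.extend(reader(Path(p), scheme))
    ds = TrialDataset(scheme, cfgs)
    ds.validate(require_balance=require_balance)
    return ds


def dataset_to_frame(dataset: TrialDataset) -> pd.DataFrame:
    """Long-format DataFrame with one row per (configuration, landmark)."""
    rows = []
    for cfg in dataset.configurations:
        for lm_id in dataset.scheme.ids:
            x, y, z = cfg.coords[lm_id]
            rows.append(
                (cfg.specimen_id, cfg.age, cfg.observer_id, cfg.trial, lm_id, x, y, z)
            )
    return pd.DataFrame(
        rows,
        columns=["specimen", "age", "observer", "trial", "landmark", "x", "y", "z"],
    )
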