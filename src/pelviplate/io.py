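"""Readers and writers for the pipeline's plain-text formats.

* Landmark JSON: ``{"side": "left", "units": "mm", "raw": {"O": [x, y,
  z], ...}, "derived": {...}}``.  Coordinates round-trip exactly
  (shortest-repr decimal strings).
* Population CSV: ``id, side, sex, geo_group, lpr_mm, lqr_mm, lir_mm,
  total_mm`` — UTF-8, header required, '.' decimal.
* Catalog JSON: a list of plate objects with model, size class, side,
  total and region lengths, and the ratio family.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import PlateCatalog, PlateSpec, RatioFamily
from .geometry import DERIVED_NAMES, RAW_NAMES, LandmarkSet
from .synthetic import POPULATION_COLUMNS

__all__ = [
    "load_landmarks",
    "dump_landmarks",
    "load_population",
    "dump_population",
    "load_catalog",
    "dump_catalog",
]


class FormatError(ValueError):
    """An input file does not follow its documented schema."""


def _check_names(found: Iterable[str], allowed: tuple[str, ...], kind: str) -> None:
    unknown = sorted(set(found) - set(allowed))
    if unknown:
        raise FormatError(f"unknown {kind} landmark name(s): {', '.join(unknown)}")


def load_landmarks(path: str | Path) -> LandmarkSet:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: expected a JSON object")
    units = payload.get("units", "mm")
    if units != "mm":
        raise FormatError(f"{path}: units must be 'mm', got {units!r}")
    side = payload.get("side", "left")

    def parse(section: str, allowed: tuple[str, ...]):
        block = payload.get(section)
        if block is None:
            return None
        if not isinstance(block, dict):
            raise FormatError(f"{path}: '{section}' must be an object")
        _check_names(block, allowed, section)
        try:
            return {k: np.asarray(v, dtype=float) for k, v in block.items()}
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad coordinates in '{section}' ({exc})") from exc

    derived = parse("derived", DERIVED_NAMES) or {}
    raw = parse("raw", RAW_NAMES)
    try:
        return LandmarkSet(derived=derived, raw=raw, side=side)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def dump_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    payload: dict = {"side": lm.side, "units": "mm"}
    if lm.raw is not None:
        payload["raw"] = {k: [float(c) for c in v] for k, v in lm.raw.items()}
    payload["derived"] = {k: [float(c) for c in v] for k, v in lm.derived.items()}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def load_population(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    for c in ("lpr_mm", "lqr_mm", "lir_mm", "total_mm"):
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise FormatError(f"{path}: column {c} must be numeric")
    return df[list(POPULATION_COLUMNS)]


def dump_population(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"population table missing column(s): {', '.join(missing)}")
    df[list(POPULATION_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


def _plate_to_dict(p: PlateSpec) -> dict:
    return {
        "model": p.model,
        "size_class": p.size_class,
        "side": p.side,
        "total_mm": p.total_mm,
        "lpr_mm": p.lpr_mm,
        "lqr_mm": p.lqr_mm,
        "lir_mm": p.lir_mm,
        "r1": p.family.r1,
        "r2": p.family.r2,
    }


def dump_catalog(catalog: PlateCatalog, path: str | Path) -> None:
    payload = [_plate_to_dict(p) for p in catalog]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def load_catalog(path: str | Path) -> PlateCatalog:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, list) or not payload:
        raise FormatError(f"{path}: expected a non-empty JSON list of plates")
    plates = []
    for i, entry in enumerate(payload):
        try:
            plates.append(
                PlateSpec(
                    model=str(entry["model"]),
                    size_class=str(entry.get("size_class", "")),
                    side=str(entry.get("side", "left")),
                    total_mm=float(entry["total_mm"]),
                    lpr_mm=float(entry["lpr_mm"]),
                    lqr_mm=float(entry["lqr_mm"]),
                    lir_mm=float(entry["lir_mm"]),
                    family=RatioFamily(float(entry["r1"]), float(entry["r2"])),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: plate entry {i}: {exc}") from exc
    try:
        return PlateCatalog(plates=tuple(plates))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
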