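"""Reading and writing concentration-time profile CSV files.

The profile format is a plain CSV with columns ``time_h`` and ``conc_ng_ml``
preceded by a ``#``-commented metadata block::

    # dose_mg_per_kg: 5
    # route: oral
    # species: mouse
    # body_weight_kg: 0.02
    # label: group mean
    time_h,conc_ng_ml
    0.0,0.0
    ...

Either ``dose_mg`` (total) or ``dose_mg_per_kg`` must be present.  Several
profiles may share one file, separated by repeated metadata blocks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidProfileError
from .nca import ConcentrationTimeProfile

_META_KEYS = {"dose_mg", "dose_mg_per_kg", "route", "species",
              "body_weight_kg", "label"}


def _profile_from_block(meta: dict[str, str], rows: list[tuple[float, float]]
                        ) -> ConcentrationTimeProfile:
    if "dose_mg" in meta:
        dose, per_kg = float(meta["dose_mg"]), False
    elif "dose_mg_per_kg" in meta:
        dose, per_kg = float(meta["dose_mg_per_kg"]), True
    else:
        raise InvalidProfileError("metadata needs dose_mg or dose_mg_per_kg")
    arr = np.asarray(rows, dtype=float)
    return ConcentrationTimeProfile(
        times=arr[:, 0], concentrations=arr[:, 1],
        dose_amount=dose, dose_per_kg=per_kg,
        route=meta.get("route", "oral"),
        species=meta.get("species", ""),
        body_weight=float(meta["body_weight_kg"]) if "body_weight_kg" in meta else None,
        label=meta.get("label", ""),
    )


def read_profiles(path: str | Path) -> list[ConcentrationTimeProfile]:
    """Parse one or more profiles from a profile CSV (see module docstring).

    Unsorted sample times are rejected."""
    profiles: list[ConcentrationTimeProfile] = []
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []

    def flush():
        if rows:
            profiles.append(_profile_from_block(meta, rows))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if rows:
                flush()
                rows.clear()
                meta = {}
            key, _, value = line.lstrip("# ").partition(":")
            key = key.strip()
            if key in _META_KEYS:
                meta[key] = value.strip()
            continue
        if line.lower().startswith("time_h"):
            continue
        t_str, _, c_str = line.partition(",")
        c_str = c_str.strip()
        conc = float("nan") if c_str in ("", "BLQ", "blq", "NA") else float(c_str)
        rows.append((float(t_str), conc))
    flush()
    if not profiles:
        raise InvalidProfileError(f"no profiles found in {path}")
    return profiles


def write_profiles(
    profiles: list[ConcentrationTimeProfile], path: str | Path
) -> None:
    """Write profiles in the same block format :func:`read_profiles` parses."""
    lines: list[str] = []
    for p in profiles:
        key = "dose_mg_per_kg" if p.dose_per_kg else "dose_mg"
        lines.append(f"# {key}: {p.dose_amount:g}")
        lines.append(f"# route: {p.route}")
        if p.species:
            lines.append(f"# species: {p.species}")
        if p.body_weight is not None:
            lines.append(f"# body_weight_kg: {p.body_weight:g}")
        if p.label:
            lines.append(f"# label: {p.label}")
        lines.append("time_h,conc_ng_ml")
        for t, c in zip(p.times, p.concentrations):
            lines.append(f"{t:g},{c:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def results_to_frame(results) -> pd.DataFrame:
    """Tabulate a list of NCA results as a DataFrame (one row per profile)."""
    from dataclasses import asdict

    rows = []
    for r in results:
        d = asdict(r)
        d.pop("extras", None)
        rows.append(d)
    return pd.DataFrame(rows)
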