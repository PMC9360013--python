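"""Derived breast-density measures.

From optically fitted composition: the percent breast density index (%BDI),
the composite optical index, and %collagen-water.  From per-breast volumetric
inputs: percent and absolute fibroglandular volume (%FGV, AFGV; DXA) and
percent and absolute mammographic breast density (%MBD, AMBD; volumetric
mammography).  Percent measures from imaging are computed per side first and
then averaged over the two breasts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def percent_bdi(water_pct, collagen_pct, lipid_pct):
    """Percent breast density index: (collagen + water) / (collagen + water + lipid) * 100.

    Scale-invariant in the three concentrations; strictly decreasing in lipid.
    """
    w = np.asarray(water_pct, dtype=float)
    c = np.asarray(collagen_pct, dtype=float)
    l = np.asarray(lipid_pct, dtype=float)
    if np.any(w < 0) or np.any(c < 0) or np.any(l < 0):
        raise ValueError("concentrations must be >= 0")
    denom = c + w + l
    if np.any(denom <= 0):
        raise ValueError("collagen + water + lipid must be > 0")
    out = (c + w) / denom * 100.0
    return float(out) if out.ndim == 0 else out


def optical_index(water_pct, collagen_pct, lipid_pct, scattering_power):
    """Composite optical index: ln((collagen + water) * scattering_power) / lipid.

    Natural log, concentrations in percent units.  Combining collagen-water
    with the scattering power (a cellularity proxy) against lipid improves
    the density contrast over any single fitted parameter.
    """
    w = np.asarray(water_pct, dtype=float)
    c = np.asarray(collagen_pct, dtype=float)
    l = np.asarray(lipid_pct, dtype=float)
    b = np.asarray(scattering_power, dtype=float)
    arg = (c + w) * b
    if np.any(arg <= 0):
        raise ValueError("(collagen + water) * power must be > 0")
    if np.any(l <= 0):
        raise ValueError("lipid must be > 0")
    out = np.log(arg) / l
    return float(out) if out.ndim == 0 else out


def percent_collagen_water(collagen_pct, water_pct):
    """%collagen-water: the sum of the collagen and water concentrations."""
    c = np.asarray(collagen_pct, dtype=float)
    w = np.asarray(water_pct, dtype=float)
    if np.any(c < 0) or np.any(w < 0):
        raise ValueError("concentrations must be >= 0")
    out = c + w
    return float(out) if out.ndim == 0 else out


def _percent_volume_pair(dense_left, vol_left, dense_right, vol_right, what: str):
    sides = []
    for dense, vol, side in ((dense_left, vol_left, "left"), (dense_right, vol_right, "right")):
        if dense is None or vol is None or (isinstance(vol, float) and math.isnan(vol)):
            continue
        if vol <= 0:
            raise ValueError(f"{side} total volume must be > 0")
        if dense < 0 or dense > vol:
            raise ValueError(f"{side} {what} must lie in [0, total volume]")
        sides.append((dense / vol * 100.0, dense))
    if not sides:
        raise ValueError("at least one side required")
    pct = float(np.mean([s[0] for s in sides]))
    absolute = float(np.mean([s[1] for s in sides]))
    return pct, absolute


def percent_fgv(fgv_left, vol_left, fgv_right, vol_right):
    """(%FGV, AFGV): per-side percent fibroglandular volume, then the
    unweighted mean over both breasts; AFGV is the mean per-side FGV in cm^3.

    Pass None for a missing side (single-side measurement).
    """
    return _percent_volume_pair(fgv_left, vol_left, fgv_right, vol_right, "FGV")


def percent_mbd(dense_left, vol_left, dense_right, vol_right):
    """(%MBD, AMBD): mammographic dense volume relative to total breast
    volume, per side then averaged; AMBD is the mean per-side dense volume."""
    return _percent_volume_pair(dense_left, vol_left, dense_right, vol_right,
                                "dense volume")


MEASURE_COLUMNS = [
    "participant_id", "pct_bdi", "optical_index", "pct_collagen_water",
    "pct_fgv", "afgv_cm3", "pct_mbd", "ambd_cm3",
]


def compute_measures(compositions: pd.DataFrame, volumetrics: pd.DataFrame) -> pd.DataFrame:
    """Join fitted compositions with volumetric imaging into one measures table.

    ``compositions``: one row per participant with water_pct, collagen_pct,
    lipid_pct, power columns (the spectral pipeline output).  ``volumetrics``:
    per participant, per-side fgv/dense/total volumes in cm^3 (dense_* may be
    NaN, e.g. daughters have no mammography).  Participants present in only
    one input keep NaN in the other modality's columns.
    """
    comp = compositions.set_index("participant_id")
    volu = volumetrics.set_index("participant_id")
    ids = sorted(set(comp.index) | set(volu.index))
    rows = []
    for pid in ids:
        row: dict = {"participant_id": pid, "pct_bdi": np.nan, "optical_index": np.nan,
                     "pct_collagen_water": np.nan, "pct_fgv": np.nan, "afgv_cm3": np.nan,
                     "pct_mbd": np.nan, "ambd_cm3": np.nan}
        if pid in comp.index:
            c = comp.loc[pid]
            row["pct_bdi"] = percent_bdi(c["water_pct"], c["collagen_pct"], c["lipid_pct"])
            row["optical_index"] = optical_index(
                c["water_pct"], c["collagen_pct"], c["lipid_pct"], c["power"])
            row["pct_collagen_water"] = percent_collagen_water(
                c["collagen_pct"], c["water_pct"])
        if pid in volu.index:
            v = volu.loc[pid]
            row["pct_fgv"], row["afgv_cm3"] = percent_fgv(
                v["fgv_left_cm3"], v["vol_left_cm3"],
                v["fgv_right_cm3"], v["vol_right_cm3"])
            if np.isfinite(v.get("dense_left_cm3", np.nan)):
                row["pct_mbd"], row["ambd_cm3"] = percent_mbd(
                    v["dense_left_cm3"], v["vol_left_cm3"],
                    v["dense_right_cm3"], v["vol_right_cm3"])
        rows.append(row)
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
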