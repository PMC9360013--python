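"""Spectrum usability filtering, constrained chromophore fitting, and
per-participant aggregation.

The inverse problem recovers 7 parameters per spectrum — water, lipid,
collagen, total hemoglobin with its oxygenated fraction, scattering amplitude
and scattering power — by bound-constrained least squares on log-signal
residuals from multiple Latin-hypercube starting points.  Constraints follow
the physiological fit ranges (water 4-90%, lipid 10-95%, collagen 1-30%,
total Hb 0.2-1%, amplitude 0.1-4 mm^-1, power 0.05-5) with the chromophore
sum capped below 100%.  The best start is the smallest-SSE candidate with at
most 2 parameters at their bounds; spectra where no start qualifies are
dropped with an explicit failure marker.  Accepted fits are averaged,
unweighted, over all spectra from both breasts of a participant.

Usability rules: a spectrum enters fitting only if it has at least 7 usable
wavelengths (matching the 7 unknowns), usable data at 985 nm, and usable
data at 905 or 940 nm — the wavelengths that separate the water and lipid
absorption peaks.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .basis import ChromophoreBasis
from .forward_model import reduced_scattering, slab_transmittance
from .records import (FitBounds, FitResult, Geometry, MeasuredSpectrum,
                      ParticipantComposition, ScatteringParams,
                      TissueComposition, geometry_for_cup)

#: QC reason codes, in precedence order.
REASON_TOO_FEW = "fewer_than_7_wavelengths"
REASON_NO_985 = "missing_985"
REASON_NO_905_940 = "missing_905_and_940"
REASON_FIT_FAILED = "no_qualifying_fit"

MIN_USABLE_WAVELENGTHS = 7
_WL_TOL_NM = 0.5

#: normalized distance from a bound at which a parameter counts as "at bounds"
AT_BOUND_TOL = 1e-6
#: feasibility tolerance for the joint chromophore-sum cap
SUM_CAP_TOL = 1e-9


def _has_wavelength(spectrum: MeasuredSpectrum, target: float) -> bool:
    wl = spectrum.usable_wavelengths()
    return bool(wl.size and np.any(np.abs(wl - target) <= _WL_TOL_NM))


def qc_filter(spectra: list[MeasuredSpectrum]
              ) -> tuple[list[MeasuredSpectrum], list[dict]]:
    """Apply the usability rules; returns (retained, exclusion log).

    A pure per-spectrum filter (input order never affects the outcome).
    Each excluded spectrum gets exactly one reason, checked in order:
    too few usable wavelengths, then missing 985 nm, then missing both
    905 and 940 nm.
    """
    retained, excluded = [], []
    for s in spectra:
        if s.n_usable < MIN_USABLE_WAVELENGTHS:
            reason = REASON_TOO_FEW
        elif not _has_wavelength(s, 985.0):
            reason = REASON_NO_985
        elif not (_has_wavelength(s, 905.0) or _has_wavelength(s, 940.0)):
            reason = REASON_NO_905_940
        else:
            retained.append(s)
            continue
        excluded.append({"spectrum_key": s.key(), "participant_id": s.participant_id,
                         "reason": reason})
    return retained, excluded


# --------------------------------------------------------------------------
# Parameterization: 7 optimizer coordinates, each box-bounded, normalized to
# [0, 1].  Fitting (total Hb, oxygenated fraction) instead of (oxy, deoxy)
# turns the joint hemoglobin bound into a box; only the chromophore-sum cap
# remains a joint constraint, enforced by hinge penalty plus projection.

PARAM_NAMES = ("water", "lipid", "collagen", "total_hb", "oxy_frac",
               "amplitude", "power")


def _bounds_arrays(bounds: FitBounds) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([bounds.water[0], bounds.lipid[0], bounds.collagen[0],
                   bounds.total_hb[0], 0.0, bounds.amplitude[0], bounds.power[0]])
    hi = np.array([bounds.water[1], bounds.lipid[1], bounds.collagen[1],
                   bounds.total_hb[1], 1.0, bounds.amplitude[1], bounds.power[1]])
    return lo, hi


def _to_params(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + u * (hi - lo)


def _project_sum_cap(p: np.ndarray, lo: np.ndarray, cap: float) -> np.ndarray:
    """Scale chromophores toward their lower bounds until the sum sits on the cap."""
    idx = [0, 1, 2, 3]  # water, lipid, collagen, total_hb
    s = p[idx].sum()
    target = cap - 1e-10
    if s <= target:
        return p
    base = lo[idx].sum()
    t = (target - base) / (s - base)
    out = p.copy()
    out[idx] = lo[idx] + t * (p[idx] - lo[idx])
    return out


def _result_from_params(p: np.ndarray) -> tuple[TissueComposition, ScatteringParams]:
    water, lipid, collagen, thb, f_oxy, amp, power = p
    comp = TissueComposition(water, lipid, collagen, f_oxy * thb,
                             (1.0 - f_oxy) * thb)
    return comp, ScatteringParams(amp, power)


def fit_spectrum(spectrum: MeasuredSpectrum, bounds: FitBounds,
                 basis: ChromophoreBasis, geometry: Geometry,
                 n_starts: int = 8, seed: int = 0, *,
                 log_residuals: bool = True,
                 free_mask: np.ndarray | None = None,
                 truth_params: np.ndarray | None = None,
                 tol: float = 1e-10, max_nfev: int = 300) -> list[FitResult]:
    """Fit one QC-passed spectrum from ``n_starts`` Latin-hypercube starts.

    Returns one :class:`FitResult` per start, sorted by (sse, n_at_bounds,
    start_index).  ``free_mask``/``truth_params`` allow fitting a subset of
    the 7 parameters with the rest pinned (used by grid-oracle checks).
    Deterministic given (spectrum, seed).
    """
    retained, _ = qc_filter([spectrum])
    if not retained:
        raise ValueError("spectrum does not pass the usability rules; "
                         "run qc_filter first")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = _bounds_arrays(bounds)
    mask = np.ones(7, dtype=bool) if free_mask is None else np.asarray(free_mask, bool)
    pinned = np.zeros(7) if truth_params is None else np.asarray(truth_params, float)

    ok = spectrum.usable
    lam = spectrum.wavelengths[ok]
    meas = spectrum.signals[ok]
    target = np.log(meas) if log_residuals else meas
    eps = basis.specific_absorption(lam)  # (n_lam, 5)
    offset = spectrum.offset_mm
    cap = bounds.sum_cap_pct
    penalty_w = 1e4

    def residuals(u_free: np.ndarray) -> np.ndarray:
        p = pinned.copy()
        p[mask] = _to_params(u_free, lo[mask], hi[mask])
        water, lipid, collagen, thb, f_oxy, amp, power = p
        conc = np.array([water, lipid, collagen, f_oxy * thb, (1 - f_oxy) * thb])
        mua = eps @ conc
        mus = reduced_scattering(ScatteringParams(amp, power), lam)
        sim = slab_transmittance(mua, mus, geometry, offset)
        model = np.log(sim) if log_residuals else sim
        overshoot = max(0.0, water + lipid + collagen + thb - (cap - 1e-9))
        return np.append(model - target, penalty_w * overshoot)

    sampler = qmc.LatinHypercube(d=int(mask.sum()), seed=seed)
    starts = sampler.random(n_starts)
    results = []
    for i, u0 in enumerate(starts):
        # keep the start feasible w.r.t. the sum cap
        p0 = pinned.copy()
        p0[mask] = _to_params(u0, lo[mask], hi[mask])
        p0 = _project_sum_cap(p0, lo, cap)
        u0 = (p0[mask] - lo[mask]) / (hi[mask] - lo[mask])
        sol = least_squares(residuals, np.clip(u0, 0, 1), bounds=(0.0, 1.0),
                            method="trf", xtol=tol, ftol=tol, gtol=tol,
                            max_nfev=max_nfev)
        p = pinned.copy()
        p[mask] = _to_params(sol.x, lo[mask], hi[mask])
        p = _project_sum_cap(p, lo, cap)
        u_full = (p - lo) / (hi - lo)
        data_resid = residuals((p[mask] - lo[mask]) / (hi[mask] - lo[mask]))[:-1]
        sse = float(data_resid @ data_resid)
        n_at = int(np.sum((u_full[mask] <= AT_BOUND_TOL)
                          | (u_full[mask] >= 1.0 - AT_BOUND_TOL)))
        comp, scat = _result_from_params(p)
        # an iteration-capped run that has already driven the residuals to
        # numerical zero is a solution, not a failure
        rms = math.sqrt(sse / max(data_resid.size, 1))
        results.append(FitResult(comp, scat, sse, n_at, i,
                                 converged=bool(sol.status > 0 or rms < 1e-8)))
    results.sort(key=lambda r: (r.sse, r.n_at_bounds, r.start_index))
    return results


def select_best_fit(candidates: list[FitResult]) -> FitResult | None:
    """Smallest-SSE converged candidate with at most 2 parameters at bounds.

    Ties on SSE break toward fewer parameters at bounds, then lower start
    index.  Returns None (fit failure) when no candidate qualifies; such a
    spectrum contributes nothing downstream.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    ok = [c for c in candidates if c.converged and c.n_at_bounds <= 2]
    if not ok:
        return None
    return min(ok, key=lambda r: (r.sse, r.n_at_bounds, r.start_index))


def aggregate_participant(fits: list[tuple[FitResult, str]], participant_id: str
                          ) -> ParticipantComposition:
    """Unweighted arithmetic mean of accepted fits over both breasts."""
    if not fits:
        raise ValueError(f"participant {participant_id}: no usable spectra")
    arr = np.array([[f.composition.water_pct, f.composition.lipid_pct,
                     f.composition.collagen_pct, f.composition.oxyhb_pct,
                     f.composition.deoxyhb_pct, f.scattering.amplitude,
                     f.scattering.power] for f, _ in fits])
    m = arr.mean(axis=0)
    return ParticipantComposition(
        participant_id=participant_id,
        composition=TissueComposition(*m[:5]),
        scattering=ScatteringParams(m[5], m[6]),
        n_spectra_used=len(fits),
        n_left=sum(1 for _, side in fits if side == "left"),
        n_right=sum(1 for _, side in fits if side == "right"),
    )


# --------------------------------------------------------------------------
# Table-level driver

SPECTRA_COLUMNS = ["participant_id", "side", "cup_size", "offset_mm",
                   "position", "wavelength_nm", "signal", "usable"]

COMPOSITION_COLUMNS = ["participant_id", "water_pct", "lipid_pct", "collagen_pct",
                       "oxyhb_pct", "deoxyhb_pct", "total_hb_pct", "amplitude",
                       "power", "n_spectra_used"]


def spectra_from_frame(df: pd.DataFrame) -> list[MeasuredSpectrum]:
    """Long-format spectra table -> MeasuredSpectrum objects (sorted keys)."""
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra table missing columns: {missing}")
    out = []
    keys = ["participant_id", "side", "cup_size", "offset_mm", "position"]
    for (pid, side, cup, off, pos), g in df.groupby(keys, sort=True):
        g = g.sort_values("wavelength_nm")
        out.append(MeasuredSpectrum(
            participant_id=str(pid), side=str(side), cup_size=str(cup),
            offset_mm=float(off), wavelengths=g["wavelength_nm"].to_numpy(float),
            signals=g["signal"].to_numpy(float),
            usable=g["usable"].to_numpy().astype(bool), position=int(pos)))
    return out


def _spectrum_seed(master_seed: int, key: str) -> int:
    return (int(master_seed) ^ zlib.crc32(key.encode())) % (2**31 - 1)


def run_spectral_pipeline(spectra, *, basis: ChromophoreBasis,
                          bounds: FitBounds | None = None, n_starts: int = 8,
                          seed: int = 0, log_residuals: bool = True
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC -> multi-start fit -> best-fit selection -> per-participant average.

    ``spectra`` is a long-format DataFrame (see SPECTRA_COLUMNS) or a list of
    :class:`MeasuredSpectrum`.  Returns (composition table, exclusion log).
    Per-spectrum optimizer seeds derive from ``seed`` and the spectrum key,
    so results do not depend on table row order.
    """
    if isinstance(spectra, pd.DataFrame):
        spectra = spectra_from_frame(spectra)
    retained, exclusions = qc_filter(spectra)
    accepted: dict[str, list[tuple[FitResult, str]]] = {}
    for s in retained:
        geo = geometry_for_cup(s.cup_size)
        fits = fit_spectrum(s, bounds or FitBounds(), basis, geo,
                            n_starts=n_starts, seed=_spectrum_seed(seed, s.key()),
                            log_residuals=log_residuals)
        best = select_best_fit(fits)
        if best is None:
            exclusions.append({"spectrum_key": s.key(),
                               "participant_id": s.participant_id,
                               "reason": REASON_FIT_FAILED})
            continue
        accepted.setdefault(s.participant_id, []).append((best, s.side))
    rows = []
    for pid in sorted(accepted):
        agg = aggregate_participant(accepted[pid], pid)
        c = agg.composition
        rows.append({
            "participant_id": pid, "water_pct": c.water_pct,
            "lipid_pct": c.lipid_pct, "collagen_pct": c.collagen_pct,
            "oxyhb_pct": c.oxyhb_pct, "deoxyhb_pct": c.deoxyhb_pct,
            "total_hb_pct": c.total_hb_pct,
            "amplitude": agg.scattering.amplitude, "power": agg.scattering.power,
            "n_spectra_used": agg.n_spectra_used,
        })
    comp_df = pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)
    excl_df = pd.DataFrame(exclusions, columns=["spectrum_key", "participant_id",
                                                "reason"])
    return comp_df, excl_df
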