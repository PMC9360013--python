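"""Chromophore specific-absorption basis.

A :class:`ChromophoreBasis` holds, per wavelength, the specific absorption of
the five modeled chromophores (water, lipid, collagen, oxy- and
deoxy-hemoglobin) in mm^-1 per percent tissue-volume concentration.  Tissue
absorption is the linear mix of these curves weighted by concentration.

Two built-in bases are provided:

* :func:`default_basis` — a smooth, densely sampled synthetic basis
  constructed from Gaussian bands placed at the chromophores' known
  near-infrared features (water peak near 975 nm, lipid near 930 nm, the
  deoxy-Hb 760 nm band, the oxy/deoxy crossover near 800 nm, collagen's
  broad 900/1020 nm structure).  It is a constructed stand-in, not a
  published extinction table, but it reproduces the spectral geometry that
  the quality-control rules and the inverse problem rely on.
* :func:`toy_basis` — a coarse well-separated five-Gaussian basis for fast
  unit tests.

User-supplied bases load from plain CSV via :func:`load_basis`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CHROMOPHORES, WAVELENGTH_MAX, WAVELENGTH_MIN

#: CSV column order for the basis-table interchange format.
BASIS_COLUMNS = ["wavelength_nm", "eps_water", "eps_lipid", "eps_collagen",
                 "eps_oxyhb", "eps_deoxyhb"]


@dataclass(frozen=True)
class ChromophoreBasis:
    """Specific-absorption curves on a common wavelength grid.

    ``curves`` has shape (n_wavelengths, 5), columns in the canonical
    chromophore order; units mm^-1 per percent concentration.
    """

    wavelengths: np.ndarray
    curves: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        cv = np.asarray(self.curves, dtype=float)
        if wl.ndim != 1 or wl.size < 3:
            raise ValueError("wavelength grid must be 1-D with >= 3 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if wl[0] > WAVELENGTH_MIN or wl[-1] < WAVELENGTH_MAX:
            raise ValueError(
                f"basis grid must cover [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm, "
                f"got [{wl[0]}, {wl[-1]}]"
            )
        if cv.shape != (wl.size, len(CHROMOPHORES)):
            raise ValueError(f"curves must have shape ({wl.size}, {len(CHROMOPHORES)})")
        if np.any(cv < 0) or not np.all(np.isfinite(cv)):
            raise ValueError("specific absorption must be finite and >= 0")
        _require_local_max(wl, cv[:, 0], 975.0, 985.0, "water")
        _require_local_max(wl, cv[:, 1], 905.0, 930.0, "lipid")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "curves", cv)

    def specific_absorption(self, wavelength) -> np.ndarray:
        """Interpolated curves at ``wavelength`` (scalar or array).

        Returns shape (..., 5); raises for wavelengths outside the grid.
        """
        lam = np.asarray(wavelength, dtype=float)
        if np.any(lam < self.wavelengths[0]) or np.any(lam > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength outside basis range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        out = np.stack(
            [np.interp(lam, self.wavelengths, self.curves[:, j])
             for j in range(len(CHROMOPHORES))],
            axis=-1,
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths})
        for j, c in enumerate(CHROMOPHORES):
            df[f"eps_{c}"] = self.curves[:, j]
        return df


def _require_local_max(wl: np.ndarray, curve: np.ndarray, lo: float, hi: float,
                       label: str) -> None:
    """The QC rules separate the water and lipid peaks; a basis without those
    peaks would make the 985 / 905-940 usability rules meaningless."""
    inner = curve[1:-1]
    left, right = curve[:-2], curve[2:]
    is_max = ((inner >= left) & (inner >= right)
              & ((inner > left) | (inner > right)))
    in_band = (wl[1:-1] >= lo - 15.0) & (wl[1:-1] <= hi + 15.0)
    if not np.any(is_max & in_band):
        raise ValueError(
            f"{label} curve must have a local maximum near {lo}-{hi} nm"
        )


def _gauss(lam: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((lam - center) / width) ** 2)


def default_basis() -> ChromophoreBasis:
    """Synthetic literature-informed basis on a 5 nm grid over 640-1070 nm.

    Peak positions and order-of-magnitude specific absorptions follow the
    well-known near-infrared features of breast-tissue chromophores; the
    exact curve shapes are synthetic (Gaussian bands), so absolute
    attenuations are representative rather than metrologically calibrated.
    Magnitudes are chosen so a typical composition (water ~17%, lipid ~46%,
    collagen ~21%, Hb ~0.6%) gives tissue mu_a of 0.002-0.015 mm^-1 across
    the band, keeping the diffusion approximation valid.
    """
    lam = np.arange(640.0, 1071.0, 5.0)
    water = (
        _gauss(lam, 978.0, 27.0, 4.5e-4)
        + _gauss(lam, 740.0, 28.0, 2.0e-5)
        + _gauss(lam, 840.0, 32.0, 2.5e-5)
        + _gauss(lam, 1070.0, 60.0, 1.2e-4)
        + 2.0e-6
    )
    lipid = (
        _gauss(lam, 928.0, 14.0, 1.25e-4)
        + _gauss(lam, 1040.0, 16.0, 9.0e-5)
        + _gauss(lam, 760.0, 25.0, 6.0e-6)
        + _gauss(lam, 890.0, 25.0, 2.0e-5)
        + 1.0e-6
    )
    collagen = (
        _gauss(lam, 910.0, 45.0, 7.0e-5)
        + _gauss(lam, 1018.0, 28.0, 9.5e-5)
        + _gauss(lam, 700.0, 80.0, 1.2e-5)
        + 5.0e-6
    )
    # Oxy-Hb: shallow minimum near 690, broad rise to ~900, decline beyond.
    oxyhb = (
        1.0e-3 * np.exp(-(lam - 640.0) / 55.0)
        + _gauss(lam, 915.0, 95.0, 2.6e-3)
        + 2.0e-4
    )
    # Deoxy-Hb: steep visible tail, 760 nm band, low beyond 900.
    deoxyhb = (
        8.5e-3 * np.exp(-(lam - 640.0) / 45.0)
        + _gauss(lam, 758.0, 22.0, 2.4e-3)
        + _gauss(lam, 850.0, 70.0, 6.0e-4)
        + 1.0e-4
    )
    curves = np.column_stack([water, lipid, collagen, oxyhb, deoxyhb])
    return ChromophoreBasis(lam, curves, name="default-synthetic")


def toy_basis() -> ChromophoreBasis:
    """Coarse five-Gaussian basis (20 nm grid) with well-separated bands.

    Designed for fast, well-conditioned unit tests of the fitting machinery;
    keeps the water (~980 nm) and lipid (~920 nm) peaks that the QC rules
    reference.
    """
    lam = np.arange(640.0, 1071.0, 20.0)
    curves = np.column_stack([
        _gauss(lam, 980.0, 30.0, 4.0e-4) + 2e-6,
        _gauss(lam, 920.0, 20.0, 1.2e-4) + 2e-6,
        _gauss(lam, 1020.0, 35.0, 1.0e-4) + _gauss(lam, 700.0, 60.0, 2.0e-5) + 2e-6,
        _gauss(lam, 900.0, 90.0, 2.5e-3) + 2e-4,
        _gauss(lam, 760.0, 25.0, 2.5e-3) + 7e-3 * np.exp(-(lam - 640.0) / 50.0) + 1e-4,
    ])
    return ChromophoreBasis(lam, curves, name="toy")


def load_basis(path: str | Path, name: str | None = None) -> ChromophoreBasis:
    """Read a basis table from CSV (columns per :data:`BASIS_COLUMNS`)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in BASIS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"basis table missing columns: {missing}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    curves = df[[f"eps_{c}" for c in CHROMOPHORES]].to_numpy(dtype=float)
    return ChromophoreBasis(wl, curves, name=name or Path(path).stem)


def save_basis(basis: ChromophoreBasis, path: str | Path) -> None:
    basis.to_frame().to_csv(path, index=False)


def get_basis(name: str) -> ChromophoreBasis:
    """Resolve a basis by config name: 'default', 'toy', or a CSV path."""
    if name == "default":
        return default_basis()
    if name == "toy":
        return toy_basis()
    p = Path(name)
    if p.suffix.lower() == ".csv" and p.exists():
        return load_basis(p)
    raise ValueError(f"unknown basis {name!r} (expected 'default', 'toy' or a CSV path)")
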