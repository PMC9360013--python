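"""Core record types shared across the pipeline.

These are plain dataclasses with eager validation: every invariant that the
downstream numerics rely on (non-negative concentrations, the <100% chromophore
sum, positive scattering, the 650-1060 nm band) is checked at construction so
that violations surface at the boundary where the bad value entered, not deep
inside an optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Spectral band of the instrument, nm.
WAVELENGTH_MIN = 650.0
WAVELENGTH_MAX = 1060.0

#: Chromophore order used throughout (concentration vectors, basis columns).
CHROMOPHORES = ("water", "lipid", "collagen", "oxyhb", "deoxyhb")


@dataclass(frozen=True)
class TissueComposition:
    """Chromophore concentrations as percent of tissue volume.

    The five modeled chromophores never sum to 100%: the remainder is
    unmodeled absorbers (e.g. myoglobin), so the sum is constrained
    strictly below 100.
    """

    water_pct: float
    lipid_pct: float
    collagen_pct: float
    oxyhb_pct: float
    deoxyhb_pct: float

    def __post_init__(self) -> None:
        for name in ("water_pct", "lipid_pct", "collagen_pct", "oxyhb_pct", "deoxyhb_pct"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.total() >= 100.0:
            raise ValueError(
                f"chromophore sum must be < 100%, got {self.total():.3f}"
            )

    def total(self) -> float:
        return (
            self.water_pct
            + self.lipid_pct
            + self.collagen_pct
            + self.oxyhb_pct
            + self.deoxyhb_pct
        )

    @property
    def total_hb_pct(self) -> float:
        return self.oxyhb_pct + self.deoxyhb_pct

    def as_array(self) -> np.ndarray:
        """Concentrations in the canonical chromophore order."""
        return np.array(
            [self.water_pct, self.lipid_pct, self.collagen_pct,
             self.oxyhb_pct, self.deoxyhb_pct]
        )


@dataclass(frozen=True)
class ScatteringParams:
    """Reduced-scattering power law: mu_s'(lambda) = amplitude * (lambda/ref)^-power.

    ``amplitude`` is mu_s' at the reference wavelength in mm^-1; ``power`` is
    the dimensionless scattering power (cellularity proxy).
    """

    amplitude: float
    power: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        # power 0 (wavelength-flat scattering) is a valid degenerate case
        if not np.isfinite(self.power) or self.power < 0:
            raise ValueError(f"power must be >= 0, got {self.power}")


@dataclass(frozen=True)
class Geometry:
    """Transmission slab geometry for one breast in one cup.

    The breast is modeled as a homogeneous slab of ``slab_thickness`` mm;
    the source is on one face and six detectors sit on the opposite face at
    the given lateral offsets from the source axis.
    """

    slab_thickness: float
    lateral_offsets: tuple[float, ...]
    cup_size: str = "B"

    def __post_init__(self) -> None:
        if not np.isfinite(self.slab_thickness) or self.slab_thickness <= 0:
            raise ValueError(f"slab_thickness must be > 0, got {self.slab_thickness}")
        offs = tuple(float(o) for o in self.lateral_offsets)
        if len(offs) != 6:
            raise ValueError(f"exactly 6 source-detector offsets required, got {len(offs)}")
        if len(set(offs)) != 6 or any(o < 0 for o in offs):
            raise ValueError("offsets must be 6 distinct values >= 0")
        object.__setattr__(self, "lateral_offsets", offs)


#: Slab thickness (mm) by measurement-cup label.
CUP_THICKNESS_MM = {"A": 45.0, "B": 55.0, "C": 65.0, "D": 75.0}

#: Default source-detector offsets (mm): six, evenly spaced 0-50.
DEFAULT_OFFSETS_MM = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


def geometry_for_cup(cup_size: str) -> Geometry:
    """Default geometry for a cup label in {A, B, C, D}."""
    try:
        thickness = CUP_THICKNESS_MM[cup_size]
    except KeyError:
        raise ValueError(f"unknown cup size {cup_size!r}") from None
    return Geometry(thickness, DEFAULT_OFFSETS_MM, cup_size)


@dataclass
class MeasuredSpectrum:
    """One attenuation spectrum: one breast, one source-detector offset.

    ``readings`` maps wavelength (nm) to detector signal; ``usable`` flags
    wavelengths that survived acquisition (dropout marks them False). Signals
    must be positive wherever usable (they are transmitted intensities).
    """

    participant_id: str
    side: str
    cup_size: str
    offset_mm: float
    wavelengths: np.ndarray
    signals: np.ndarray
    usable: np.ndarray
    position: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (
            self.wavelengths.shape == self.signals.shape == self.usable.shape
        ):
            raise ValueError("wavelengths, signals and usable must have equal shape")
        wl = self.wavelengths
        if wl.size and (wl.min() < WAVELENGTH_MIN or wl.max() > WAVELENGTH_MAX):
            raise ValueError(
                f"wavelengths must lie in [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )
        if np.any(self.signals[self.usable] <= 0):
            raise ValueError("usable signals must be > 0")

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def usable_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.usable]

    def key(self) -> str:
        return f"{self.participant_id}:{self.side}:{self.offset_mm:g}:{self.position}"


@dataclass(frozen=True)
class FitBounds:
    """Box bounds on the fitted parameters plus the joint chromophore-sum cap.

    Water, lipid and collagen bounds are in percent; total hemoglobin
    (oxy + deoxy jointly) in percent; amplitude in mm^-1 at the reference
    wavelength; power dimensionless. ``sum_cap_pct`` bounds
    water + lipid + collagen + total Hb strictly from above.
    """

    water: tuple[float, float] = (4.0, 90.0)
    lipid: tuple[float, float] = (10.0, 95.0)
    collagen: tuple[float, float] = (1.0, 30.0)
    total_hb: tuple[float, float] = (0.2, 1.0)
    amplitude: tuple[float, float] = (0.1, 4.0)
    power: tuple[float, float] = (0.05, 5.0)
    sum_cap_pct: float = 100.0

    def __post_init__(self) -> None:
        for name in ("water", "lipid", "collagen", "total_hb", "amplitude", "power"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound {lo} must be < upper {hi}")
        if self.sum_cap_pct <= 0:
            raise ValueError("sum_cap_pct must be > 0")

    def contains(self, composition: TissueComposition, scattering: ScatteringParams,
                 tol: float = 1e-9) -> bool:
        checks = [
            (composition.water_pct, self.water),
            (composition.lipid_pct, self.lipid),
            (composition.collagen_pct, self.collagen),
            (composition.total_hb_pct, self.total_hb),
            (scattering.amplitude, self.amplitude),
            (scattering.power, self.power),
        ]
        if any(v < lo - tol or v > hi + tol for v, (lo, hi) in checks):
            return False
        chrom_sum = (composition.water_pct + composition.lipid_pct
                     + composition.collagen_pct + composition.total_hb_pct)
        return chrom_sum < self.sum_cap_pct + tol


@dataclass
class FitResult:
    """Outcome of one optimizer start for one spectrum."""

    composition: TissueComposition
    scattering: ScatteringParams
    sse: float
    n_at_bounds: int
    start_index: int
    converged: bool

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")
        if not 0 <= self.n_at_bounds <= 7:
            raise ValueError("n_at_bounds must be in 0..7")


@dataclass
class ParticipantComposition:
    """Per-participant unweighted average over all accepted spectrum fits."""

    participant_id: str
    composition: TissueComposition
    scattering: ScatteringParams
    n_spectra_used: int
    n_left: int = 0
    n_right: int = 0

    def __post_init__(self) -> None:
        if self.n_spectra_used < 1:
            raise ValueError("n_spectra_used must be >= 1")


@dataclass
class StatResult:
    """One statistical comparison: estimate, test statistic, df, two-sided p, n."""

    estimate: float
    statistic: float
    df: float
    p_two_sided: float
    n: int
    kind: str = ""

    def __post_init__(self) -> None:
        if self.kind in ("pearson", "partial") and np.isfinite(self.estimate):
            if abs(self.estimate) > 1 + 1e-12:
                raise ValueError(f"|r| must be <= 1, got {self.estimate}")
        if np.isfinite(self.p_two_sided) and not 0 <= self.p_two_sided <= 1:
            raise ValueError(f"p must be in [0, 1], got {self.p_two_sided}")
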