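"""Synthetic paired mother-daughter cohort with known ground truth.

The generator emulates the measurement study end to end so every pipeline
stage can be tested against a known truth:

* **Composition.**  Each participant's percent breast density index (the
  density estimand, %BDI) is drawn from a group-anchored normal model with
  linear age and BMI confounding; the chromophore composition is then
  constructed so that its %BDI equals that draw exactly: lipid takes the
  non-dense share and water/collagen split the dense share.  Group anchors
  (means/SDs of density, composition, scattering, age, BMI) default to the
  observed daughter (n=42) / mother (n=39) cohort summaries.
* **Familial resemblance.**  A latent density factor is shared within each
  pair with a correlation calibrated so the *marginal* mother-daughter
  correlation of true density equals the configured value.
* **Spectra.**  Up to 12 transmission spectra per breast (6 source-detector
  offsets x positions) from the shared forward model, with independent
  per-wavelength Bernoulli dropout and multiplicative log-normal noise.
* **Imaging.**  %FGV (both groups) and %MBD (mothers only) are affine in
  true density plus Gaussian noise, with per-side jitter giving a
  configurable left-right correlation; absolute volumes come from log-normal
  breast volumes.

Everything is driven by one ``numpy.random.Generator``, so a fixed master
seed reproduces the cohort bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .basis import ChromophoreBasis
from .forward_model import DEFAULT_WAVELENGTHS_NM, simulate_spectrum
from .records import (Geometry, MeasuredSpectrum, ScatteringParams,
                      TissueComposition, geometry_for_cup)

GROUPS = ("daughter", "mother")


def _tnorm(rng: np.random.Generator, mean: float, sd: float,
           lo: float, hi: float) -> float:
    """One truncated-normal draw by inverse-CDF (cheap and deterministic)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    return float(mean + sd * ndtri(rng.uniform(a, b)))


@lru_cache(maxsize=256)
def _tnorm_moments(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """(mean, variance) of the truncated normal, for calibration."""
    if sd == 0:
        return float(np.clip(mean, lo, hi)), 0.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    d = stats.truncnorm(a, b, loc=mean, scale=sd)
    return float(d.mean()), float(d.var())


@dataclass(frozen=True)
class GroupParams:
    """Distributional anchors for one group (daughters or mothers).

    Density (%BDI) and composition anchors are means (SDs) on the percent
    scale; ``age_slope``/``bmi_slope`` are the within-group linear
    confounding of true density on age (per year) and BMI (per kg/m^2),
    absorbed into the density SD so the marginal SD stays at ``bdi_sd``.
    """

    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    bmi_mean: float
    bmi_sd: float
    bmi_range: tuple[float, float]
    bdi_mean: float
    bdi_sd: float
    age_slope: float
    bmi_slope: float
    # water + lipid + collagen total and the water share of collagen+water
    sum_chrom_mean: float
    sum_chrom_sd: float
    water_share_mean: float
    water_share_sd: float
    thb_mean: float
    thb_sd: float
    oxy_frac_mean: float = 0.70
    oxy_frac_sd: float = 0.08
    amplitude_mean: float = 1.7
    amplitude_sd: float = 0.5
    power_mean: float = 1.3
    power_sd: float = 0.5
    # imaging links: measure = intercept + slope * density + N(0, noise_sd)
    volume_mean_cm3: float = 500.0
    volume_log_sd: float = 0.25
    fgv_slope: float = 1.0
    fgv_intercept: float = 0.0
    fgv_noise_sd: float = 10.0
    mbd_slope: float = 0.0
    mbd_intercept: float = 0.0
    mbd_noise_sd: float = 0.0
    has_mammography: bool = False

    def density_residual_sd(self) -> float:
        """SD of density left after age/BMI confounding (keeps marginal SD at bdi_sd)."""
        _, va = _tnorm_moments(self.age_mean, self.age_sd, *self.age_range)
        _, vb = _tnorm_moments(self.bmi_mean, self.bmi_sd, *self.bmi_range)
        explained = self.age_slope**2 * va + self.bmi_slope**2 * vb
        resid_var = self.bdi_sd**2 - explained
        if resid_var <= 0:
            raise ValueError("age/BMI slopes explain more variance than bdi_sd allows")
        return math.sqrt(resid_var)


def _daughter_defaults() -> GroupParams:
    return GroupParams(
        age_mean=15.1, age_sd=0.6, age_range=(14.0, 16.3),
        bmi_mean=24.2, bmi_sd=5.1, bmi_range=(15.0, 45.0),
        bdi_mean=46.0, bdi_sd=9.8, age_slope=0.0, bmi_slope=-0.8,
        sum_chrom_mean=84.5, sum_chrom_sd=3.0,
        water_share_mean=0.447, water_share_sd=0.04,
        thb_mean=0.61, thb_sd=0.16,
        amplitude_mean=1.7, amplitude_sd=0.5, power_mean=1.3, power_sd=0.5,
        volume_mean_cm3=485.0, volume_log_sd=0.25,
        fgv_slope=1.2, fgv_intercept=45.2 - 1.2 * 46.0, fgv_noise_sd=9.95,
        has_mammography=False,
    )


def _mother_defaults() -> GroupParams:
    return GroupParams(
        age_mean=47.5, age_sd=7.1, age_range=(36.9, 61.2),
        bmi_mean=30.7, bmi_sd=6.3, bmi_range=(17.0, 55.0),
        bdi_mean=38.9, bdi_sd=9.1, age_slope=-0.3, bmi_slope=-0.8,
        sum_chrom_mean=85.6, sum_chrom_sd=3.0,
        water_share_mean=0.458, water_share_sd=0.04,
        thb_mean=0.58, thb_sd=0.15,
        amplitude_mean=1.6, amplitude_sd=0.5, power_mean=1.4, power_sd=0.8,
        volume_mean_cm3=777.0, volume_log_sd=0.25,
        fgv_slope=0.9, fgv_intercept=31.6 - 0.9 * 38.9, fgv_noise_sd=5.56,
        mbd_slope=0.35, mbd_intercept=7.3 - 0.35 * 38.9, mbd_noise_sd=2.58,
        has_mammography=True,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_pairs: int = 42
    daughters: GroupParams = field(default_factory=_daughter_defaults)
    mothers: GroupParams = field(default_factory=_mother_defaults)
    #: marginal mother-daughter correlation of true density
    pair_correlation: float = 0.32
    #: left-right correlation of per-side imaging measures
    lr_correlation: float = 0.95
    #: multiplicative spectral noise SD on the log scale (~CV)
    noise_sd: float = 0.01
    #: independent per-wavelength dropout probability
    dropout_prob: float = 0.3
    n_positions: int = 2
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if not -1.0 <= self.pair_correlation <= 1.0:
            raise ValueError("pair_correlation must be in [-1, 1]")
        if not 0.0 <= self.lr_correlation <= 1.0:
            raise ValueError("lr_correlation must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.n_positions <= 2:
            raise ValueError("n_positions must be 1 or 2 (<= 12 spectra per breast)")

    def group(self, name: str) -> GroupParams:
        if name == "daughter":
            return self.daughters
        if name == "mother":
            return self.mothers
        raise ValueError(f"unknown group {name!r} (expected 'daughter' or 'mother')")

    def latent_pair_correlation(self) -> float:
        """Latent-factor correlation giving the configured marginal density correlation."""
        rd = self.daughters.density_residual_sd()
        rm = self.mothers.density_residual_sd()
        rho = (self.pair_correlation
               * (self.daughters.bdi_sd * self.mothers.bdi_sd) / (rd * rm))
        if abs(rho) > 1:
            raise ValueError(
                "pair_correlation unattainable given age/BMI confounding strength")
        return rho

    def with_conditional_fgv_correlation(self, rho: float) -> "CohortConfig":
        """Re-derive each group's %FGV noise SD so that the correlation of
        %FGV with true density *given age and BMI* equals ``rho``.

        rho = 0 switches the link slope off (conditional independence).
        """
        if not 0.0 <= rho < 1.0:
            raise ValueError("conditional correlation must be in [0, 1)")
        groups = {}
        for key in ("daughters", "mothers"):
            g: GroupParams = getattr(self, key)
            if rho == 0.0:
                # keep the group's mean %FGV where the link would have put it
                groups[key] = replace(
                    g, fgv_slope=0.0,
                    fgv_intercept=g.fgv_intercept + g.fgv_slope * g.bdi_mean)
                continue
            signal_var = (g.fgv_slope * g.density_residual_sd()) ** 2
            # the side-jitter SD depends on the noise SD being solved for;
            # iterate the fixed point (contractive, converges in a few steps)
            noise_sd = g.fgv_noise_sd
            for _ in range(100):
                jitter = _side_jitter_sd(abs(g.fgv_slope) * g.bdi_sd + noise_sd,
                                         self.lr_correlation)
                noise_var = signal_var * (1.0 / rho**2 - 1.0) - jitter**2 / 2.0
                if noise_var < 0:
                    raise ValueError("requested conditional correlation too high "
                                     "for the configured left-right jitter")
                new_sd = math.sqrt(noise_var)
                if abs(new_sd - noise_sd) < 1e-12:
                    break
                noise_sd = new_sd
            groups[key] = replace(g, fgv_noise_sd=noise_sd)
        return replace(self, daughters=groups["daughters"], mothers=groups["mothers"])


def _side_jitter_sd(scale_sd: float, lr_corr: float) -> float:
    """Per-side jitter SD giving left-right correlation ``lr_corr`` when the
    person-level component has SD ``scale_sd``."""
    if lr_corr >= 1.0:
        return 0.0
    return scale_sd * math.sqrt(1.0 / lr_corr - 1.0)


@dataclass
class ParticipantTruth:
    """Ground truth for one synthetic participant."""

    participant_id: str
    pair_id: str
    group: str
    age: float
    bmi: float
    composition: TissueComposition
    scattering: ScatteringParams
    breast_volume_left_cm3: float
    breast_volume_right_cm3: float
    true_percent_density: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.breast_volume_left_cm3 <= 0 or self.breast_volume_right_cm3 <= 0:
            raise ValueError("breast volumes must be > 0")

    def cup_size(self) -> str:
        """Measurement cup from mean breast volume (larger breast, thicker slab)."""
        v = 0.5 * (self.breast_volume_left_cm3 + self.breast_volume_right_cm3)
        for label, cut in (("A", 350.0), ("B", 550.0), ("C", 800.0)):
            if v < cut:
                return label
        return "D"


def sample_participant(group: str, config: CohortConfig, rng: np.random.Generator,
                       *, pair_id: str = "P0001", latent: float | None = None
                       ) -> ParticipantTruth:
    """Draw one participant's ground truth.

    ``latent`` is the standard-normal density factor (shared within a pair by
    :func:`generate_paired_cohort`); drawn fresh when omitted.
    """
    g = config.group(group)
    if latent is None:
        latent = float(rng.standard_normal())
    age = _tnorm(rng, g.age_mean, g.age_sd, *g.age_range)
    bmi = _tnorm(rng, g.bmi_mean, g.bmi_sd, *g.bmi_range)
    age_c, _ = _tnorm_moments(g.age_mean, g.age_sd, *g.age_range)
    bmi_c, _ = _tnorm_moments(g.bmi_mean, g.bmi_sd, *g.bmi_range)
    density = (g.bdi_mean
               + g.age_slope * (age - age_c)
               + g.bmi_slope * (bmi - bmi_c)
               + g.density_residual_sd() * latent)
    density = float(np.clip(density, 2.0, 98.0))

    total_wlc = _tnorm(rng, g.sum_chrom_mean, g.sum_chrom_sd, 40.0, 97.0)
    water_share = _tnorm(rng, g.water_share_mean, g.water_share_sd, 0.10, 0.90)
    dense = density / 100.0 * total_wlc
    lipid = total_wlc - dense
    water = water_share * dense
    collagen = dense - water
    thb = _tnorm(rng, g.thb_mean, g.thb_sd, 0.2, 1.0)
    oxy_frac = _tnorm(rng, g.oxy_frac_mean, g.oxy_frac_sd, 0.30, 0.95)
    comp = TissueComposition(water, lipid, collagen, oxy_frac * thb,
                             (1.0 - oxy_frac) * thb)
    scat = ScatteringParams(
        _tnorm(rng, g.amplitude_mean, g.amplitude_sd, 0.3, 3.8),
        _tnorm(rng, g.power_mean, g.power_sd, 0.1, 4.5),
    )
    vol_person = g.volume_mean_cm3 * math.exp(
        g.volume_log_sd * rng.standard_normal() - 0.5 * g.volume_log_sd**2)
    vol_l = vol_person * math.exp(0.03 * rng.standard_normal())
    vol_r = vol_person * math.exp(0.03 * rng.standard_normal())
    suffix = {"daughter": "D", "mother": "M"}[group]
    return ParticipantTruth(
        participant_id=f"{pair_id}{suffix}", pair_id=pair_id, group=group,
        age=age, bmi=bmi, composition=comp, scattering=scat,
        breast_volume_left_cm3=vol_l, breast_volume_right_cm3=vol_r,
        true_percent_density=density,
    )


def sample_interior_truth(rng: np.random.Generator
                          ) -> tuple[TissueComposition, ScatteringParams]:
    """Uniform draw comfortably inside the physiological fit ranges.

    Used for parameter-recovery exercises: truths keep a margin from every
    bound (and from the 100% sum cap), so a correct fit has no reason to
    touch a constraint.
    """
    while True:
        water = rng.uniform(10.0, 35.0)
        lipid = rng.uniform(25.0, 60.0)
        collagen = rng.uniform(5.0, 25.0)
        if water + lipid + collagen <= 92.0:
            break
    thb = rng.uniform(0.3, 0.9)
    oxy_frac = rng.uniform(0.35, 0.85)
    comp = TissueComposition(water, lipid, collagen, oxy_frac * thb,
                             (1.0 - oxy_frac) * thb)
    scat = ScatteringParams(rng.uniform(0.8, 3.0), rng.uniform(0.4, 3.0))
    return comp, scat


def generate_paired_cohort(config: CohortConfig, rng: np.random.Generator
                           ) -> list[tuple[ParticipantTruth, ParticipantTruth]]:
    """Draw ``n_pairs`` daughter-mother pairs with correlated true density."""
    rho = config.latent_pair_correlation()
    pairs = []
    for i in range(config.n_pairs):
        zd = float(rng.standard_normal())
        zm = rho * zd + math.sqrt(max(1.0 - rho * rho, 0.0)) * float(rng.standard_normal())
        pid = f"P{i + 1:04d}"
        daughter = sample_participant("daughter", config, rng, pair_id=pid, latent=zd)
        mother = sample_participant("mother", config, rng, pair_id=pid, latent=zm)
        pairs.append((daughter, mother))
    return pairs


def measure_spectra(truth: ParticipantTruth, config: CohortConfig,
                    rng: np.random.Generator, basis: ChromophoreBasis,
                    geometry: Geometry | None = None) -> list[MeasuredSpectrum]:
    """Noisy transmission spectra for both breasts of one participant.

    Per breast: one spectrum per (offset, position), at most 12.  Each
    wavelength is independently unusable with probability ``dropout_prob``;
    usable signals get multiplicative log-normal noise exp(noise_sd * Z).
    """
    geo = geometry or geometry_for_cup(truth.cup_size())
    lam = np.asarray(config.wavelengths, dtype=float)
    out: list[MeasuredSpectrum] = []
    for side in ("left", "right"):
        for offset in geo.lateral_offsets:
            for pos in range(config.n_positions):
                clean = simulate_spectrum(
                    truth.composition, truth.scattering, geo, offset,
                    wavelengths=lam, basis=basis,
                    participant_id=truth.participant_id, side=side, position=pos)
                usable = rng.uniform(size=lam.size) >= config.dropout_prob
                signals = clean.signals.copy()
                if config.noise_sd > 0:
                    signals = signals * np.exp(
                        config.noise_sd * rng.standard_normal(lam.size))
                signals[~usable] = np.nan
                out.append(MeasuredSpectrum(
                    participant_id=truth.participant_id, side=side,
                    cup_size=geo.cup_size, offset_mm=float(offset),
                    wavelengths=lam, signals=signals, usable=usable, position=pos))
    return out


def generate_imaging_measures(truth: ParticipantTruth, config: CohortConfig,
                              rng: np.random.Generator) -> dict[str, float]:
    """Per-breast DXA volumes (and mammographic dense volumes for mothers).

    Percent measures are affine in true density with Gaussian noise; the two
    sides share the person-level value plus jitter sized to the configured
    left-right correlation.  Dense/fibroglandular volumes are the percent
    measure applied to the side's total volume, so they never exceed it.
    """
    g = config.group(truth.group)
    d = truth.true_percent_density
    out: dict[str, float] = {
        "participant_id": truth.participant_id,
        "vol_left_cm3": truth.breast_volume_left_cm3,
        "vol_right_cm3": truth.breast_volume_right_cm3,
    }

    def two_sides(person_value: float, scale_sd: float, lo: float, hi: float):
        jit = _side_jitter_sd(scale_sd, config.lr_correlation)
        left = person_value + jit * rng.standard_normal()
        right = person_value + jit * rng.standard_normal()
        return float(np.clip(left, lo, hi)), float(np.clip(right, lo, hi))

    fgv_scale = abs(g.fgv_slope) * g.bdi_sd + g.fgv_noise_sd
    fgv_person = (g.fgv_intercept + g.fgv_slope * d
                  + g.fgv_noise_sd * rng.standard_normal())
    pl, pr = two_sides(fgv_person, fgv_scale, 1.0, 99.0)
    out["fgv_left_cm3"] = pl / 100.0 * out["vol_left_cm3"]
    out["fgv_right_cm3"] = pr / 100.0 * out["vol_right_cm3"]

    if g.has_mammography:
        mbd_scale = abs(g.mbd_slope) * g.bdi_sd + g.mbd_noise_sd
        mbd_person = (g.mbd_intercept + g.mbd_slope * d
                      + g.mbd_noise_sd * rng.standard_normal())
        ml, mr = two_sides(mbd_person, mbd_scale, 0.2, 60.0)
        out["dense_left_cm3"] = ml / 100.0 * out["vol_left_cm3"]
        out["dense_right_cm3"] = mr / 100.0 * out["vol_right_cm3"]
    else:
        out["dense_left_cm3"] = float("nan")
        out["dense_right_cm3"] = float("nan")
    return out


@dataclass
class CohortData:
    """A fully simulated cohort: truths plus everything the pipeline consumes."""

    truths: list[ParticipantTruth]
    spectra: list[MeasuredSpectrum]
    volumetrics: pd.DataFrame
    covariates: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            c = t.composition
            rows.append({
                "participant_id": t.participant_id, "pair_id": t.pair_id,
                "group": t.group, "age": t.age, "bmi": t.bmi,
                "water_pct": c.water_pct, "lipid_pct": c.lipid_pct,
                "collagen_pct": c.collagen_pct, "oxyhb_pct": c.oxyhb_pct,
                "deoxyhb_pct": c.deoxyhb_pct, "total_hb_pct": c.total_hb_pct,
                "amplitude": t.scattering.amplitude, "power": t.scattering.power,
                "true_percent_density": t.true_percent_density,
                "vol_left_cm3": t.breast_volume_left_cm3,
                "vol_right_cm3": t.breast_volume_right_cm3,
            })
        return pd.DataFrame(rows)

    def spectra_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.spectra:
            for lam, sig, ok in zip(s.wavelengths, s.signals, s.usable):
                rows.append((s.participant_id, s.side, s.cup_size, s.offset_mm,
                             s.position, lam, sig, int(ok)))
        return pd.DataFrame(rows, columns=[
            "participant_id", "side", "cup_size", "offset_mm", "position",
            "wavelength_nm", "signal", "usable"])


def simulate_cohort(config: CohortConfig, seed: int, basis: ChromophoreBasis,
                    *, with_spectra: bool = True) -> CohortData:
    """Generate a complete cohort from one master seed (bit-reproducible)."""
    rng = np.random.default_rng(seed)
    pairs = generate_paired_cohort(config, rng)
    truths = [p for pair in pairs for p in pair]
    spectra: list[MeasuredSpectrum] = []
    if with_spectra:
        for t in truths:
            spectra.extend(measure_spectra(t, config, rng, basis))
    volumetrics = pd.DataFrame([generate_imaging_measures(t, config, rng)
                                for t in truths])
    covariates = pd.DataFrame([
        {"participant_id": t.participant_id, "pair_id": t.pair_id,
         "group": t.group, "age": t.age, "bmi": t.bmi}
        for t in truths])
    return CohortData(truths, spectra, volumetrics, covariates)
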