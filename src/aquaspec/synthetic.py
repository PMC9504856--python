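"""Synthetic NIR spectra of polymer-water mixtures.

The generator builds absorbance spectra as a sum of Gaussian (optionally
Lorentzian) bands:

* polymer bands at the characteristic C-H/O-H/N-H overtone and combination
  positions of each matrix, with their intensity weakly coupled to water
  content (factor ``1 + kappa * w``);
* two water bands — the ~6900 cm^-1 "overtone" (nu_s + nu_as) and the
  ~5200 cm^-1 combination (nu_as + delta) — whose center shifts linearly
  with water mass fraction between per-polymer endpoints measured at 1 %
  and 10 % w/w, with amplitude ``residual + a * w**gamma`` per band and a
  broad red shoulder standing for self-associated, bulk-like water domains
  in hydrophobic matrices;
* a per-preparation constant baseline offset and i.i.d. additive noise.

Per-band response exponents ``gamma`` (default 1, i.e. strictly linear)
let the two water bands respond at different rates to the water content,
which is what creates lead/lag structure in asynchronous 2D correlation
maps.  All band amplitudes and widths are implementer-chosen, documented
model parameters — not measured values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .core import SampleMeta, SpectraError, SpectraSet, Spectrum, \
    WavenumberGrid, DESIGN_WATER_FRACTIONS

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class BandSpec:
    """One spectral band: center and FWHM in cm^-1, peak amplitude in AU."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise SpectraError("band fwhm must be positive")
        if self.amplitude < 0:
            raise SpectraError("band amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise SpectraError(f"unknown band shape {self.shape!r}")


@dataclass(frozen=True)
class WaterResponse:
    """How the two water bands of one matrix respond to water content.

    Band centers move linearly in w between the ``lo`` (w = 1 %) and ``hi``
    (w = 10 %) endpoints, clipped outside that range.  Amplitudes follow
    ``residual_amplitude + amplitude_per_w * w**exponent``; the residual
    term is trace bound water present at nominal dryness.  A shoulder at
    ``center - shoulder_offset`` with weight ``shoulder_weight`` (fraction
    of the water-driven amplitude) models bulk-like water domains.
    """

    overtone_center_lo: float
    overtone_center_hi: float
    combination_center_lo: float
    combination_center_hi: float
    overtone_fwhm: float = 300.0
    combination_fwhm: float = 230.0
    overtone_amplitude_per_w: float = 5.5
    combination_amplitude_per_w: float = 7.5
    residual_amplitude: float = 0.0
    shoulder_offset: float = 380.0
    shoulder_weight: float = 0.0
    overtone_exponent: float = 1.0
    combination_exponent: float = 1.0

    def __post_init__(self) -> None:
        for c in (self.overtone_center_lo, self.overtone_center_hi):
            if not 6500.0 <= c <= 7300.0:
                raise SpectraError(f"overtone center {c} outside 6500-7300")
        for c in (self.combination_center_lo, self.combination_center_hi):
            if not 5000.0 <= c <= 5400.0:
                raise SpectraError(f"combination center {c} outside 5000-5400")
        if self.shoulder_weight < 0 or self.residual_amplitude < 0:
            raise SpectraError("weights must be non-negative")


@dataclass(frozen=True)
class PolymerProfile:
    """Band model and water response of one polymer matrix."""

    name: str
    hydrophilicity_rank: int
    bands: tuple[BandSpec, ...]
    water: WaterResponse
    coupling: float = 0.0  # relative polymer-band intensity change per unit w


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections: per-preparation constant baseline offset
    (sd in AU) and i.i.d. additive noise per grid point."""

    baseline_sd: float = 0.01
    additive_sd: float = 3e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.additive_sd < 0:
            raise SpectraError("noise sds must be non-negative")


NOISE_FREE = NoiseModel(0.0, 0.0)


def band_values(grid: WavenumberGrid, band: BandSpec) -> np.ndarray:
    """Evaluate one band on the grid; peak value equals ``amplitude``."""
    x = grid.values - band.center
    if band.shape == "gaussian":
        sigma = band.fwhm * _FWHM_TO_SIGMA
        return band.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
    hwhm = band.fwhm / 2.0
    return band.amplitude * hwhm ** 2 / (x ** 2 + hwhm ** 2)


def _interp_center(lo: float, hi: float, w: float) -> float:
    t = np.clip((w - 0.01) / (0.10 - 0.01), 0.0, 1.0)
    return lo + t * (hi - lo)


def water_component(grid: WavenumberGrid, profile: PolymerProfile,
                    w: float) -> np.ndarray:
    """Noise-free water contribution (both bands + shoulders) at fraction w."""
    if not 0.0 <= w <= 0.15:
        raise SpectraError(f"water fraction {w} outside [0, 0.15]")
    wr = profile.water
    out = np.zeros(len(grid))
    for lo, hi, fwhm, a, gamma in (
        (wr.overtone_center_lo, wr.overtone_center_hi, wr.overtone_fwhm,
         wr.overtone_amplitude_per_w, wr.overtone_exponent),
        (wr.combination_center_lo, wr.combination_center_hi,
         wr.combination_fwhm, wr.combination_amplitude_per_w,
         wr.combination_exponent),
    ):
        center = _interp_center(lo, hi, w)
        driven = a * w ** gamma if w > 0 else 0.0
        amp = wr.residual_amplitude + driven
        if amp > 0:
            out += band_values(grid, BandSpec(center, fwhm, amp))
        sh_amp = wr.shoulder_weight * driven
        if sh_amp > 0:
            out += band_values(
                grid, BandSpec(center - wr.shoulder_offset, fwhm, sh_amp))
    return out


def polymer_component(grid: WavenumberGrid, profile: PolymerProfile,
                      w: float = 0.0) -> np.ndarray:
    """Polymer bands scaled by the water-coupling factor (1 + kappa * w)."""
    out = np.zeros(len(grid))
    for band in profile.bands:
        out += band_values(grid, band)
    return out * (1.0 + profile.coupling * w)


def synthesize_sample(profile: PolymerProfile, w: float,
                      noise: NoiseModel = NOISE_FREE,
                      seed: int | None = None,
                      grid: WavenumberGrid | None = None,
                      preparation: int = 1, measurement: int = 1,
                      baseline: float | None = None) -> Spectrum:
    """One synthetic absorbance spectrum; identical seed => identical output.

    ``baseline`` overrides the random baseline draw (used to share one
    baseline across the repeated measurements of a preparation).
    """
    grid = grid or WavenumberGrid.default()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    y = polymer_component(grid, profile, w) + water_component(grid, profile, w)
    if baseline is None:
        baseline = rng.normal(0.0, noise.baseline_sd) if noise.baseline_sd \
            else 0.0
    y = y + baseline
    if noise.additive_sd:
        y = y + rng.normal(0.0, noise.additive_sd, size=len(grid))
    meta = SampleMeta(polymer=profile.name, water_fraction=w,
                      preparation=preparation, measurement=measurement)
    return Spectrum(grid, y, meta=meta)


def synthesize_dataset(profiles: list[PolymerProfile],
                       concentrations=DESIGN_WATER_FRACTIONS,
                       n_prep: int = 6, n_meas: int = 3,
                       noise: NoiseModel = NoiseModel(),
                       seed: int = 0,
                       grid: WavenumberGrid | None = None) -> SpectraSet:
    """Full factorial design: profiles x concentrations x n_prep x n_meas.

    The baseline offset is drawn once per preparation and shared by its
    repeated measurements; all randomness derives deterministically from
    the master seed.
    """
    if not profiles:
        raise SpectraError("empty profile list")
    grid = grid or WavenumberGrid.default()
    spectra = []
    for pi, profile in enumerate(profiles):
        for ci, w in enumerate(concentrations):
            for prep in range(1, n_prep + 1):
                ss = np.random.SeedSequence(entropy=seed,
                                            spawn_key=(pi, ci, prep))
                rng = np.random.default_rng(ss)
                baseline = (rng.normal(0.0, noise.baseline_sd)
                            if noise.baseline_sd else 0.0)
                clean = (polymer_component(grid, profile, w)
                         + water_component(grid, profile, w) + baseline)
                for meas in range(1, n_meas + 1):
                    y = clean
                    if noise.additive_sd:
                        y = y + rng.normal(0.0, noise.additive_sd,
                                           size=len(grid))
                    spectra.append(Spectrum(
                        grid, y,
                        meta=SampleMeta(profile.name, float(w), prep, meas)))
    return SpectraSet.from_spectra(spectra)


def shift_free(profile: PolymerProfile) -> PolymerProfile:
    """Copy of a profile with both water-band centers frozen at their
    midpoints — makes the mixture model exactly bilinear when the residual
    amplitude is zero (useful for curve-resolution benchmarks)."""
    wr = profile.water
    o = 0.5 * (wr.overtone_center_lo + wr.overtone_center_hi)
    c = 0.5 * (wr.combination_center_lo + wr.combination_center_hi)
    return replace(profile, water=replace(
        wr, overtone_center_lo=o, overtone_center_hi=o,
        combination_center_lo=c, combination_center_hi=c))


def bulk_water_profile(grid: WavenumberGrid | None = None) -> PolymerProfile:
    """Pseudo-profile for pure liquid water (bulk band positions, no
    polymer bands); its w = 0.10 spectrum serves as the pure-water
    reference in difference spectroscopy and curve resolution."""
    return PolymerProfile(
        name="water", hydrophilicity_rank=0, bands=(),
        water=WaterResponse(6900.0, 6900.0, 5180.0, 5180.0,
                            overtone_fwhm=320.0, combination_fwhm=240.0,
                            overtone_amplitude_per_w=5.5,
                            combination_amplitude_per_w=7.5),
        coupling=0.0)


def load_profile_library() -> dict[str, PolymerProfile]:
    """Bundled per-polymer parameter library, ordered by hydrophilicity."""
    text = (importlib.resources.files("aquaspec") / "data" /
            "profiles.yaml").read_text()
    raw = yaml.safe_load(text)
    lib: dict[str, PolymerProfile] = {}
    for name, p in raw["profiles"].items():
        bands = tuple(BandSpec(*b) for b in p["bands"])
        lib[name] = PolymerProfile(
            name=name, hydrophilicity_rank=int(p["rank"]),
            bands=bands, water=WaterResponse(**p["water"]),
            coupling=float(p.get("coupling", 0.0)))
    ranks = [p.hydrophilicity_rank for p in lib.values()]
    if len(set(ranks)) != len(ranks):
        raise SpectraError("duplicate hydrophilicity ranks in library")
    return dict(sorted(lib.items(),
                       key=lambda kv: kv[1].hydrophilicity_rank))
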