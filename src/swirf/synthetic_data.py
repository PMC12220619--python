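"""Synthetic SWIR cohort studies with controllable age structure.

The generator is a stand-in for field spectra: no published spectral model
of mosquito cuticle aging exists at this band, so cohorts are simulated
from the simplest mechanism that reproduces the qualitative behaviour the
outlier-fraction statistic relies on.

Model for one scan of a specimen of age ``a`` (days):

    spectrum(lambda) = scale * [ baseline(lambda)
                                 + amplitude(a) * drift(lambda)
                                 + water peaks (1210, 1450 nm)
                                 + N(0, noise_sd) per point ] + offset

* ``baseline`` is a smooth sloping curve; the water O-H bands are Gaussians
  at 1210 and 1450 nm.
* ``drift`` is one fixed unit-norm shape whose contribution grows with age
  through the saturating amplitude ``A_max * (1 - exp(-a / tau_age))``:
  spectra change quickly over the first days of adult life and flatten out
  in old age.  A cohort mixing ages therefore spreads out spectrally, and
  the spread survives SNV because the drift shape differs from the
  baseline shape.
* ``scale``/``offset`` are per-scan multiplicative/additive scatter, drawn
  uniformly from configurable ranges — exactly the nuisance SNV removes.
  Detector noise is added after the scatter (it arises in the instrument,
  not the specimen).  Noise is generated in the transmitted-intensity
  domain and propagated through the log to absorbance:
  ``A' = A - log10(1 + eps)`` with ``eps ~ N(0, ln(10) * noise_sd)``, which
  for small ``noise_sd`` is Gaussian absorbance noise of that standard
  deviation but develops the right-skewed heavy upper tail of real
  absorbance measurements as the noise level rises.

Each specimen is scanned ``scans_per_specimen`` times (default 2, matching
the study's duplicate scans); replicates share the specimen's age but get
independent scatter and noise.

A treatment study draws a PRE population from an age mixture, applies an
age-class-dependent kill (old mosquitoes die at ``kill_old``, young at
``kill_young``), adds a recruit pulse of newly emerged adults, and samples
the POST d1 and POST d2 cohorts from the surviving+recruited pool aged by
one and two days.  With a strong kill of old individuals and a young
recruit pulse the post cohorts are more age-heterogeneous, so the pipeline
recovers a higher post-treatment f.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .spectra_io import DEFAULT_GRID, CollectionDay, ScanSpectrum, WavelengthGrid

__all__ = [
    "AgeComponent",
    "SimulationConfig",
    "YOUNG_MIXED_AGES",
    "OLD_HOMOGENEOUS_AGES",
    "simulate_cohort",
    "simulate_treatment_study",
    "simulate_standard_trials",
]


@dataclass(frozen=True)
class AgeComponent:
    """One component of an age mixture: weight, mean age and SD in days."""

    weight: float
    mean_days: float
    sd_days: float

    def __post_init__(self) -> None:
        if self.weight < 0 or self.sd_days < 0 or self.mean_days < 0:
            raise ValueError("age component parameters must be non-negative")


#: Heterogeneous "young" cohort: mostly newly emerged adults with an older
#: minority — the age structure expected shortly after an effective
#: adulticide treatment.
YOUNG_MIXED_AGES = (
    AgeComponent(0.9, 2.0, 0.5),
    AgeComponent(0.1, 12.0, 1.5),
)

#: Homogeneous old cohort: a settled population of similar, mature ages.
OLD_HOMOGENEOUS_AGES = (AgeComponent(1.0, 15.0, 1.5),)

#: Settled pre-treatment population: mature, moderately spread ages.
SETTLED_AGES = (AgeComponent(1.0, 12.0, 3.0),)


@dataclass
class SimulationConfig:
    """Everything the generator needs; one seed drives all randomness."""

    seed: int = 0
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)
    n_specimens: int = 100
    scans_per_specimen: int = 2
    age_distribution: tuple[AgeComponent, ...] = SETTLED_AGES
    # spectral model
    age_amplitude_max: float = 0.5    # absorbance units at full saturation
    age_tau_days: float = 5.0         # age scale of spectral maturation
    noise_sd: float = 0.002           # per-point detector noise (absorbance)
    scatter_scale_range: tuple[float, float] = (0.7, 1.3)
    scatter_offset_range: tuple[float, float] = (-0.1, 0.1)
    # treatment dynamics
    kill_old: float = 0.9             # kill probability, age >= old_age_days
    kill_young: float = 0.1           # kill probability, age < old_age_days
    old_age_days: float = 7.0
    recruit_fraction: float = 0.8     # recruit pulse size / n_specimens
    recruit_ages: tuple[AgeComponent, ...] = (AgeComponent(1.0, 1.0, 0.5),)
    # study layout
    species: tuple[str, ...] = ("Sim sp. 1", "Sim sp. 2", "Sim sp. 3")
    n_cycles: int = 4

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.age_distribution)
        if not np.isclose(w, 1.0):
            raise ValueError(f"age mixture weights sum to {w}, expected 1")
        if not 0 <= self.kill_old <= 1 or not 0 <= self.kill_young <= 1:
            raise ValueError("kill fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _baseline(w: np.ndarray) -> np.ndarray:
    # gentle slope with broad curvature across the band
    t = (w - w[0]) / max(w[-1] - w[0], 1.0)
    return 0.8 + 0.4 * t + 0.15 * np.sin(2.2 * np.pi * t)


def _water_peaks(w: np.ndarray) -> np.ndarray:
    return 0.30 * np.exp(-0.5 * ((w - 1210.0) / 40.0) ** 2) + 0.50 * np.exp(
        -0.5 * ((w - 1450.0) / 30.0) ** 2
    )


def _drift_shape(w: np.ndarray) -> np.ndarray:
    # fixed unit-norm aging signature: a ramp plus a localized feature,
    # deliberately not collinear with the baseline
    t = (w - w[0]) / max(w[-1] - w[0], 1.0)
    shape = np.tanh(4.0 * (t - 0.5)) + 0.8 * np.exp(-0.5 * ((t - 0.25) / 0.08) ** 2)
    return shape / np.linalg.norm(shape)


def _amplitude(ages: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    return cfg.age_amplitude_max * (1.0 - np.exp(-ages / cfg.age_tau_days))


def _absorbance_noise(
    rng: np.random.Generator, noise_sd: float, n: int
) -> np.ndarray:
    # intensity-domain detector noise propagated to absorbance; the relative
    # intensity error is floored at -0.999 so the log stays finite
    if noise_sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, np.log(10.0) * noise_sd, size=n)
    return -np.log10(np.maximum(1.0 + eps, 1e-3))


def _draw_ages(
    rng: np.random.Generator, n: int, mixture: Sequence[AgeComponent]
) -> np.ndarray:
    weights = np.array([c.weight for c in mixture])
    idx = rng.choice(len(mixture), size=n, p=weights / weights.sum())
    means = np.array([c.mean_days for c in mixture])[idx]
    sds = np.array([c.sd_days for c in mixture])[idx]
    return np.clip(rng.normal(means, sds), 0.05, None)


def _scan_specimens(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    ages: np.ndarray,
    species: str,
    day: CollectionDay,
    cycle: int,
    id_prefix: str,
) -> list[ScanSpectrum]:
    w = cfg.grid.wavelengths
    clean = _baseline(w) + _water_peaks(w)
    drift = _drift_shape(w)
    amp = _amplitude(ages, cfg)
    scans = []
    for i, a_amp in enumerate(amp):
        true_spec = clean + a_amp * drift
        for rep in range(1, cfg.scans_per_specimen + 1):
            scale = rng.uniform(*cfg.scatter_scale_range)
            offset = rng.uniform(*cfg.scatter_offset_range)
            noise = _absorbance_noise(rng, cfg.noise_sd, w.size)
            scans.append(
                ScanSpectrum(
                    specimen_id=f"{id_prefix}-{i:04d}",
                    species=species,
                    treatment_cycle=cycle,
                    collection_day=day,
                    scan_replicate=rep,
                    absorbance=scale * true_spec + offset + noise,
                    grid=cfg.grid,
                )
            )
    return scans


def simulate_cohort(
    config: SimulationConfig,
    species: str = "Sim sp. 1",
    day: CollectionDay = CollectionDay.PRE,
    cycle: int = 1,
    rng: np.random.Generator | None = None,
) -> list[ScanSpectrum]:
    """One cohort: ``n_specimens`` specimens x ``scans_per_specimen`` scans.

    Deterministic given the config seed (or a caller-supplied generator).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ages = _draw_ages(rng, config.n_specimens, config.age_distribution)
    return _scan_specimens(
        rng, config, ages, species, day, cycle, f"{species}|{day.value}|c{cycle}"
    )


@dataclass
class TreatmentStudy:
    """A simulated pre/post study: the scans plus per-cohort population sizes."""

    scans: list[ScanSpectrum]
    abundance: dict  # (species, day_class) -> simulated population size


def _treatment_pool(
    rng: np.random.Generator, cfg: SimulationConfig, pre_ages: np.ndarray
) -> np.ndarray:
    kill_p = np.where(pre_ages >= cfg.old_age_days, cfg.kill_old, cfg.kill_young)
    survivors = pre_ages[rng.uniform(size=pre_ages.size) >= kill_p]
    n_recruits = int(round(cfg.recruit_fraction * cfg.n_specimens))
    recruits = (
        _draw_ages(rng, n_recruits, cfg.recruit_ages)
        if n_recruits > 0
        else np.empty(0)
    )
    pool = np.concatenate([survivors, recruits])
    if pool.size == 0:
        raise ValueError("treatment emptied the population: no post cohort")
    return pool


def simulate_treatment_study(config: SimulationConfig) -> TreatmentStudy:
    """Full pre/post adulticide study for the configured species and cycles.

    Per species and treatment cycle: a PRE cohort from the configured age
    mixture; a post-treatment age pool of survivors (age-dependent kill)
    plus a recruit pulse; POST d1 and d2 cohorts sampled from that pool
    with ages advanced 1 and 2 days.  Simulated population sizes per
    collection-day class are recorded as the study's abundance analogue.
    """
    rng = np.random.default_rng(config.seed)
    scans: list[ScanSpectrum] = []
    abundance: dict = {}
    for species in config.species:
        for day_class in ("pre", "post_d1", "post_d2"):
            abundance[(species, day_class)] = 0
        for cycle in range(1, config.n_cycles + 1):
            pre_ages = _draw_ages(rng, config.n_specimens, config.age_distribution)
            pool = _treatment_pool(rng, config, pre_ages)
            prefix = f"{species}|c{cycle}"
            scans += _scan_specimens(
                rng, config, pre_ages, species, CollectionDay.PRE, cycle,
                f"{prefix}|PRE",
            )
            abundance[(species, "pre")] += pre_ages.size
            for day, label, age_shift in (
                (CollectionDay.POST_D1, "post_d1", 1.0),
                (CollectionDay.POST_D2, "post_d2", 2.0),
            ):
                n_sample = min(config.n_specimens, pool.size)
                sampled = rng.choice(pool, size=n_sample, replace=False)
                scans += _scan_specimens(
                    rng, config, sampled + age_shift, species, day, cycle,
                    f"{prefix}|{day.value}",
                )
                abundance[(species, label)] += pool.size
    return TreatmentStudy(scans=scans, abundance=abundance)


def simulate_standard_trials(
    config: SimulationConfig, n_trials: int = 2, n_scans: int = 30
) -> list[list[ScanSpectrum]]:
    """Repeated scanning trials of a fixed physical standard.

    The standard's true spectrum (an aspirin-tablet-like curve with sharp
    features) is identical across trials; trials differ only in scatter and
    noise, so feeding the per-trial f values to
    :func:`swirf.outlier_stats.measurement_tolerance` estimates the
    scanning inaccuracy alone.  With ``noise_sd = 0`` the tolerance is
    exactly 0.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 standard trials")
    rng = np.random.default_rng(config.seed)
    w = config.grid.wavelengths
    t = (w - w[0]) / max(w[-1] - w[0], 1.0)
    # low-contrast tablet spectrum: a bright, nearly flat reflector with
    # shallow features, so scanning noise is a non-trivial fraction of the
    # spectral contrast (as for a real white-ish physical standard)
    standard = (
        1.0
        + 0.05 * t
        + 0.06 * np.exp(-0.5 * ((t - 0.35) / 0.03) ** 2)
        + 0.04 * np.exp(-0.5 * ((t - 0.7) / 0.05) ** 2)
    )
    trials = []
    for trial in range(n_trials):
        scans = []
        for i in range(n_scans):
            scale = rng.uniform(*config.scatter_scale_range)
            offset = rng.uniform(*config.scatter_offset_range)
            noise = _absorbance_noise(rng, config.noise_sd, w.size)
            scans.append(
                ScanSpectrum(
                    specimen_id=f"standard-t{trial}-{i:03d}",
                    species="aspirin standard",
                    treatment_cycle=1,
                    collection_day=CollectionDay.PRE,
                    scan_replicate=1,
                    absorbance=scale * standard + offset + noise,
                    grid=config.grid,
                )
            )
        trials.append(scans)
    return trials
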