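"""Synthetic filter-sample and registry generators.

The case study publishes only annual mean ± SD summaries, so the package
generates per-sample data with the statistical structure the analysis
assumes: PM mass and total metal concentrations are log-normal (strictly
positive, right-skewed — the usual shape of environmental concentration
data) with moments matched to the profile, and each sample's extractable
(bioaccessible) fraction is drawn from a moment-matched beta distribution
so the extract concentration, fraction × total, can never exceed the
total.  Everything is deterministic under an explicit seed.

Moment matching
---------------
Log-normal: given mean m > 0 and sd s, σ² = ln(1 + s²/m²) and
μ = ln m − σ²/2.  Beta on (0, 1): given mean m and variance v < m(1−m),
t = m(1−m)/v − 1, α = m·t, β = (1−m)·t.  Zero-SD inputs degenerate to
point masses at the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ExposureParameters, Physiology, PipelineConfig
from .exceptions import ValidationError


@dataclass(frozen=True)
class MetalProfile:
    """Mean ± SD structure for one metal at one site."""

    total_mean: float  # ng·m⁻³
    total_sd: float
    alf_fraction_mean: float  # dimensionless, in (0, 1)
    alf_fraction_sd: float
    gs_fraction_mean: float
    gs_fraction_sd: float

    def __post_init__(self) -> None:
        if self.total_mean <= 0:
            raise ValidationError("total_mean must be > 0")
        if self.total_sd < 0:
            raise ValidationError("total_sd must be >= 0")
        for name in ("alf_fraction_mean", "gs_fraction_mean"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        for name in ("alf_fraction_sd", "gs_fraction_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SiteProfile:
    """Sampling-site profile: PM mass plus per-metal concentration structure."""

    site: str
    pm25_mean: float  # µg·m⁻³
    pm25_sd: float
    metals: dict[str, MetalProfile]

    def __post_init__(self) -> None:
        if self.pm25_mean <= 0:
            raise ValidationError("pm25_mean must be > 0")
        if self.pm25_sd < 0:
            raise ValidationError("pm25_sd must be >= 0")


def _lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if mean <= 0:
        raise ValidationError(f"log-normal mean must be > 0, got {mean}")
    if sd == 0:
        return np.full(n, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _beta_fraction(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    var = sd * sd
    limit = mean * (1.0 - mean)
    if var >= limit:
        raise ValidationError(
            f"fraction sd {sd} too large for beta with mean {mean} "
            f"(need sd² < {limit:.4g})"
        )
    t = limit / var - 1.0
    draws = rng.beta(mean * t, (1.0 - mean) * t, size=n)
    # open-interval guard: beta can return exactly 0.0 in floating point
    return np.clip(draws, np.finfo(float).tiny, 1.0)


def generate_samples(
    profile: SiteProfile, n: int, seed: int, start_date: str = "2015-01-01"
) -> pd.DataFrame:
    """Draw ``n`` synthetic filter samples from a site profile.

    Returns the long-format sample table consumed by
    :func:`pmrisk.io.read_samples` (one row per sample × metal).  Extract
    concentrations are fraction × total by construction, so extract ≤ total
    for every sample and fluid.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if seed is None:
        raise ValidationError("a seed is required")
    rng = np.random.default_rng(seed)
    pm = _lognormal(rng, profile.pm25_mean, profile.pm25_sd, n)
    dates = pd.date_range(start_date, periods=n, freq="9D").strftime("%Y-%m-%d")
    rows = []
    for metal, mp in profile.metals.items():
        total = _lognormal(rng, mp.total_mean, mp.total_sd, n)
        alf_frac = _beta_fraction(rng, mp.alf_fraction_mean, mp.alf_fraction_sd, n)
        gs_frac = _beta_fraction(rng, mp.gs_fraction_mean, mp.gs_fraction_sd, n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{profile.site}-{i + 1:04d}",
                    "site": profile.site,
                    "date": dates[i],
                    "pm25_ugm3": pm[i],
                    "metal": metal,
                    "total_ngm3": total[i],
                    "alf_ngm3": total[i] * alf_frac[i],
                    "gs_ngm3": total[i] * gs_frac[i],
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["sample_id", "metal"], ignore_index=True)


def generate_registries(
    seed: int, perturbation: float = 0.0
) -> tuple[dict, dict]:
    """Jittered copies of the default physiology and exposure registries.

    Each positive scalar field is multiplied by an independent log-normal
    factor with coefficient of variation ``perturbation``; zero
    perturbation returns the shipped defaults unchanged.  Useful for
    robustness/smoke testing of the downstream stages.
    """
    if perturbation < 0:
        raise ValidationError("perturbation must be >= 0")
    cfg = PipelineConfig()
    if perturbation == 0:
        return cfg.physiology, cfg.exposure
    rng = np.random.default_rng(seed)

    def jitter(value: float) -> float:
        return float(value * _lognormal(rng, 1.0, perturbation, 1)[0])

    physiology = {
        c: replace(
            p,
            height_cm=jitter(p.height_cm),
            body_weight_kg=jitter(p.body_weight_kg),
            frc_ml=jitter(p.frc_ml),
            tidal_volume_ml=jitter(p.tidal_volume_ml),
            breathing_frequency=jitter(p.breathing_frequency),
        )
        for c, p in cfg.physiology.items()
    }
    exposure = {
        c: replace(e, inh_r=jitter(e.inh_r), bw=jitter(e.bw))
        for c, e in cfg.exposure.items()
    }
    return physiology, exposure
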