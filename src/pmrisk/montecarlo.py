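"""Monte Carlo propagation of parameter uncertainty through dose and risk.

Per the study design, only the respiration (inhalation) rate is random —
normal with mean equal to the registry value and a configurable
coefficient of variation, truncated at zero by resampling — while
concentrations and body weights are held at their means.  Each iteration
recomputes ADD/LADD → HQ/HI/ILCR through the exposure and risk equations,
yielding empirical distributions, cumulative probability curves, and
exceedance probabilities against the regulatory thresholds.

Runs are reproducible: a seed is mandatory, and identical seeds give
bit-identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import Cohort, all_cohorts
from .config import PipelineConfig
from .deposition import df_lookup
from .exceptions import ValidationError
from .exposure import VARIANTS, ConcentrationSet
from .risk import HI_RISK, ILCR_CARCINOGENIC, ILCR_POTENTIAL

DEFAULT_THRESHOLDS = (HI_RISK, ILCR_CARCINOGENIC, ILCR_POTENTIAL)


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one input parameter."""

    parameter: str = "inhalation_rate"
    family: str = "normal"  # 'normal' or 'point'
    cv: float = 0.3  # coefficient of variation; ignored for 'point'

    def __post_init__(self) -> None:
        if self.family not in ("normal", "point"):
            raise ValidationError("family must be 'normal' or 'point'")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")


@dataclass
class MCResult:
    """Draws of HI and ILCR for one cohort × concentration variant."""

    cohort: Cohort
    variant: str
    hi: np.ndarray
    ilcr: np.ndarray | None
    n_iter: int
    seed: int

    def draws(self, metric: str = "hi") -> np.ndarray:
        arr = self.hi if metric == "hi" else self.ilcr
        if arr is None:
            raise ValidationError(f"no {metric} draws for {self.cohort}")
        return arr

    def cdf(self, metric: str = "hi") -> tuple[np.ndarray, np.ndarray]:
        """Sorted draws and their cumulative probabilities i/n."""
        x = np.sort(self.draws(metric))
        return x, np.arange(1, len(x) + 1) / len(x)

    def cdf_at(self, threshold: float, metric: str = "hi") -> float:
        """P(draw ≤ threshold)."""
        return float(np.mean(self.draws(metric) <= threshold))


def _truncated_normal(
    rng: np.random.Generator, mean: float, cv: float, n: int
) -> np.ndarray:
    """Normal(mean, cv·mean) truncated at zero by resampling negatives."""
    if cv == 0:
        return np.full(n, mean)
    draws = rng.normal(mean, cv * mean, size=n)
    bad = draws <= 0
    while bad.any():
        draws[bad] = rng.normal(mean, cv * mean, size=int(bad.sum()))
        bad = draws <= 0
    return draws


def run_mc(
    conc_summary: pd.DataFrame,
    df_table: pd.DataFrame,
    config: PipelineConfig,
    seed: int,
    n_iter: int | None = None,
    spec: DistributionSpec | None = None,
    variants: tuple[str, ...] = VARIANTS,
    site: str | None = None,
) -> list[MCResult]:
    """Monte Carlo risk distributions per cohort × variant.

    ``conc_summary`` is :func:`pmrisk.exposure.concentration_summary`
    output.  The inhalation-rate draws are shared across variants and
    metals within a cohort (one simulated person per iteration).
    """
    if seed is None:
        raise ValidationError("run_mc requires an explicit seed")
    n_iter = int(n_iter if n_iter is not None else config.mc.iterations)
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if spec is None:
        spec = DistributionSpec(cv=config.mc.inh_r_cv)
    cv = 0.0 if spec.family == "point" else spec.cv

    sites = list(conc_summary["site"].unique())
    if site is None:
        site = "ALL" if "ALL" in sites else sites[0]
    sel = conc_summary[conc_summary["site"] == site]
    if sel.empty:
        raise ValidationError(f"site {site!r} not present in the summary")

    rng = np.random.default_rng(seed)
    results: list[MCResult] = []
    for cohort in all_cohorts():
        params = config.exposure[cohort]
        df_pulm = df_lookup(df_table, cohort).pulmonary
        inh_r = _truncated_normal(rng, params.inh_r, cv, n_iter)
        # ADD = C × InhR × EF/(365 × BW); LADD = ADD × ED/70
        k_add = inh_r * params.ef / (365.0 * params.bw)
        k_ladd = k_add * params.ed / 70.0
        per_variant_hi = {v: np.zeros(n_iter) for v in variants}
        per_variant_ilcr = {v: np.zeros(n_iter) for v in variants}
        any_carcinogen = False
        for _, rec in sel.iterrows():
            tox = config.toxicity[rec.metal]
            cs = ConcentrationSet(
                total=float(rec.total_mgm3),
                alf=float(rec.alf_mgm3) if pd.notna(rec.alf_mgm3) else 0.0,
                gs=float(rec.gs_mgm3) if pd.notna(rec.gs_mgm3) else 0.0,
                df_pulmonary=df_pulm,
            )
            for v in variants:
                c = cs.variant(v)
                per_variant_hi[v] += c * k_add / tox.rfd
                if tox.csf is not None:
                    per_variant_ilcr[v] += c * k_ladd * tox.csf
                    any_carcinogen = True
        for v in variants:
            results.append(
                MCResult(
                    cohort=cohort,
                    variant=v,
                    hi=per_variant_hi[v],
                    ilcr=per_variant_ilcr[v] if any_carcinogen else None,
                    n_iter=n_iter,
                    seed=seed,
                )
            )
    return results


def cumulative_curve(result: MCResult, metric: str = "hi") -> pd.DataFrame:
    """Empirical CDF table (sorted value, cumulative probability)."""
    x, p = result.cdf(metric)
    return pd.DataFrame({"value": x, "cumulative_probability": p})


def exceedance_probability(
    result: MCResult, threshold: float, metric: str = "ilcr"
) -> float:
    """Fraction of draws strictly above ``threshold``."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return float(np.mean(result.draws(metric) > threshold))


def summarize(results: list[MCResult]) -> pd.DataFrame:
    """Summary table: moments, percentiles and threshold exceedances."""
    rows = []
    for r in results:
        row = {
            "age_group": r.cohort.age_group,
            "sex": r.cohort.sex,
            "variant": r.variant,
            "n_iter": r.n_iter,
            "hi_mean": float(r.hi.mean()),
            "hi_sd": float(r.hi.std(ddof=1)) if r.n_iter > 1 else 0.0,
            "hi_p5": float(np.percentile(r.hi, 5)),
            "hi_p50": float(np.percentile(r.hi, 50)),
            "hi_p95": float(np.percentile(r.hi, 95)),
            "p_hi_gt_1": exceedance_probability(r, HI_RISK, "hi"),
        }
        if r.ilcr is not None:
            row.update(
                {
                    "ilcr_mean": float(r.ilcr.mean()),
                    "ilcr_p5": float(np.percentile(r.ilcr, 5)),
                    "ilcr_p50": float(np.percentile(r.ilcr, 50)),
                    "ilcr_p95": float(np.percentile(r.ilcr, 95)),
                    "p_ilcr_gt_1e6": exceedance_probability(r, ILCR_POTENTIAL),
                    "p_ilcr_gt_1e4": exceedance_probability(r, ILCR_CARCINOGENIC),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_cdf(
    results: list[MCResult],
    metric: str = "hi",
    variant: str = "ALF+DF",
    ax=None,
):
    """Cumulative-probability curves per cohort for one variant.

    Solid lines for males, dashed for females, one colour per age group.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    cmap = plt.get_cmap("tab10")
    age_groups = sorted({r.cohort.age_group for r in results})
    for r in results:
        if r.variant != variant:
            continue
        if metric == "ilcr" and r.ilcr is None:
            continue
        x, p = r.cdf(metric)
        ax.plot(
            x,
            p,
            color=cmap(age_groups.index(r.cohort.age_group) % 10),
            linestyle="-" if r.cohort.sex == "male" else "--",
            label=f"{r.cohort.age_group} {r.cohort.sex}",
            linewidth=1.0,
        )
    ax.set_xlabel(metric.upper())
    ax.set_ylabel("cumulative probability")
    ax.set_title(f"{metric.upper()} — {variant}")
    ax.legend(fontsize=6, ncol=2)
    return ax
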