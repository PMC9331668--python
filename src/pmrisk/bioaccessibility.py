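"""Bioaccessible fractions of particle-bound metals in simulated lung fluids.

Bioaccessibility is the share of a metal's total airborne concentration
that dissolves in a simulated physiological fluid — here the acidic
artificial lysosomal fluid (ALF, pH ≈ 4.5, the intracellular macrophage
environment) and the neutral Gamble's solution (GS, pH ≈ 7.4, the
extracellular lung interstitium).  It is computed as
100 × extract / total and classified on a four-level scale:
low (<15 %), intermediate (15–30 %), high (30–50 %), very high (>50 %).

Group-level fractions use the ratio of group *mean* extract to group mean
total (not the mean of per-sample ratios); that convention reproduces the
published summary tables from their printed means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import UndefinedFractionError, ValidationError

log = logging.getLogger("pmrisk")

FLUIDS = ("ALF", "GS")
LEVELS = ("low", "intermediate", "high", "very_high")

RESULT_COLUMNS = [
    "site", "metal", "fluid", "n",
    "total_mean", "total_sd", "extract_mean", "extract_sd",
    "fraction_pct", "level",
]


def bioaccessible_fraction(extract_conc: float, total_conc: float) -> float:
    """Bioaccessibility in percent: 100 × extract / total.

    Fractions above 100 % (extract exceeding total) are returned as-is —
    flagging happens at the sample-validation stage, and clamping would
    hide analytical error.
    """
    if total_conc <= 0:
        raise UndefinedFractionError(
            f"bioaccessible fraction undefined for total_conc={total_conc}"
        )
    if extract_conc < 0:
        raise ValidationError("extract_conc must be >= 0")
    return 100.0 * extract_conc / total_conc


def classify_level(fraction_pct: float) -> str:
    """Map a percentage to the four-level bioaccessibility scale.

    Boundary convention: [0, 15) low, [15, 30) intermediate, [30, 50]
    high, (50, ∞) very_high.
    """
    if fraction_pct < 0:
        raise ValidationError("fraction_pct must be >= 0")
    if fraction_pct < 15.0:
        return "low"
    if fraction_pct < 30.0:
        return "intermediate"
    if fraction_pct <= 50.0:
        return "high"
    return "very_high"


def site_bioaccessibility(samples: pd.DataFrame, grouping: str = "site") -> pd.DataFrame:
    """Per-group bioaccessibility summary (one row per group × metal × fluid).

    ``grouping='site'`` summarises each site separately; ``'all'`` pools
    every sample into a single group labelled ``ALL``.  Groups whose fluid
    concentrations are entirely missing are omitted with a logged warning.
    """
    if grouping not in ("site", "all"):
        raise ValidationError("grouping must be 'site' or 'all'")
    if samples.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    work = samples.copy()
    if grouping == "all":
        work["site"] = "ALL"

    fluid_col = {"ALF": "alf_ngm3", "GS": "gs_ngm3"}
    rows = []
    for (site, metal), grp in work.groupby(["site", "metal"], sort=True):
        total = pd.to_numeric(grp["total_ngm3"], errors="coerce")
        for fluid in FLUIDS:
            extract = pd.to_numeric(grp[fluid_col[fluid]], errors="coerce")
            if extract.isna().all():
                log.warning(
                    "no %s concentrations for %s at %s; omitting", fluid, metal, site
                )
                continue
            frac = bioaccessible_fraction(float(extract.mean()), float(total.mean()))
            rows.append(
                {
                    "site": site,
                    "metal": metal,
                    "fluid": fluid,
                    "n": int(len(grp)),
                    "total_mean": float(total.mean()),
                    "total_sd": float(total.std(ddof=1)) if len(grp) > 1 else 0.0,
                    "extract_mean": float(extract.mean()),
                    "extract_sd": float(extract.std(ddof=1)) if len(grp) > 1 else 0.0,
                    "fraction_pct": frac,
                    "level": classify_level(frac),
                }
            )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out.attrs["units"] = {"total_mean": "ng/m3", "total_sd": "ng/m3",
                          "extract_mean": "ng/m3", "extract_sd": "ng/m3",
                          "fraction_pct": "percent"}
    return out


def pm25_summary(samples: pd.DataFrame, grouping: str = "site",
                 standard: float = 35.0) -> pd.DataFrame:
    """PM₂.₅ mass summary per group with the exceedance ratio mean/standard.

    ``standard`` defaults to the 35 µg·m⁻³ annual ambient-air norm.
    """
    if samples.empty:
        return pd.DataFrame(columns=["site", "n", "pm25_mean", "pm25_sd",
                                     "exceedance_ratio"])
    work = samples.drop_duplicates(subset="sample_id").copy()
    if grouping == "all":
        work["site"] = "ALL"
    rows = []
    for site, grp in work.groupby("site", sort=True):
        pm = grp["pm25_ugm3"].astype(float)
        rows.append(
            {
                "site": site,
                "n": int(len(grp)),
                "pm25_mean": float(pm.mean()),
                "pm25_sd": float(pm.std(ddof=1)) if len(grp) > 1 else 0.0,
                "exceedance_ratio": float(pm.mean()) / standard,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["units"] = {"pm25_mean": "ug/m3", "pm25_sd": "ug/m3"}
    return out
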