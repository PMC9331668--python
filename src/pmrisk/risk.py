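"""Risk characterisation: hazard quotients, hazard index, cancer risk.

Non-carcinogenic risk per metal is the hazard quotient HQ = ADD / RfD;
metals combine additively (no interaction modelled) into the hazard index
HI = Σ HQ, with HI > 1 flagging non-carcinogenic risk.  Carcinogenic risk
is ILCR = LADD × CSF, categorised as carcinogenic above 10⁻⁴, potential
between 10⁻⁶ and 10⁻⁴, and none below 10⁻⁶.  Boundary values fall in the
lower category ("exceeds" read strictly).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .exceptions import NotACarcinogenError, ValidationError

ILCR_CARCINOGENIC = 1e-4
ILCR_POTENTIAL = 1e-6
HI_RISK = 1.0


def hazard_quotient(add: float, rfd: float) -> float:
    """HQ = ADD / RfD (dimensionless)."""
    if rfd <= 0:
        raise ValidationError("RfD must be > 0")
    return add / rfd


def hazard_index(hqs: Mapping[str, float]) -> float:
    """HI = Σᵢ HQᵢ over metals (no interaction terms)."""
    if not hqs:
        raise ValidationError("hazard_index needs at least one HQ")
    return float(sum(hqs.values()))


def ilcr(ladd: float, csf: float | None) -> float:
    """ILCR = LADD × CSF.  Raises for metals without a slope factor."""
    if csf is None:
        raise NotACarcinogenError(
            "no cancer slope factor for this metal; ILCR is undefined"
        )
    if csf <= 0:
        raise ValidationError("CSF must be > 0")
    return ladd * csf


def categorize(hi: float, ilcr_value: float | None = None) -> tuple[str, str | None]:
    """Category labels for (HI, ILCR).

    HI: 'risk' iff HI > 1, else 'no_risk'.  ILCR: 'carcinogenic' above
    10⁻⁴, 'potential' in (10⁻⁶, 10⁻⁴], 'none' at or below 10⁻⁶; ``None``
    passes through when no carcinogen was assessed.
    """
    if hi < 0 or (ilcr_value is not None and ilcr_value < 0):
        raise ValidationError("HI and ILCR must be >= 0")
    hi_cat = "risk" if hi > HI_RISK else "no_risk"
    if ilcr_value is None:
        return hi_cat, None
    if ilcr_value > ILCR_CARCINOGENIC:
        ilcr_cat = "carcinogenic"
    elif ilcr_value > ILCR_POTENTIAL:
        ilcr_cat = "potential"
    else:
        ilcr_cat = "none"
    return hi_cat, ilcr_cat


def risk_table(doses: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Risk characterisation of a dose table.

    One row per cohort × variant with per-metal HQ columns, HI, summed
    carcinogen ILCR, and category labels.  Full precision is retained;
    display rounding is left to the caller.
    """
    toxicity = config.toxicity
    missing = set(doses["metal"].unique()) - set(toxicity)
    if missing:
        raise ValidationError(f"no toxicity reference for metal(s) {sorted(missing)}")
    carcinogens = set(config.carcinogens)

    rows = []
    for (age_group, sex, variant), grp in doses.groupby(
        ["age_group", "sex", "variant"], sort=False
    ):
        hqs = {}
        ilcrs = {}
        for _, rec in grp.iterrows():
            tox = toxicity[rec.metal]
            hqs[rec.metal] = hazard_quotient(rec.add_mgkgday, tox.rfd)
            if rec.metal in carcinogens:
                ilcrs[rec.metal] = ilcr(rec.ladd_mgkgday, tox.csf)
        hi = hazard_index(hqs)
        total_ilcr = float(sum(ilcrs.values())) if ilcrs else None
        hi_cat, ilcr_cat = categorize(hi, total_ilcr)
        row = {"age_group": age_group, "sex": sex, "variant": variant}
        row.update({f"hq_{m}": v for m, v in hqs.items()})
        row["hi"] = hi
        row["hi_category"] = hi_cat
        row.update({f"ilcr_{m}": v for m, v in ilcrs.items()})
        row["ilcr"] = total_ilcr if total_ilcr is not None else np.nan
        row["ilcr_category"] = ilcr_cat
        rows.append(row)
    return pd.DataFrame(rows)
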