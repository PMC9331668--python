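"""Reading and writing sample tables and result tables.

Sample tables are long-format delimited text (comma default, tab
accepted): one row per filter sample × metal, with PM₂.₅ mass in µg·m⁻³
and metal concentrations in ng·m⁻³.  Result tables are CSV with a
deterministic column order and ``#``-prefixed metadata comment lines
(units, provenance) above the header; re-reading a written table restores
the numeric payload at full double precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .exceptions import SchemaError, ValidationError

log = logging.getLogger("pmrisk")

#: Canonical sample-table columns (long format).
SAMPLE_COLUMNS = [
    "sample_id",
    "site",
    "date",
    "pm25_ugm3",
    "metal",
    "total_ngm3",
    "alf_ngm3",
    "gs_ngm3",
]
_REQUIRED = [c for c in SAMPLE_COLUMNS if c not in ("date", "alf_ngm3", "gs_ngm3")]

#: Units metadata attached to every sample table.
SAMPLE_UNITS = {"pm25_ugm3": "ug/m3", "total_ngm3": "ng/m3",
                "alf_ngm3": "ng/m3", "gs_ngm3": "ng/m3"}


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Enforce the sample-table invariants, returning the validated frame.

    Negative concentrations raise; an extract concentration exceeding the
    total is *flagged* (``qc_extract_gt_total`` column plus a warning log),
    never clamped, since it is evidence of analytical error.
    """
    missing = [c for c in _REQUIRED if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample table missing column(s): {', '.join(missing)}")
    out = samples.copy()
    for col in ("date", "alf_ngm3", "gs_ngm3"):
        if col not in out.columns:
            out[col] = pd.NA
    out = out[SAMPLE_COLUMNS + [c for c in out.columns if c not in SAMPLE_COLUMNS]]

    dup = out.duplicated(subset=["sample_id", "metal"])
    if dup.any():
        raise ValidationError(
            f"duplicate sample_id × metal rows: "
            f"{out.loc[dup, ['sample_id', 'metal']].to_dict('records')}"
        )
    for col in ("pm25_ugm3", "total_ngm3", "alf_ngm3", "gs_ngm3"):
        vals = pd.to_numeric(out[col], errors="coerce")
        neg = vals < 0
        if neg.any():
            bad = out.loc[neg, "sample_id"].tolist()
            raise ValidationError(f"negative {col} in sample(s) {bad}")
        out[col] = vals

    flag = pd.Series(False, index=out.index)
    for col in ("alf_ngm3", "gs_ngm3"):
        over = out[col].notna() & (out[col] > out["total_ngm3"])
        if over.any():
            for sid in out.loc[over, "sample_id"]:
                log.warning(
                    "extract concentration exceeds total in sample %s (%s)",
                    sid, col,
                )
            flag |= over
    out["qc_extract_gt_total"] = flag
    out.attrs["units"] = dict(SAMPLE_UNITS)
    return out


def read_samples(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a delimited sample table (CSV; TSV detected from the header).

    ``schema`` optionally maps file column names to the canonical names,
    e.g. ``{"station": "site"}``.  Units are taken as µg·m⁻³ (PM) and
    ng·m⁻³ (metals) and recorded in ``DataFrame.attrs['units']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    header = next(
        (line for line in text.splitlines() if line.strip() and not line.startswith("#")),
        "",
    )
    if not header:
        return validate_samples(pd.DataFrame(columns=SAMPLE_COLUMNS))
    sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, comment="#")
    if schema:
        raw = raw.rename(columns=dict(schema))
    return validate_samples(raw)


def write_results(results: pd.DataFrame, path: str | Path,
                  metadata: Mapping[str, str] | None = None) -> None:
    """Write a result table as CSV with ``#`` metadata comments.

    Column order is preserved as given (deterministic); floats are written
    at full round-trip precision.
    """
    if results is None:
        raise ValidationError("results table is None")
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("writer", "pmrisk")
    units = results.attrs.get("units")
    if units:
        meta.setdefault("units", "; ".join(f"{k}={v}" for k, v in units.items()))
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
        results.to_csv(fh, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
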