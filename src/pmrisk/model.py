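"""Model/Results facade over the full assessment pipeline.

:class:`InhalationRiskModel` bundles a validated sample table with the
configuration registries and deposition-fraction source;  ``fit()`` runs
the deterministic pipeline (bioaccessibility summaries → concentration
variants → doses → risk characterisation) and returns an
:class:`InhalationRiskResults` carrying the stage tables, a ``summary()``
report, and the Monte Carlo / plotting entry points.

Example
-------
>>> from pmrisk import InhalationRiskModel, huludao
>>> res = InhalationRiskModel(huludao.pseudo_samples()).fit()
>>> print(res.summary())                          # doctest: +SKIP
>>> mc = res.simulate(seed=1)                     # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import bioaccessibility as _bio
from . import deposition as _dep
from . import exposure as _exp
from . import montecarlo as _mc
from . import risk as _risk
from .config import PipelineConfig, default_config
from .exceptions import ValidationError
from .io import validate_samples
from .synthetic import SiteProfile, generate_samples


class InhalationRiskModel:
    """Inhalation health-risk assessment of PM₂.₅-bound metals.

    Parameters
    ----------
    samples:
        Long-format sample table (see :mod:`pmrisk.io`); validated on
        construction.
    config:
        :class:`~pmrisk.config.PipelineConfig`; defaults to the shipped
        registries.
    df_table:
        Per-cohort deposition-fraction table; defaults to the shipped
        calibrated table.
    site:
        Which concentration group drives the dose stage ('ALL' pools all
        samples — the default — or a site label with ``grouping='site'``).
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        config: PipelineConfig | None = None,
        df_table: pd.DataFrame | None = None,
        site: str | None = None,
    ) -> None:
        self.samples = validate_samples(samples)
        self.config = (config or default_config()).validate()
        self.df_table = (
            _dep.load_df_table(df_table) if df_table is not None
            else _dep.default_df_table()
        )
        self.site = site

    @classmethod
    def from_profiles(
        cls,
        profiles: dict[str, SiteProfile],
        n: int,
        seed: int,
        **kwargs,
    ) -> "InhalationRiskModel":
        """Build a model from synthetic samples drawn from site profiles."""
        frames = [
            generate_samples(p, n=n, seed=seed + i)
            for i, p in enumerate(profiles.values())
        ]
        return cls(pd.concat(frames, ignore_index=True), **kwargs)

    def fit(self) -> "InhalationRiskResults":
        """Run the deterministic pipeline and return the results object."""
        sites = set(self.samples["site"].unique())
        bio = _bio.site_bioaccessibility(self.samples, grouping="site")
        pm = _bio.pm25_summary(self.samples, grouping="site")
        if "ALL" not in sites:
            # add the pooled group unless the table already carries one
            bio = pd.concat(
                [bio, _bio.site_bioaccessibility(self.samples, grouping="all")],
                ignore_index=True,
            )
            pm = pd.concat(
                [pm, _bio.pm25_summary(self.samples, grouping="all")],
                ignore_index=True,
            )
        if self.site is not None or "ALL" in sites:
            grouping, site = "site", self.site or "ALL"
        else:
            grouping, site = "all", "ALL"
        conc = _exp.concentration_summary(self.samples, grouping=grouping)
        doses = _exp.dose_table(conc, self.df_table, self.config, site=site)
        risks = _risk.risk_table(doses, self.config)
        deposition = _dep.deposition_report(self.df_table)
        return InhalationRiskResults(
            model=self,
            bioaccessibility=bio,
            pm25=pm,
            concentrations=conc,
            deposition=deposition,
            doses=doses,
            risks=risks,
        )


@dataclass
class InhalationRiskResults:
    """Fitted pipeline output: stage tables plus simulation/plot methods."""

    model: InhalationRiskModel
    bioaccessibility: pd.DataFrame
    pm25: pd.DataFrame
    concentrations: pd.DataFrame
    deposition: pd.DataFrame
    doses: pd.DataFrame
    risks: pd.DataFrame
    mc_results: list = field(default_factory=list, repr=False)

    def simulate(
        self,
        seed: int,
        n_iter: int | None = None,
        cv: float | None = None,
        variants: tuple[str, ...] = _exp.VARIANTS,
    ) -> list[_mc.MCResult]:
        """Seeded Monte Carlo over the respiration rate; caches the draws."""
        spec = None
        if cv is not None:
            spec = _mc.DistributionSpec(cv=cv)
        self.mc_results = _mc.run_mc(
            self.concentrations,
            self.model.df_table,
            self.model.config,
            seed=seed,
            n_iter=n_iter,
            spec=spec,
            variants=variants,
            site=self.model.site,
        )
        return self.mc_results

    def mc_summary(self) -> pd.DataFrame:
        if not self.mc_results:
            raise ValidationError("call simulate() before mc_summary()")
        return _mc.summarize(self.mc_results)

    def plot_cdf(self, metric: str = "hi", variant: str = "ALF+DF", ax=None):
        if not self.mc_results:
            raise ValidationError("call simulate() before plot_cdf()")
        return _mc.plot_cdf(self.mc_results, metric=metric, variant=variant, ax=ax)

    def summary(self) -> str:
        """Human-readable report of the headline results."""
        lines = ["Inhalation risk assessment of PM2.5-bound metals", "=" * 50]
        lines.append("\nPM2.5 mass (ug/m3) and exceedance of the 35 ug/m3 norm:")
        for _, r in self.pm25.iterrows():
            lines.append(
                f"  {r.site:>4}: mean {r.pm25_mean:7.1f}  "
                f"ratio {r.exceedance_ratio:4.2f}x"
            )
        lines.append("\nBioaccessibility (group mean extract / mean total):")
        for _, r in self.bioaccessibility.iterrows():
            lines.append(
                f"  {r.site:>4} {r.metal:>2} {r.fluid:<3} "
                f"{r.fraction_pct:5.1f} %  ({r.level})"
            )
        lines.append("\nHazard index / Cd ILCR by variant (most exposed cohorts):")
        sub = self.risks[
            ((self.risks.age_group == "2-5") | (self.risks.age_group == "23-30"))
            & (self.risks.sex == "male")
        ]
        for _, r in sub.iterrows():
            lines.append(
                f"  {r.age_group:>5} male {r.variant:<7} "
                f"HI {r.hi:9.3e} ({r.hi_category})  "
                f"ILCR {r.ilcr:9.3e} ({r.ilcr_category})"
            )
        return "\n".join(lines)
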