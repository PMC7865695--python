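"""Parameter registry for the DxH 800 extended CBC.

The analyzer reports 126 parameters per sample: 23 conventional CBC
parameters, 98 cell population data (CPD) parameters and 5 research-use-only
(RUO) parameters.  CPD parameters are the per-population mean (MN) and
standard deviation (SD) of volume (V), conductivity (C) and five light-scatter
channels (MALS, UMALS, LMALS, LALS, AL2), named with the
``STAT-CHANNEL-POPULATION`` grammar, e.g. ``SD-V-NE``.

Only the "research parameters" (CPD + RUO) that are not derivable from the
routine CBC enter the analysis: MAF is computed from CBC data and is
excluded, and every reticulocyte-derived parameter is excluded because the
reticulocyte count is not part of the basic CBC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

CPD_STATISTICS = ("MN", "SD")
CPD_CHANNELS = ("V", "C", "MALS", "UMALS", "LMALS", "LALS", "AL2")
#: Leukocyte/erythrocyte populations plus reticulocytes (RET).  RET rows are
#: enumerated so the CPD block totals 98, but are never analysis-eligible.
CPD_POPULATIONS = ("NE", "LY", "MO", "EO", "NRBC", "NNRBC", "RET")

RUO_NAMES = ("LHD", "MAF", "PDW", "EGC", "WNOP")

#: The routine CBC panel: counts, erythrocyte and platelet indices, the
#: five-part differential as percentages and absolute counts, and NRBC.
CBC_NAMES = (
    "RBC", "Hb", "Hct", "MCV", "MCH", "MCHC", "RDW", "Plt", "MPV", "MPC",
    "WBC",
    "% NE", "% LY", "% MO", "% EO", "% BA",
    "Abs NE", "Abs LY", "Abs MO", "Abs EO", "Abs BA",
    "% NRBC", "Abs NRBC",
)


class ParameterNameError(ValueError):
    """Raised when a parameter name cannot be parsed or resolved."""


@dataclass(frozen=True)
class ParameterDescriptor:
    """Identity and taxonomy of one extended-CBC parameter.

    Attributes
    ----------
    name : str
        Token such as ``"SD-V-NE"`` or ``"Hb"``.
    category : {"CBC", "CPD", "RUO"}
    statistic : {"MN", "SD", "NA"}
        ``NA`` for CBC and RUO parameters.
    channel : {"V", "C", "MALS", "UMALS", "LMALS", "LALS", "AL2", "NA"}
    population : {"NE", "LY", "MO", "EO", "NRBC", "NNRBC", "RET", "NA"}
    analysis_eligible : bool
        True only for research parameters that survive the MAF and
        reticulocyte exclusions.
    """

    name: str
    category: str
    statistic: str = "NA"
    channel: str = "NA"
    population: str = "NA"
    analysis_eligible: bool = False

    def __post_init__(self) -> None:
        if self.category not in ("CBC", "CPD", "RUO"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "CPD":
            if self.statistic not in CPD_STATISTICS:
                raise ValueError(f"{self.name}: CPD statistic must be MN or SD")
            if self.channel not in CPD_CHANNELS:
                raise ValueError(f"{self.name}: invalid CPD channel")
            if self.population not in CPD_POPULATIONS:
                raise ValueError(f"{self.name}: invalid CPD population")
        elif self.statistic != "NA":
            raise ValueError(f"{self.name}: {self.category} statistic must be NA")

    @property
    def is_research(self) -> bool:
        return self.category in ("CPD", "RUO")


class Registry:
    """Ordered collection of :class:`ParameterDescriptor` with unique names."""

    def __init__(self, descriptors: Iterable[ParameterDescriptor]):
        self.descriptors = list(descriptors)
        names = [d.name for d in self.descriptors]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dupes}")
        self._by_name = {d.name: d for d in self.descriptors}

    def __len__(self) -> int:
        return len(self.descriptors)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ParameterDescriptor:
        try:
            return self._by_name[name]
        except KeyError:
            raise ParameterNameError(f"unknown parameter {name!r}") from None

    @property
    def counts(self) -> dict[str, int]:
        tallies: dict[str, int] = {"CBC": 0, "CPD": 0, "RUO": 0}
        for d in self.descriptors:
            tallies[d.category] += 1
        return tallies

    def names(self, category: str | None = None) -> list[str]:
        return [d.name for d in self.descriptors
                if category is None or d.category == category]

    def research_set(self) -> list[ParameterDescriptor]:
        """All CPD + RUO descriptors (103 in the default registry)."""
        return [d for d in self.descriptors if d.is_research]

    def counting_set(self) -> list[ParameterDescriptor]:
        """Research parameters minus MAF (102 in the default registry)."""
        return [d for d in self.research_set() if d.name != "MAF"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.name, d.category, d.statistic, d.channel, d.population,
              d.analysis_eligible) for d in self.descriptors],
            columns=["name", "category", "statistic", "channel",
                     "population", "analysis_eligible"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Registry":
        return cls(
            ParameterDescriptor(
                name=row["name"], category=row["category"],
                statistic=row["statistic"], channel=row["channel"],
                population=row["population"],
                analysis_eligible=str(row["analysis_eligible"]).lower()
                in ("true", "1"),
            )
            for _, row in frame.iterrows()
        )

    @classmethod
    def from_csv(cls, path) -> "Registry":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def _cpd_eligible(population: str) -> bool:
    return population != "RET"


def build_default_registry() -> Registry:
    """Build the 126-parameter registry: 23 CBC + 98 CPD + 5 RUO.

    Research parameters (CPD + RUO) total 103.  MAF and every
    reticulocyte-population descriptor are marked ineligible, leaving 88
    analysis-eligible parameters.
    """
    descriptors: list[ParameterDescriptor] = []
    for name in CBC_NAMES:
        descriptors.append(ParameterDescriptor(name=name, category="CBC"))
    for stat in CPD_STATISTICS:
        for channel in CPD_CHANNELS:
            for pop in CPD_POPULATIONS:
                descriptors.append(ParameterDescriptor(
                    name=f"{stat}-{channel}-{pop}", category="CPD",
                    statistic=stat, channel=channel, population=pop,
                    analysis_eligible=_cpd_eligible(pop),
                ))
    for name in RUO_NAMES:
        descriptors.append(ParameterDescriptor(
            name=name, category="RUO",
            analysis_eligible=(name != "MAF"),
        ))
    return Registry(descriptors)


def parse_parameter_name(name: str) -> ParameterDescriptor:
    """Resolve a parameter name to its descriptor.

    CBC and RUO names resolve by lookup; hyphenated names are parsed with the
    ``STAT-CHANNEL-POPULATION`` grammar.  Raises
    :class:`ParameterNameError` naming the offending segment.
    """
    if name in CBC_NAMES:
        return ParameterDescriptor(name=name, category="CBC")
    if name in RUO_NAMES:
        return ParameterDescriptor(name=name, category="RUO",
                                   analysis_eligible=(name != "MAF"))
    parts = name.split("-")
    if len(parts) != 3:
        raise ParameterNameError(
            f"{name!r} is not a known CBC/RUO name nor a STAT-CHANNEL-POP token")
    stat, channel, pop = parts
    if stat not in CPD_STATISTICS:
        raise ParameterNameError(f"{name!r}: unknown statistic segment {stat!r}")
    if channel not in CPD_CHANNELS:
        raise ParameterNameError(f"{name!r}: unknown channel segment {channel!r}")
    if pop not in CPD_POPULATIONS:
        raise ParameterNameError(f"{name!r}: unknown population segment {pop!r}")
    return ParameterDescriptor(name=name, category="CPD", statistic=stat,
                               channel=channel, population=pop,
                               analysis_eligible=_cpd_eligible(pop))


def analysis_set(registry: Registry) -> list[ParameterDescriptor]:
    """Research parameters eligible for analysis, in registry order."""
    return [d for d in registry.research_set() if d.analysis_eligible]
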