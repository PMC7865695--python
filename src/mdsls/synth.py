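"""Synthetic two-group extended-CBC cohort generator.

Emulates the study design the score construction assumes: 101 MDS patients
vs 88 healthy volunteers, each described by the full 126-parameter extended
CBC.  Conventional CBC parameters use the published group means +/- SDs
(e.g. haemoglobin 93.8 +/- 18.1 g/L in MDS vs 140.2 +/- 9.2 g/L in health);
the ten critical leukocyte research parameters carry planted shifts with the
clinically observed directions (mean scatter decreased, SD parameters
increased in MDS); every remaining parameter is identically distributed in
the two groups.

Each parameter is drawn from a truncated normal — the published tables give
only marginal moments, so independence is the default.  An optional
equicorrelation ``rho`` induces dependence through a Gaussian copula while
preserving every marginal and its physiological lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .registry import Registry, analysis_set, build_default_registry

GROUP_MDS = "MDS"
GROUP_HEALTHY = "HEALTHY"

#: Generic channel-unit scale for CPD/RUO parameters whose absolute
#: magnitudes are instrument-internal and unpublished.
DEFAULT_RESEARCH_MEAN = 100.0
DEFAULT_RESEARCH_SD = 10.0
#: Planted standardized effect size (Cohen's d) for the critical set.
DEFAULT_EFFECT_D = 1.5

#: The ten critical leukocyte parameters with the direction of the MDS shift:
#: mean light-scatter values fall (hypogranular, less complex cells), while
#: volume / scatter dispersions rise (more heterogeneous populations).
CRITICAL_PARAMETERS: dict[str, int] = {
    "MN-LALS-NNRBC": -1,
    "MN-LMALS-NNRBC": -1,
    "MN-UMALS-NNRBC": -1,
    "MN-MALS-NNRBC": -1,
    "SD-AL2-MO": +1,
    "SD-AL2-NE": +1,
    "SD-MALS-NE": +1,
    "SD-UMALS-NE": +1,
    "SD-V-MO": +1,
    "SD-V-NE": +1,
}

#: Published conventional-CBC group moments: (mds_mean, mds_sd,
#: healthy_mean, healthy_sd) in the parameter's clinical units.
CONVENTIONAL_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "Hb": (93.8, 18.1, 140.2, 9.2),
    "Plt": (154.7, 143.8, 252.9, 48.8),
    "WBC": (4.7, 3.8, 5.8, 1.2),
    "Abs NE": (2.9, 2.9, 3.2, 0.8),
    "MCV": (99.1, 12.3, 92.2, 4.4),
}

#: Plausible healthy reference moments for the remaining CBC panel
#: (identical in both groups — null parameters).
_CBC_NULL_MOMENTS: dict[str, tuple[float, float]] = {
    "RBC": (4.7, 0.4),
    "Hct": (42.0, 3.0),
    "MCH": (30.0, 1.5),
    "MCHC": (33.5, 1.0),
    "RDW": (13.5, 1.0),
    "MPV": (9.5, 1.0),
    "MPC": (27.0, 2.0),
    "% NE": (60.0, 8.0),
    "% LY": (30.0, 7.0),
    "% MO": (7.0, 2.0),
    "% EO": (2.5, 1.5),
    "% BA": (0.5, 0.3),
    "Abs LY": (1.9, 0.5),
    "Abs MO": (0.45, 0.15),
    "Abs EO": (0.15, 0.1),
    "Abs BA": (0.03, 0.02),
    "% NRBC": (0.05, 0.05),
    "Abs NRBC": (0.0, 0.01),
}


@dataclass(frozen=True)
class EffectSpec:
    """Per-parameter group moments and physiological floor."""

    parameter_name: str
    healthy_mean: float
    healthy_sd: float
    mds_mean: float
    mds_sd: float
    lower_bound: float | None = 0.0

    def __post_init__(self) -> None:
        if self.healthy_sd <= 0 or self.mds_sd <= 0:
            raise ValueError(f"{self.parameter_name}: sd must be positive")

    @property
    def is_null(self) -> bool:
        return (self.mds_mean == self.healthy_mean
                and self.mds_sd == self.healthy_sd)


@dataclass
class CohortSpec:
    """Complete description of a synthetic cohort.

    ``effects`` must cover every parameter the cohort table is to contain;
    with the default registry that is all 126 parameters.
    """

    n_mds: int = 101
    n_healthy: int = 88
    effects: dict[str, EffectSpec] = field(default_factory=dict)
    seed: int = 0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_mds < 0 or self.n_healthy < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")

    @property
    def parameter_names(self) -> list[str]:
        return list(self.effects)

    def planted(self) -> list[str]:
        return [name for name, e in self.effects.items() if not e.is_null]


def default_cohort_spec(
    registry: Registry | None = None,
    effect_d: float = DEFAULT_EFFECT_D,
    n_mds: int = 101,
    n_healthy: int = 88,
    seed: int = 0,
    rho: float = 0.0,
) -> CohortSpec:
    """Study-condition cohort spec: published CBC moments, critical set
    planted at standardized effect ``effect_d``, all else null."""
    registry = registry or build_default_registry()
    effects: dict[str, EffectSpec] = {}
    for desc in registry.descriptors:
        name = desc.name
        if name in CONVENTIONAL_EFFECTS:
            m_m, m_s, h_m, h_s = CONVENTIONAL_EFFECTS[name]
            effects[name] = EffectSpec(name, h_m, h_s, m_m, m_s)
        elif desc.category == "CBC":
            mean, sd = _CBC_NULL_MOMENTS[name]
            effects[name] = EffectSpec(name, mean, sd, mean, sd)
        else:
            mean, sd = DEFAULT_RESEARCH_MEAN, DEFAULT_RESEARCH_SD
            direction = CRITICAL_PARAMETERS.get(name)
            if direction is None:
                effects[name] = EffectSpec(name, mean, sd, mean, sd)
            else:
                effects[name] = EffectSpec(
                    name, mean, sd, mean + direction * effect_d * sd, sd)
    return CohortSpec(n_mds=n_mds, n_healthy=n_healthy, effects=effects,
                      seed=seed, rho=rho)


def _truncnorm_params(mean: float, sd: float, lower: float | None):
    a = -np.inf if lower is None else (lower - mean) / sd
    return a, np.inf


def _draw_group(rng: np.random.Generator, effects: list[EffectSpec],
                n: int, group: str, rho: float) -> np.ndarray:
    """Draw an (n, p) block; truncated-normal marginals, optional
    equicorrelated Gaussian copula."""
    p = len(effects)
    out = np.empty((n, p))
    if n == 0:
        return out
    if rho > 0:
        # latent equicorrelated standard normals: common factor + noise
        z_common = rng.standard_normal((n, 1))
        z_idio = rng.standard_normal((n, p))
        z = np.sqrt(rho) * z_common + np.sqrt(1 - rho) * z_idio
        u = stats.norm.cdf(z)
    for j, eff in enumerate(effects):
        mean, sd = ((eff.mds_mean, eff.mds_sd) if group == GROUP_MDS
                    else (eff.healthy_mean, eff.healthy_sd))
        a, b = _truncnorm_params(mean, sd, eff.lower_bound)
        if rho > 0:
            out[:, j] = stats.truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd)
        else:
            out[:, j] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                            size=n, random_state=rng)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the cohort table: one row per subject, columns
    ``subject_id``, ``group`` plus every parameter.  Deterministic in
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    effects = list(spec.effects.values())
    names = [e.parameter_name for e in effects]
    mds = _draw_group(rng, effects, spec.n_mds, GROUP_MDS, spec.rho)
    healthy = _draw_group(rng, effects, spec.n_healthy, GROUP_HEALTHY, spec.rho)
    values = np.vstack([mds, healthy])
    groups = [GROUP_MDS] * spec.n_mds + [GROUP_HEALTHY] * spec.n_healthy
    ids = [f"S{i + 1:04d}" for i in range(len(groups))]
    frame = pd.DataFrame(values, columns=names)
    frame.insert(0, "group", groups)
    frame.insert(0, "subject_id", ids)
    return frame


def null_cohort_spec(n_parameters: int = 200, n_mds: int = 101,
                     n_healthy: int = 88, seed: int = 0) -> CohortSpec:
    """All-null cohort of generic parameters, for type-I-error checks."""
    effects = {
        f"NULL{i:03d}": EffectSpec(f"NULL{i:03d}", DEFAULT_RESEARCH_MEAN,
                                   DEFAULT_RESEARCH_SD, DEFAULT_RESEARCH_MEAN,
                                   DEFAULT_RESEARCH_SD)
        for i in range(n_parameters)
    }
    return CohortSpec(n_mds=n_mds, n_healthy=n_healthy, effects=effects,
                      seed=seed)


def flip_effects(spec: CohortSpec) -> CohortSpec:
    """Mirror every planted shift about the healthy mean (sign flip)."""
    flipped = {
        name: replace(e, mds_mean=2 * e.healthy_mean - e.mds_mean)
        for name, e in spec.effects.items()
    }
    return replace(spec, effects=flipped)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in frame.columns:
            raise ValueError(f"cohort CSV missing required column {col!r}")
    return frame


def cohort_parameters(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in ("subject_id", "group")]


def analysis_parameters(cohort: pd.DataFrame,
                        registry: Registry | None = None) -> list[str]:
    """Analysis-eligible research parameters present in the cohort."""
    registry = registry or build_default_registry()
    eligible = {d.name for d in analysis_set(registry)}
    return [c for c in cohort_parameters(cohort) if c in eligible]
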