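"""Dose factors DF(AM<-TBV) and DF(AM<-CBV) and their aggregation.

A dose factor converts a unit activity concentration of the source region
(Bq per kg of trabecular or cortical bone) into dose rate in the marrow
target (Gy/s); reported values are in units of 1e-14 Gy/s per Bq/kg.  Active
and inactive marrow are assumed to receive equal doses, so the marrow-cavity
tally applies to AM without a cellularity correction.

Aggregation follows the anatomy: segment DFs combine to a site value with
weights proportional to segment marrow volume (the AM fraction per unit
marrow volume is taken equal across the segments of a site), and site values
combine to a skeletal average with the age-dependent AM-distribution weights.
Individual variability is expressed as the relative root-mean-square
deviation of an ensemble of randomized (supplementary) phantoms from the
population-average (basic) one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .registry import AMDistribution
from .transport import TallyResult
from .voxelizer import Morphometry

J_PER_MEV = 1.602176634e-13
REPORT_SCALE = 1e-14  # reporting unit, Gy/s per Bq/kg


class DegenerateDoseError(ValueError):
    pass


@dataclass(frozen=True)
class DFResult:
    """A dose factor in reporting units (1e-14 Gy/s per Bq/kg)."""

    level: str  # segment | site | skeletal
    source: str  # TBV | CBV
    nuclide: str
    value: float
    se_mc: float = 0.0
    cv_individual: float | None = None
    name: str = ""
    components: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("dose factor must be non-negative")
        if self.cv_individual is not None and self.cv_individual < 0:
            raise ValueError("CV must be non-negative")


def compute_df(
    tally: TallyResult,
    morph: Morphometry,
    source: str,
    multiplicity: int | None = None,
    name: str = "",
) -> DFResult:
    """Segment dose factor from a tally and the phantom morphometry.

    DF = multiplicity x e_marrow [MeV/electron] x 1.602e-13 [J/MeV]
         x m_source [kg] / m_marrow [kg],
    expressed per unit activity concentration in the source region and
    reported in 1e-14 Gy/s per Bq/kg.  The Monte Carlo SE propagates linearly.
    """
    m_source_g = {"TBV": morph.m_tbv, "CBV": morph.m_cbv}.get(source)
    if m_source_g is None:
        raise ValueError(f"source must be TBV or CBV, got {source!r}")
    if m_source_g <= 0 or morph.m_marrow <= 0:
        raise DegenerateDoseError("source and marrow masses must be positive")
    if multiplicity is None:
        multiplicity = tally.multiplicity
    scale = multiplicity * J_PER_MEV * (m_source_g / morph.m_marrow) / REPORT_SCALE
    return DFResult(
        level="segment",
        source=source,
        nuclide=tally.nuclide,
        value=tally.e_marrow * scale,
        se_mc=tally.se_marrow * scale,
        name=name,
    )


def site_average(dfs: list[tuple[DFResult, float]], name: str = "") -> DFResult:
    """Marrow-volume-weighted site average of segment dose factors."""
    if not dfs:
        raise ValueError("need at least one segment DF")
    if any(v <= 0 for _, v in dfs):
        raise ValueError("marrow volumes must be positive")
    wtot = sum(v for _, v in dfs)
    value = sum(df.value * v for df, v in dfs) / wtot
    se = math.sqrt(sum((df.se_mc * v) ** 2 for df, v in dfs)) / wtot
    first = dfs[0][0]
    return DFResult(
        level="site",
        source=first.source,
        nuclide=first.nuclide,
        value=value,
        se_mc=se,
        name=name,
        components=tuple(df for df, _ in dfs),
    )


def skeletal_average(
    site_dfs: dict[str, DFResult],
    amdist: AMDistribution,
    missing: str = "renormalize",
) -> DFResult:
    """AM-fraction-weighted skeletal average over the supplied sites.

    Sites carrying AM weight but absent from ``site_dfs`` are either dropped
    with renormalization over the supplied sites (``missing="renormalize"``,
    the default) or raise (``missing="error"``).
    """
    if not site_dfs:
        raise ValueError("no site DFs supplied")
    weights = amdist.normalized()
    absent = [s for s, w in weights.items() if w > 0 and s not in site_dfs]
    if absent and missing == "error":
        raise ValueError(f"sites with AM weight missing from inputs: {absent}")
    used = {s: w for s, w in weights.items() if s in site_dfs and w > 0}
    if not used:
        raise ValueError("no overlap between AM weights and supplied sites")
    wtot = sum(used.values())
    value = sum(site_dfs[s].value * w for s, w in used.items()) / wtot
    se = math.sqrt(sum((site_dfs[s].se_mc * w) ** 2 for s, w in used.items())) / wtot
    first = next(iter(site_dfs.values()))
    return DFResult(
        level="skeletal",
        source=first.source,
        nuclide=first.nuclide,
        value=value,
        se_mc=se,
        name=f"skeletal_{amdist.age_group}",
        components=tuple(site_dfs.values()),
    )


def ensemble_cv(basic: DFResult | float, supplementary: list[DFResult | float]) -> float:
    """Individual-variability CV (%) as relative RMSD from the basic model.

    CV = 100 * sqrt(mean((DF_i - DF_basic)^2)) / DF_basic over the
    supplementary (randomized-phantom) dose factors.
    """
    if len(supplementary) < 2:
        raise ValueError("need at least 2 supplementary results")
    base = basic.value if isinstance(basic, DFResult) else float(basic)
    if base == 0:
        raise DegenerateDoseError("basic DF is zero")
    vals = [s.value if isinstance(s, DFResult) else float(s) for s in supplementary]
    msd = sum((v - base) ** 2 for v in vals) / len(vals)
    return 100.0 * math.sqrt(msd) / base
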