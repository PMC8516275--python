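"""Curated anatomical, material and marrow-distribution parameters.

The registry ships structured-text (YAML) data files, one per bone site,
holding the stylized segment macro-dimensions, the spongiosa microstructure
parameters, tissue densities/compositions, and the age-dependent distribution
of active marrow (AM) over the hematopoietic sites.  All macro lengths are in
cm, all micro lengths in mm, densities in g/cm^3, compositions in % by mass.

Individual variability is expressed as a coefficient of variation (CV, %) for
each parameter; :func:`sample_individual` draws a randomized copy of a spec
from truncated-normal distributions, which is how supplementary phantoms for
uncertainty ensembles are produced.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

AGE_GROUPS = ("newborn", "1y", "5y", "10y", "15y", "adult")
SEXES = ("male", "female", "both")
SHAPES = ("RC", "DC", "EC")

#: Default within-specimen CV (%) of trabecular thickness / separation, used
#: by the framework generator; histomorphometric collections show broad,
#: near-lognormal within-specimen distributions of both quantities.
DEFAULT_INTRA_CV = 25.0


class RegistryLookupError(KeyError):
    """Raised when a site/age/sex/segment combination is not in the registry."""


@dataclass(frozen=True)
class SegmentSpec:
    """Stylized shape and macro-parameters of one bone segment.

    Shapes: ``RC`` round cylinder (h, d1), ``EC`` elliptical cylinder
    (h, d1, d2), ``DC`` deformed cylinder whose cross-section blends linearly
    from a circle of diameter d1 to an ellipse with axes d2 x d3.
    Lengths are cm; each parameter carries a (mean, CV%) pair.
    """

    site_name: str
    segment_name: str
    age_group: str
    sex: str
    shape: str
    h: float
    d1: float
    ct_th: float
    h_cv: float = 0.0
    d1_cv: float = 0.0
    ct_th_cv: float = 0.0
    d2: float | None = None
    d2_cv: float = 0.0
    d3: float | None = None
    d3_cv: float = 0.0
    capped_faces: tuple[str, ...] = ("lateral",)
    micro_key: str = "all"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "RC" and self.d2 is not None:
            raise ValueError("RC takes d1 only")
        if self.shape == "EC" and (self.d2 is None or self.d3 is not None):
            raise ValueError("EC takes d1 and d2")
        if self.shape == "DC" and (self.d2 is None or self.d3 is None):
            raise ValueError("DC takes d1, d2 and d3")
        for name in ("h", "d1", "ct_th"):
            if getattr(self, name) <= 0 and not (name == "ct_th" and self.ct_th == 0):
                raise ValueError(f"{name} must be positive")
        for name in ("h_cv", "d1_cv", "d2_cv", "d3_cv", "ct_th_cv"):
            cv = getattr(self, name)
            if not 0.0 <= cv <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.ct_th >= self.min_cross_radius():
            raise ValueError("ct_th must be smaller than the minimal cross-section radius")

    def min_cross_radius(self) -> float:
        """Smallest cross-sectional semi-axis over the segment height (cm)."""
        semi = [self.d1 / 2.0]
        if self.d2 is not None:
            semi.append(self.d2 / 2.0)
        if self.d3 is not None:
            semi.append(self.d3 / 2.0)
        return min(semi)

    def extents(self) -> tuple[float, float, float]:
        """Axis-aligned bounding extents (cm) of the shape along x, y, z."""
        if self.shape == "RC":
            return self.d1, self.d1, self.h
        if self.shape == "EC":
            return self.d1, self.d2, self.h
        return max(self.d1, self.d2), max(self.d1, self.d3), self.h


@dataclass(frozen=True)
class MicroSpec:
    """Spongiosa microstructure parameters of one segment group.

    ``bvtv`` is the bone volume fraction of spongiosa with its
    inter-individual (min, max) range; ``tb_th`` / ``tb_sp`` are mean
    trabecular thickness / separation in mm with inter-individual CVs (%).
    ``intra_cv_th`` / ``intra_cv_sp`` are the within-specimen CVs used by the
    stochastic framework generator.
    """

    site_name: str
    key: str
    age_group: str
    bvtv: float
    bvtv_min: float
    bvtv_max: float
    tb_th: float
    tb_th_cv: float
    tb_sp: float
    tb_sp_cv: float
    intra_cv_th: float = DEFAULT_INTRA_CV
    intra_cv_sp: float = DEFAULT_INTRA_CV

    def __post_init__(self) -> None:
        if not 0.0 < self.bvtv_min <= self.bvtv <= self.bvtv_max < 1.0:
            raise ValueError("require 0 < bvtv_min <= bvtv <= bvtv_max < 1")
        if not self.tb_th < self.tb_sp:
            raise ValueError("mean Tb.Th must be below mean Tb.Sp")
        if self.tb_th <= 0 or self.tb_sp <= 0:
            raise ValueError("micro lengths must be positive")


@dataclass(frozen=True)
class MaterialSpec:
    """Density (g/cm^3) and elemental mass fractions (%) of one tissue."""

    tissue: str
    density: float
    element_mass_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        total = sum(self.element_mass_fractions.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"mass fractions sum to {total}, expected 100 +- 0.5")


@dataclass(frozen=True)
class AMDistribution:
    """Active-marrow weights per hematopoietic site for one age group.

    Raw weights are % of whole-skeleton AM mass as tabulated; printed columns
    do not sum exactly to 100, so :meth:`normalized` renormalizes to unity.
    """

    age_group: str
    weights: Mapping[str, float]
    sds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("AM weights must be non-negative")

    def normalized(self) -> dict[str, float]:
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("AM weights sum to zero")
        return {k: v / total for k, v in self.weights.items()}


# ---------------------------------------------------------------------------
# data-file loading


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("osteodose.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


_SITE_CACHE: dict[str, dict] = {}
KNOWN_SITES = ("femur",)


def _site_data(site: str) -> dict:
    if site not in KNOWN_SITES:
        raise RegistryLookupError(f"unknown site {site!r}; curated sites: {KNOWN_SITES}")
    if site not in _SITE_CACHE:
        _SITE_CACHE[site] = _load_yaml(f"{site}.yaml")
    return _SITE_CACHE[site]


def load_segment_specs(site: str, age_group: str, sex: str = "both") -> list[SegmentSpec]:
    """Return the ordered segment set for a site/age/sex combination.

    For ages below 15 y segment dimensions are sex-independent and stored with
    ``sex: both``; from 15 y on, sex-specific rows are returned and ``sex``
    must be ``male`` or ``female``.
    """
    if age_group not in AGE_GROUPS:
        raise RegistryLookupError(f"unknown age group {age_group!r}; valid: {AGE_GROUPS}")
    if sex not in SEXES:
        raise RegistryLookupError(f"unknown sex {sex!r}; valid: {SEXES}")
    data = _site_data(site)
    out: list[SegmentSpec] = []
    for row in data["segments"]:
        if row["age_group"] != age_group:
            continue
        if row["sex"] != "both" and row["sex"] != sex:
            continue
        kwargs = dict(
            site_name=site,
            segment_name=row["name"],
            age_group=age_group,
            sex=row["sex"],
            shape=row["shape"],
            h=float(row["h"][0]),
            h_cv=float(row["h"][1]),
            d1=float(row["d1"][0]),
            d1_cv=float(row["d1"][1]),
            ct_th=float(row["ct_th"][0]),
            ct_th_cv=float(row["ct_th"][1]),
            capped_faces=tuple(row["capped_faces"]),
            micro_key=row["micro_key"],
        )
        if "d2" in row:
            kwargs.update(d2=float(row["d2"][0]), d2_cv=float(row["d2"][1]))
        if "d3" in row:
            kwargs.update(d3=float(row["d3"][0]), d3_cv=float(row["d3"][1]))
        out.append(SegmentSpec(**kwargs))
    if not out:
        ages = sorted({r["age_group"] for r in data["segments"]})
        raise RegistryLookupError(
            f"no segments for ({site}, {age_group}, {sex}); ages with data: {ages}"
        )
    return out


def load_micro_spec(site: str, segment_name: str, age_group: str) -> MicroSpec:
    """Return the microstructure parameters for one segment (sex-independent)."""
    data = _site_data(site)
    key = None
    for row in data["segments"]:
        if row["age_group"] == age_group and row["name"] == segment_name:
            key = row["micro_key"]
            break
    if key is None:
        raise RegistryLookupError(
            f"no segment ({site}, {segment_name}, {age_group}) in registry"
        )
    return micro_spec_by_key(site, key, age_group)


def micro_spec_by_key(site: str, key: str, age_group: str) -> MicroSpec:
    data = _site_data(site)
    for row in data["micro"]:
        if row["age_group"] == age_group and row["key"] == key:
            return MicroSpec(
                site_name=site,
                key=key,
                age_group=age_group,
                bvtv=float(row["bvtv"]["mean"]),
                bvtv_min=float(row["bvtv"]["min"]),
                bvtv_max=float(row["bvtv"]["max"]),
                tb_th=float(row["tb_th"][0]),
                tb_th_cv=float(row["tb_th"][1]),
                tb_sp=float(row["tb_sp"][0]),
                tb_sp_cv=float(row["tb_sp"][1]),
            )
    raise RegistryLookupError(f"no micro row ({site}, {key}, {age_group})")


_MATERIALS: dict[str, MaterialSpec] | None = None


def _materials() -> dict[str, MaterialSpec]:
    global _MATERIALS
    if _MATERIALS is None:
        raw = _load_yaml("materials.yaml")["materials"]
        _MATERIALS = {
            name: MaterialSpec(name, float(row["density"]), dict(row["elements"]))
            for name, row in raw.items()
        }
    return _MATERIALS


def material_for(tissue: str, age_group: str = "adult") -> MaterialSpec:
    """Look up a tissue material, resolving age-dependent mineralized bone.

    ``mineralized_bone`` resolves to the newborn composition/density for the
    newborn group and to adult values for every later age (no interpolation);
    marrow materials are age-independent.
    """
    mats = _materials()
    if tissue == "mineralized_bone":
        tissue = (
            "mineralized_bone_newborn" if age_group == "newborn" else "mineralized_bone_adult"
        )
    if tissue not in mats:
        raise RegistryLookupError(f"unknown tissue {tissue!r}; valid: {sorted(mats)}")
    return mats[tissue]


def load_am_distribution(age_group: str) -> AMDistribution:
    """Active-marrow site weights for one age group (raw %, see normalized())."""
    if age_group not in AGE_GROUPS:
        raise RegistryLookupError(f"unknown age group {age_group!r}; valid: {AGE_GROUPS}")
    raw = _load_yaml("am_distribution.yaml")["weights"]
    weights: dict[str, float] = {}
    sds: dict[str, float] = {}
    for site, cols in raw.items():
        cell = cols[age_group]
        if isinstance(cell, dict):
            weights[site] = float(cell["mean"])
            sds[site] = float(cell["sd"])
        else:
            weights[site] = float(cell)
    return AMDistribution(age_group=age_group, weights=weights, sds=sds)


# ---------------------------------------------------------------------------
# individual sampling


def _truncnorm_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One draw from N(mean, cv%*mean) truncated to +-3 SD, floored at 10% of mean."""
    if cv <= 0.0:
        return mean
    sd = cv / 100.0 * mean
    lo = max(mean - 3.0 * sd, 0.1 * mean)
    hi = mean + 3.0 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_individual(spec: SegmentSpec | MicroSpec, rng_seed) -> SegmentSpec | MicroSpec:
    """Draw a randomized individual's copy of a segment or micro spec.

    Each parameter is drawn independently from a truncated normal centred on
    the registry mean with SD = CV% x mean (truncated at +-3 SD and floored at
    10% of the mean).  BV/TV, for which the registry stores a mean and an
    inter-individual range, is drawn from a truncated normal with
    SD = (max - min)/4 confined to [min, max].  A pure function of
    (spec, seed): the same seed always yields the same draw.
    """
    rng = np.random.default_rng(rng_seed)
    if isinstance(spec, SegmentSpec):
        updates: dict[str, float] = {
            "h": _truncnorm_draw(rng, spec.h, spec.h_cv),
            "d1": _truncnorm_draw(rng, spec.d1, spec.d1_cv),
        }
        if spec.d2 is not None:
            updates["d2"] = _truncnorm_draw(rng, spec.d2, spec.d2_cv)
        if spec.d3 is not None:
            updates["d3"] = _truncnorm_draw(rng, spec.d3, spec.d3_cv)
        ct = _truncnorm_draw(rng, spec.ct_th, spec.ct_th_cv)
        # keep the drawn cortex physically consistent with the drawn diameters
        semi = [updates["d1"] / 2.0]
        if "d2" in updates:
            semi.append(updates["d2"] / 2.0)
        if "d3" in updates:
            semi.append(updates["d3"] / 2.0)
        updates["ct_th"] = min(ct, 0.9 * min(semi))
        return replace(spec, **updates)
    if isinstance(spec, MicroSpec):
        sd = (spec.bvtv_max - spec.bvtv_min) / 4.0
        if sd > 0:
            a = (spec.bvtv_min - spec.bvtv) / sd
            b = (spec.bvtv_max - spec.bvtv) / sd
            bvtv = float(stats.truncnorm.rvs(a, b, loc=spec.bvtv, scale=sd, random_state=rng))
        else:
            bvtv = spec.bvtv
        tb_th = _truncnorm_draw(rng, spec.tb_th, spec.tb_th_cv)
        tb_sp = _truncnorm_draw(rng, spec.tb_sp, spec.tb_sp_cv)
        if tb_th >= tb_sp:  # keep the draw physically ordered
            tb_th = 0.99 * tb_sp
        return replace(
            spec,
            bvtv=bvtv,
            bvtv_min=min(spec.bvtv_min, bvtv),
            bvtv_max=max(spec.bvtv_max, bvtv),
            tb_th=tb_th,
            tb_sp=tb_sp,
        )
    raise TypeError(f"cannot sample {type(spec).__name__}")
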