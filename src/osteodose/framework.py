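"""Continuous stochastic rod-lattice model of trabecular spongiosa.

Spongiosa is modeled as a deformed simple-cubic lattice of rod-like
trabeculae: lattice nodes are jittered, each node carries a random thickness,
and every nearest-neighbour edge becomes a conical rod (frustum) whose end
radii are the half-thicknesses of its nodes; the clamped rod ends act as
junction spheres.  The generated separation scale (the lattice spacing) is
calibrated so that the bone volume fraction of the generated structure
matches the target BV/TV, because a cubic rod lattice at the literature
Tb.Th/Tb.Sp ratio does not by itself reproduce the literature BV/TV.

Lengths are cm throughout this module; :class:`~osteodose.registry.MicroSpec`
micro-parameters (mm) are converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .registry import MicroSpec

Box = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


class GeometryError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class Framework:
    """A generated rod lattice: node positions/radii (cm) and rod index pairs."""

    node_pos: np.ndarray  # (N, 3) cm
    node_radius: np.ndarray  # (N,) cm
    rods: np.ndarray  # (M, 2) int32 node-index pairs
    lattice_spacing: float  # cm
    bounding_box: Box
    seed: int

    def __post_init__(self) -> None:
        if self.rods.size and (
            self.rods.min() < 0 or self.rods.max() >= len(self.node_pos)
        ):
            raise ValueError("rod references a missing node")
        if np.any(self.node_radius <= 0):
            raise ValueError("node thicknesses must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.node_pos)

    @property
    def n_rods(self) -> int:
        return len(self.rods)

    def to_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Debug dump: (node table [x y z radius], rod table [ia ib])."""
        nodes = np.column_stack([self.node_pos, self.node_radius])
        return nodes, self.rods.copy()


def _lognormal_params(mean: float, cv_frac: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv_frac * cv_frac)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def generate_framework(
    micro: MicroSpec,
    box: Box,
    rng_seed: int,
    spacing_scale: float = 1.0,
) -> Framework:
    """Generate a deformed cubic rod lattice filling ``box`` (cm).

    The lattice spacing is ``spacing_scale * Tb.Sp``; each node is displaced
    by a uniform jitter of amplitude ``intra_cv_sp% of the spacing`` per
    coordinate and assigned a lognormal thickness with mean Tb.Th and CV
    ``intra_cv_th`` (within-specimen variability).  Rods connect all
    6-neighbour lattice pairs.  Deterministic for a fixed seed.
    """
    tb_sp_cm = micro.tb_sp / 10.0
    tb_th_cm = micro.tb_th / 10.0
    spacing = spacing_scale * tb_sp_cm
    for lo, hi in box:
        if hi - lo < 3.0 * spacing:
            raise GeometryError(
                f"box {box} smaller than 3 lattice spacings = {3 * spacing:.3f} cm on some axis"
            )
    rng = np.random.default_rng(rng_seed)
    # lattice index ranges covering the box expanded by one spacing
    los = [int(np.floor((lo - spacing) / spacing)) for lo, _ in box]
    his = [int(np.ceil((hi + spacing) / spacing)) for _, hi in box]
    counts = [hi - lo + 1 for lo, hi in zip(los, his)]
    ii, jj, kk = np.meshgrid(
        np.arange(los[0], his[0] + 1),
        np.arange(los[1], his[1] + 1),
        np.arange(los[2], his[2] + 1),
        indexing="ij",
    )
    base = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    n = len(base)
    delta = micro.intra_cv_sp / 100.0
    jitter = rng.uniform(-delta, delta, size=(n, 3))
    pos = (base + jitter) * spacing
    mu, sigma = _lognormal_params(tb_th_cm, micro.intra_cv_th / 100.0)
    thickness = rng.lognormal(mu, sigma, size=n)
    radius = thickness / 2.0

    idx = np.arange(n).reshape(counts)
    edges = []
    for axis in range(3):
        a = idx.take(np.arange(counts[axis] - 1), axis=axis).ravel()
        b = idx.take(np.arange(1, counts[axis]), axis=axis).ravel()
        edges.append(np.column_stack([a, b]))
    rods = np.ascontiguousarray(np.vstack(edges).astype(np.int32))
    return Framework(
        node_pos=np.ascontiguousarray(pos),
        node_radius=np.ascontiguousarray(radius),
        rods=rods,
        lattice_spacing=spacing,
        bounding_box=box,
        seed=int(rng_seed),
    )


def point_in_bone(fw: Framework, p) -> bool:
    """True iff ``p`` (cm) lies inside at least one rod frustum / node sphere."""
    p = np.asarray(p, dtype=np.float64)
    for c, (lo, hi) in zip(p, fw.bounding_box):
        if not lo <= c <= hi:
            raise GeometryError(f"point {p} outside bounding box {fw.bounding_box}")
    return bool(
        _kernels.points_in_bone(fw.node_pos, fw.node_radius, fw.rods, p.reshape(1, 3))[0]
    )


def points_in_bone(fw: Framework, pts: np.ndarray) -> np.ndarray:
    """Vectorized membership test (no bounding-box check)."""
    pts = np.ascontiguousarray(pts, dtype=np.float64)
    return _kernels.points_in_bone(fw.node_pos, fw.node_radius, fw.rods, pts)


def rasterized_volume_fraction(fw: Framework, region: Box, res_cm: float) -> float:
    """Bone volume fraction of ``region`` measured on a centre-point voxel grid."""
    origin = np.array([lo for lo, _ in region], dtype=np.float64)
    shape = tuple(
        max(int(round((hi - lo) / res_cm)), 1) for lo, hi in region
    )
    mask = np.zeros(shape, dtype=np.uint8)
    _kernels.rasterize_rods(fw.node_pos, fw.node_radius, fw.rods, origin, res_cm, mask)
    return float(mask.mean())


def _calibration_vf(micro: MicroSpec, n_cells: int, seed: int, scale: float) -> float:
    """VF of the interior of a generation-box framework at a given spacing scale."""
    spacing = scale * micro.tb_sp / 10.0
    box = ((0.0, n_cells * spacing),) * 3
    fw = generate_framework(micro, box, seed, spacing_scale=scale)
    interior = tuple((spacing, (n_cells - 1) * spacing) for _ in range(3))
    res = min(micro.tb_th / 10.0 / 4.0, spacing / 8.0)
    # cap the raster at 400^3 voxels; only bracket endpoints far from the
    # solution ever hit this, where precision is irrelevant
    res = max(res, (n_cells - 2) * spacing / 400.0)
    return rasterized_volume_fraction(fw, interior, res)


def calibrate_spacing(
    micro: MicroSpec,
    rng_seed: int = 0,
    tol: float = 0.005,
    n_cells: int = 12,
    max_iter: int = 30,
    s_lo: float = 0.2,
    s_hi: float = 5.0,
) -> float:
    """Find the spacing scale s so that generated BV/TV matches ``micro.bvtv``.

    The volume fraction of the generated lattice is a strictly decreasing
    function of the spacing (node radii are fixed while the skeleton scales),
    so a bisection bracket on s converges monotonically.  ``tol`` is the
    relative BV/TV tolerance.  The volume fraction is measured on the interior
    of a ``n_cells``-cell generation box, voxelized at Tb.Th/4, with all
    random draws held fixed across iterations.
    """
    if not 0.0 < tol <= 0.05:
        raise ValueError("tol must be in (0, 0.05]")
    target = micro.bvtv
    f_lo = _calibration_vf(micro, n_cells, rng_seed, s_lo)  # dense end: VF high
    f_hi = _calibration_vf(micro, n_cells, rng_seed, s_hi)
    if not (f_hi < target < f_lo):
        raise CalibrationError(
            f"BV/TV target {target} outside attainable bracket "
            f"[{f_hi:.4f} @ s={s_hi}, {f_lo:.4f} @ s={s_lo}]"
        )
    lo, hi = s_lo, s_hi
    s = 1.0 if s_lo < 1.0 < s_hi else 0.5 * (lo + hi)
    best_s, best_err = s, np.inf
    for _ in range(max_iter):
        vf = _calibration_vf(micro, n_cells, rng_seed, s)
        err = abs(vf - target)
        if err < best_err:
            best_s, best_err = s, err
        if err <= tol * target:
            return float(s)
        if vf > target:
            lo = s  # too dense: increase spacing
        else:
            hi = s
        s = 0.5 * (lo + hi)
    # bracket exhausted: the raster estimate has a finite noise floor, so
    # accept the best point if it is within a few tolerances of the target
    if best_err <= 4.0 * tol * target:
        return float(best_s)
    raise CalibrationError(
        f"no convergence within {max_iter} iterations; bracket [{lo:.4f}, {hi:.4f}], "
        f"best |VF - target| = {best_err:.4f}"
    )


def segment_box(extents: tuple[float, float, float], margin: float) -> Box:
    """Centered-x/y, z in [0, h] bounding box for a segment, expanded by margin."""
    ex, ey, ez = extents
    return (
        (-ex / 2.0 - margin, ex / 2.0 + margin),
        (-ey / 2.0 - margin, ey / 2.0 + margin),
        (-margin, ez + margin),
    )
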