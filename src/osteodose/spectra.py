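"""Beta emission model for bone-seeking strontium and source-site sampling.

Spectra are built from Fermi theory: phase space p*W*(W0-W)^2, a
non-relativistic screened Coulomb (Fermi) function for the daughter nucleus,
and the unique first-forbidden shape factor p^2 + q^2 appropriate for the
89Sr, 90Sr and 90Y ground-state transitions.  The combined 90Sr+90Y spectrum
assumes secular equilibrium of the short-lived 90Y daughter with its parent:
two electrons are emitted per parent decay, and the spectrum is normalized
per emitted electron with the emission multiplicity recorded separately.

A tabulated-spectrum override is supported for callers who prefer evaluated
spectra over the analytic shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import LBL_CORT, LBL_TRAB
from .constants import ELECTRON_REST_MEV

_MC2_KEV = ELECTRON_REST_MEV * 1000.0
_ALPHA = 1.0 / 137.035999

#: nuclide -> (endpoint keV, daughter Z); all three transitions are unique
#: first-forbidden
_BRANCHES = {
    "Sr89": (1495.1, 39),
    "Sr90": (546.0, 39),
    "Y90": (2280.1, 40),
}


class SourceError(ValueError):
    pass


@dataclass(frozen=True)
class BetaSpectrum:
    """Normalized beta energy spectrum on a keV grid (pdf per keV)."""

    nuclide: str
    energy_grid: np.ndarray  # keV, ascending
    pdf: np.ndarray  # 1/keV, trapezoidal integral 1
    endpoints: tuple[float, ...]
    multiplicity: int = 1  # electrons per parent decay
    _cdf: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def mean_energy(self) -> float:
        """Mean emitted electron energy, keV (trapezoidal quadrature)."""
        return float(np.trapezoid(self.energy_grid * self.pdf, self.energy_grid))

    def cdf(self) -> np.ndarray:
        if self._cdf is None:
            dE = np.diff(self.energy_grid)
            c = np.concatenate(
                [[0.0], np.cumsum(0.5 * (self.pdf[1:] + self.pdf[:-1]) * dE)]
            )
            c /= c[-1]
            object.__setattr__(self, "_cdf", c)
        return self._cdf


def _branch_pdf(grid_kev: np.ndarray, q_kev: float, z_daughter: int) -> np.ndarray:
    """Unnormalized unique first-forbidden beta shape on ``grid_kev``.

    At E -> 0 the screened Fermi function diverges as 1/beta, cancelling the
    vanishing momentum in the phase space, so the spectrum has a finite
    non-zero intercept; the zero grid point is evaluated in that limit.
    """
    grid_kev = np.where(grid_kev <= 0.0, 1e-6, grid_kev)
    w = 1.0 + grid_kev / _MC2_KEV
    w0 = 1.0 + q_kev / _MC2_KEV
    with np.errstate(invalid="ignore"):
        p = np.sqrt(np.clip(w * w - 1.0, 0.0, None))
    q = np.clip(w0 - w, 0.0, None)  # neutrino momentum, mc^2 units
    shape = np.where(grid_kev < q_kev, p * w * q * q, 0.0)
    beta = np.divide(p, w, out=np.ones_like(p), where=p > 0)
    eta = _ALPHA * z_daughter / np.clip(beta, 1e-9, None)
    fermi = 2.0 * np.pi * eta / -np.expm1(-2.0 * np.pi * eta)
    forbidden = p * p + q * q
    pdf = shape * fermi * forbidden
    pdf[grid_kev >= q_kev] = 0.0
    return pdf


def build_spectrum(
    nuclide: str,
    grid_step_kev: float = 1.0,
    table: tuple[np.ndarray, np.ndarray] | None = None,
) -> BetaSpectrum:
    """Build the emission spectrum of ``Sr89`` or combined ``Sr90Y90``.

    ``table=(energy_kev, relative_intensity)`` overrides the analytic shape
    (the result is renormalized; the endpoint is the last grid energy).
    """
    if table is not None:
        grid = np.asarray(table[0], dtype=np.float64)
        pdf = np.asarray(table[1], dtype=np.float64)
        if np.any(pdf < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("override table must be ascending with pdf >= 0")
        pdf = pdf / np.trapezoid(pdf, grid)
        mult = 2 if nuclide == "Sr90Y90" else 1
        return BetaSpectrum(nuclide, grid, pdf, (float(grid[-1]),), mult)

    if nuclide in _BRANCHES:
        q, z = _BRANCHES[nuclide]
        grid = np.arange(0.0, q + grid_step_kev, grid_step_kev)
        pdf = _branch_pdf(grid, q, z)
        pdf /= np.trapezoid(pdf, grid)
        return BetaSpectrum(nuclide, grid, pdf, (q,), 1)
    if nuclide == "Sr90Y90":
        q_sr, z_sr = _BRANCHES["Sr90"]
        q_y, z_y = _BRANCHES["Y90"]
        grid = np.arange(0.0, q_y + grid_step_kev, grid_step_kev)
        p_sr = _branch_pdf(grid, q_sr, z_sr)
        p_sr /= np.trapezoid(p_sr, grid)
        p_y = _branch_pdf(grid, q_y, z_y)
        p_y /= np.trapezoid(p_y, grid)
        pdf = 0.5 * (p_sr + p_y)  # per emitted electron, 2 electrons per decay
        return BetaSpectrum(nuclide, grid, pdf, (q_sr, q_y), 2)
    raise ValueError(f"unsupported nuclide {nuclide!r}; known: Sr89, Sr90, Y90, Sr90Y90")


def sample_energy(sp: BetaSpectrum, rng: np.random.Generator, size: int | None = None):
    """Inverse-CDF sample of emission energies (keV)."""
    u = rng.random(size if size is not None else ())
    return np.interp(u, sp.cdf(), sp.energy_grid)


def isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cz = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sz = np.sqrt(1.0 - cz * cz)
    return np.column_stack([sz * np.cos(phi), sz * np.sin(phi), cz])


def sample_source_site(ph, region: str, rng: np.random.Generator, size: int = 1):
    """Uniform source sites in TBV or CBV voxels of a phantom.

    Returns (voxel indices (n,3), positions cm (n,3), directions (n,3)):
    voxels uniform over the region, positions uniform within each voxel,
    directions isotropic.
    """
    label = {"TBV": LBL_TRAB, "CBV": LBL_CORT}.get(region)
    if label is None:
        raise SourceError(f"region must be TBV or CBV, got {region!r}")
    vox = np.argwhere(ph.labels == label)
    if len(vox) == 0:
        raise SourceError(f"phantom has no {region} voxels")
    sel = vox[rng.integers(0, len(vox), size)]
    res = ph.res_cm
    pos = ph.origin[None, :] + (sel + rng.random((size, 3))) * res
    return sel, pos, isotropic_directions(rng, size)
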