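"""Stopping-power physics and condensed-history transport behaviour."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from osteodose.constants import CLASSICAL_COEFF, ELECTRON_REST_MEV, ELEMENTS
from osteodose.registry import MaterialSpec, material_for
from osteodose.spectra import build_spectrum
from osteodose.transport import (
    TransportConfig,
    csda_range,
    homogeneous_spongiosa,
    mix_materials,
    radial_absorption,
    run_mc,
    stopping_power,
    transport_history,
)


def _bethe_oracle(mat: MaterialSpec, e_mev: float) -> float:
    """Independent re-derivation of the collision stopping power (MeV/cm)."""
    za = sum(
        w / 100.0 * ELEMENTS[el][0] / ELEMENTS[el][1]
        for el, w in mat.element_mass_fractions.items()
    )
    ln_i = (
        sum(
            w / 100.0 * ELEMENTS[el][0] / ELEMENTS[el][1]
            * math.log(ELEMENTS[el][2] * 1e-6 / ELECTRON_REST_MEV)
            for el, w in mat.element_mass_fractions.items()
        )
        / za
    )
    tau = e_mev / ELECTRON_REST_MEV
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    f_tau = 1.0 - beta2 + (tau**2 / 8.0 - (2 * tau + 1) * math.log(2)) / (tau + 1) ** 2
    bracket = math.log(tau * tau * (tau + 2.0) / 2.0) - 2.0 * ln_i + f_tau
    return CLASSICAL_COEFF * za / beta2 * bracket * mat.density


class TestStoppingPower:
    def test_density_scaling(self):
        bone = material_for("mineralized_bone", "adult")
        doubled = MaterialSpec("dense", bone.density * 2, bone.element_mass_fractions)
        s1 = stopping_power(bone, 500.0)
        s2 = stopping_power(doubled, 500.0)
        assert s2[0] == pytest.approx(2 * s1[0], rel=1e-12)
        assert s2[1] == pytest.approx(2 * s1[1], rel=1e-12)

    def test_matches_independent_bethe_evaluation(self):
        bone = material_for("mineralized_bone", "adult")
        s_col, _ = stopping_power(bone, 500.0)
        assert s_col == pytest.approx(_bethe_oracle(bone, 0.5), rel=1e-6)

    def test_energy_range_enforced(self):
        marrow = material_for("active_marrow")
        with pytest.raises(ValueError):
            stopping_power(marrow, 0.5)
        with pytest.raises(ValueError):
            stopping_power(marrow, 4000.0)

    def test_csda_path_in_spongiosa_about_2mm(self):
        """Mean-beta-energy electron path length in homogeneous spongiosa."""
        sp = build_spectrum("Sr90Y90")
        mat = homogeneous_spongiosa("adult", bvtv=0.17)
        path_mm = csda_range(mat, sp.mean_energy, cutoff_kev=10.0) * 10.0
        assert path_mm == pytest.approx(2.0, rel=0.25)

    def test_mixture_mass_fractions_consistent(self):
        mat = homogeneous_spongiosa("adult", bvtv=0.17)
        assert sum(mat.element_mass_fractions.values()) == pytest.approx(100.0, abs=1e-9)
        bone = material_for("mineralized_bone", "adult")
        marrow = material_for("active_marrow")
        assert mat.density == pytest.approx(0.17 * bone.density + 0.83 * marrow.density)


class TestTransportHistory:
    def test_energy_below_cutoff_deposits_locally(self, tiny_phantom):
        trab = np.argwhere(tiny_phantom.labels == 2)[0]
        start = tiny_phantom.origin + (trab + 0.5) * tiny_phantom.res_cm
        dep = transport_history(tiny_phantom, start, (0.0, 0.0, 1.0), 5.0)
        assert dep["tbv"] == pytest.approx(0.005)
        assert dep["marrow"] == dep["cbv"] == dep["escaped"] == dep["radiative"] == 0.0

    def test_per_history_energy_conservation(self, tiny_phantom, rng):
        for trial in range(20):
            idx = np.argwhere(tiny_phantom.labels == 3)
            v = idx[rng.integers(len(idx))]
            start = tiny_phantom.origin + (v + 0.5) * tiny_phantom.res_cm
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            e0_kev = rng.uniform(50.0, 2000.0)
            dep = transport_history(tiny_phantom, start, u, e0_kev, seed=trial)
            assert sum(dep.values()) == pytest.approx(e0_kev / 1000.0, rel=1e-6)

    def test_containment_within_csda_range(self):
        """Point source in infinite marrow: deposits confined to the CSDA sphere."""
        marrow = material_for("active_marrow")
        grid = np.array([499.9, 500.1])
        mono = build_spectrum("Sr89", table=(grid, np.array([1.0, 1.0])))
        r_csda_mm = csda_range(marrow, 500.0, cutoff_kev=10.0) * 10.0
        radii, edep, e_rad = radial_absorption(
            marrow, mono, n_histories=3000, seed=3, bin_width_mm=0.05, r_max_mm=5.0
        )
        total = edep.sum()
        within = edep[radii <= r_csda_mm * 1.02].sum()
        assert within / total > 0.999


class TestRunMC:
    def test_seed_reproducibility(self, tiny_phantom):
        cfg = TransportConfig(n_histories=2000, seed=9)
        a = run_mc(tiny_phantom, "Sr90Y90", "TBV", cfg)
        b = run_mc(tiny_phantom, "Sr90Y90", "TBV", cfg)
        assert a == b

    def test_tally_closes_energy_balance(self, tiny_phantom):
        cfg = TransportConfig(n_histories=4000, seed=1)
        t = run_mc(tiny_phantom, "Sr90Y90", "TBV", cfg)
        assert t.total() == pytest.approx(t.mean_source_energy, rel=1e-4)

    def test_se_scales_as_inverse_sqrt_n(self, tiny_phantom):
        t1 = run_mc(
            tiny_phantom, "Sr90Y90", "TBV",
            TransportConfig(n_histories=4000, n_batches=100, seed=4),
        )
        t2 = run_mc(
            tiny_phantom, "Sr90Y90", "TBV",
            TransportConfig(n_histories=16000, n_batches=100, seed=5),
        )
        assert t1.se_marrow / t2.se_marrow == pytest.approx(2.0, rel=0.30)

    def test_zero_marrow_field(self, tiny_phantom):
        lab = tiny_phantom.labels.copy()
        lab[lab == 3] = 2  # relabel all marrow as trabecular bone
        ph = dataclasses.replace(tiny_phantom, labels=lab)
        t = run_mc(ph, "Sr90Y90", "TBV", TransportConfig(n_histories=2000, seed=6))
        assert t.e_marrow == 0.0

    def test_low_energy_electrons_do_not_escape(self, tiny_phantom):
        """50 keV range (~40 um) is far below segment size and cortex thickness."""
        grid = np.array([49.9, 50.1])
        mono = build_spectrum("Sr89", table=(grid, np.array([1.0, 1.0])))
        t = run_mc(
            tiny_phantom, "Sr89", "TBV",
            TransportConfig(n_histories=2000, seed=7), spectrum=mono,
        )
        assert t.e_escaped < 1e-4 * t.mean_source_energy

    def test_quarter_turn_symmetry(self, tiny_phantom):
        """Rotating the phantom about the grid axis leaves tallies within SE."""
        rot = dataclasses.replace(
            tiny_phantom, labels=np.ascontiguousarray(np.rot90(tiny_phantom.labels, axes=(0, 1)))
        )
        cfg = TransportConfig(n_histories=6000, seed=8)
        t1 = run_mc(tiny_phantom, "Sr90Y90", "TBV", cfg)
        t2 = run_mc(rot, "Sr90Y90", "TBV", cfg)
        tol = 3.0 * math.hypot(t1.se_marrow, t2.se_marrow)
        assert abs(t1.e_marrow - t2.e_marrow) < tol

    def test_marrow_absorbed_fraction_decreases_with_bvtv(self, tiny_spec, tiny_micro):
        """At fixed energy, denser bone soaks up more of the emitted energy."""
        from osteodose.pipeline import build_phantom

        lo = dataclasses.replace(tiny_micro, bvtv=0.15, bvtv_min=0.1, bvtv_max=0.2)
        hi = dataclasses.replace(tiny_micro, bvtv=0.40, bvtv_min=0.35, bvtv_max=0.45)
        grid = np.array([199.9, 200.1])
        mono = build_spectrum("Sr89", table=(grid, np.array([1.0, 1.0])))
        cfg = TransportConfig(n_histories=4000, seed=11)
        afs = []
        for micro in (lo, hi):
            ph = build_phantom(tiny_spec, micro, seed=12, resolution_um=100.0).phantom
            t = run_mc(ph, "Sr89", "TBV", cfg, spectrum=mono)
            afs.append(t.e_marrow / t.mean_source_energy)
        assert afs[0] > afs[1]
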