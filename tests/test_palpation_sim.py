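"""Virtual-palpation FE solver: microstructures, oracles, suite plumbing."""

import numpy as np
import pytest

from viscopalp import (
    LoadProtocol,
    Microstructure2D,
    PalpationBC,
    PronyMaterial,
    SuiteConfig,
    generate_random_microstructure,
    run_parametric_suite,
    simulate_relaxation,
)
from viscopalp.characterize import fit_prony_1term


class TestMicrostructureGeneration:
    def test_fraction_zero_all_healthy(self):
        m = generate_random_microstructure(8, 8, 0.0, seed=3)
        assert m.realized_fraction == 0.0

    def test_exact_count_rule(self):
        m = generate_random_microstructure(10, 10, 0.6, seed=5)
        assert int(np.count_nonzero(m.labels)) == 60
        assert m.realized_fraction == pytest.approx(0.6)

    def test_determinism_per_seed(self):
        a = generate_random_microstructure(12, 9, 0.4, seed=11)
        b = generate_random_microstructure(12, 9, 0.4, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = generate_random_microstructure(12, 9, 0.4, seed=12)
        assert np.any(a.labels != c.labels)

    def test_text_round_trip(self, tmp_path):
        m = generate_random_microstructure(7, 5, 0.3, seed=2)
        p = tmp_path / "micro.txt"
        m.save_text(p)
        back = Microstructure2D.load_text(p)
        np.testing.assert_array_equal(back.labels, m.labels)
        assert back.seed == 2 and back.element_size == m.element_size

    def test_vtk_export_is_parseable_text(self, tmp_path):
        m = generate_random_microstructure(3, 2, 0.5, seed=1)
        p = tmp_path / "micro.vtk"
        m.save_vtk(p)
        text = p.read_text()
        assert "DATASET UNSTRUCTURED_GRID" in text
        assert f"CELLS {3 * 2} " in text

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            Microstructure2D(nx=2, ny=2, element_size=1e-3,
                             labels=np.array([[0, 2], [0, 1]]),
                             target_fraction=0.5)


class TestSolverOracles:
    def test_elastic_patch_test_machine_tolerance(self, healthy, cancerous,
                                                  relaxation_step_protocol):
        # instantaneous response of a uniform sample under full-edge platen
        # compression is the exact uniform uniaxial stress state
        micro = generate_random_microstructure(6, 6, 0.0, seed=1,
                                               element_size=1e-3)
        trace = simulate_relaxation(micro, healthy, cancerous,
                                    relaxation_step_protocol)
        width = 6 * 1e-3
        strain = relaxation_step_protocol.magnitude / (6 * 1e-3)
        F_exact = healthy.E0 * strain * width
        assert trace.values[0] == pytest.approx(F_exact, rel=1e-12)

    def test_homogeneous_relaxation_matches_analytic_modulus(self, healthy,
                                                             cancerous):
        # correspondence with the 1D law under uniform uniaxial stress
        prot = LoadProtocol(mode="relaxation", magnitude=1e-3, hold_time=5.0,
                            ramp_time=0.0, dt=0.05)
        micro = generate_random_microstructure(8, 8, 1.0, seed=1)
        trace = simulate_relaxation(micro, healthy, cancerous, prot)
        g = trace.values / trace.values[0]
        g_ref = cancerous.relaxation_modulus(trace.times) / cancerous.E0
        assert np.max(np.abs(g - g_ref) / g_ref) < 0.01

    def test_relabel_symmetry(self, healthy, cancerous,
                              relaxation_ramp_protocol):
        micro = generate_random_microstructure(10, 10, 0.4, seed=7)
        swapped = Microstructure2D(nx=10, ny=10,
                                   element_size=micro.element_size,
                                   labels=1 - micro.labels,
                                   target_fraction=0.6, seed=7)
        t1 = simulate_relaxation(micro, healthy, cancerous,
                                 relaxation_ramp_protocol)
        t2 = simulate_relaxation(swapped, cancerous, healthy,
                                 relaxation_ramp_protocol)
        np.testing.assert_allclose(t1.values, t2.values, rtol=1e-12)

    @pytest.mark.parametrize("nx,ny,nu,rtol", [
        # nu=0 removes lateral coupling entirely: closed form is exact
        (10, 10, 0.0, 1e-12),
        # at the default nu the bonded-interface Poisson boundary layer is
        # physical; a slender stack keeps it below the closed form's 0.5%
        (4, 40, 0.45, 0.005),
    ])
    def test_series_laminate_instantaneous_compliance(self, nx, ny, nu, rtol,
                                                      healthy, cancerous,
                                                      relaxation_step_protocol):
        # stripes perpendicular to loading: elastic series-compliance formula
        labels = np.zeros((ny, nx), dtype=np.int8)
        labels[: ny // 2, :] = 1  # bottom half cancerous
        micro = Microstructure2D(nx=nx, ny=ny, element_size=1e-3, labels=labels,
                                 target_fraction=0.5)
        trace = simulate_relaxation(micro, healthy, cancerous,
                                    relaxation_step_protocol, nu=nu)
        width = nx * 1e-3
        strain = relaxation_step_protocol.magnitude / (ny * 1e-3)
        E_series = 1.0 / (0.5 / healthy.E0 + 0.5 / cancerous.E0)
        assert trace.values[0] == pytest.approx(E_series * strain * width,
                                                rel=rtol)

    def test_recurrence_matches_hereditary_integral(self, healthy, cancerous):
        # 2x2 homogeneous mesh with a ramp: the internal-variable recurrence
        # must reproduce dense-grid quadrature of F(t) = w*int E(t-s) deps(s)
        prot = LoadProtocol(mode="relaxation", magnitude=1e-3, hold_time=5.0,
                            ramp_time=1.0, dt=0.05)
        micro = generate_random_microstructure(2, 2, 0.0, seed=1,
                                               element_size=1e-3)
        trace = simulate_relaxation(micro, healthy, cancerous, prot)
        width, height = 2e-3, 2e-3
        eps_rate = prot.magnitude / height / prot.ramp_time

        def force_oracle(t):
            s = np.linspace(0.0, min(t, prot.ramp_time), 4001)
            E = healthy.relaxation_modulus(t - s)
            return width * eps_rate * np.trapezoid(E, s)

        ref = np.array([force_oracle(t) for t in trace.times[1:]])
        assert np.max(np.abs(trace.values[1:] - ref) / ref) < 0.001

    def test_hold_force_non_increasing(self, healthy, cancerous,
                                       relaxation_ramp_protocol):
        for seed in (1, 2):
            micro = generate_random_microstructure(12, 12, 0.5, seed=seed)
            tr = simulate_relaxation(micro, healthy, cancerous,
                                     relaxation_ramp_protocol)
            hold = tr.values[tr.hold_mask()]
            assert np.all(np.diff(hold) <= 1e-12 * hold[0])

    def test_lateral_equals_posterior_on_transpose(self, healthy, cancerous,
                                                   relaxation_step_protocol):
        micro = generate_random_microstructure(8, 6, 0.3, seed=4)
        lat = simulate_relaxation(micro, healthy, cancerous,
                                  relaxation_step_protocol,
                                  PalpationBC(indented_edge="lateral",
                                              constrained_edges=("posterior",)))
        post = simulate_relaxation(micro.transposed(), healthy, cancerous,
                                   relaxation_step_protocol)
        np.testing.assert_allclose(lat.values, post.values, rtol=1e-12)

    def test_creep_protocol_rejected(self, healthy, cancerous, creep_protocol):
        micro = generate_random_microstructure(4, 4, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate_relaxation(micro, healthy, cancerous, creep_protocol)


class TestHomogenizationConsistency:
    def test_seed_scatter_shrinks_with_mesh_refinement(self, healthy,
                                                       cancerous):
        prot = LoadProtocol(mode="relaxation", magnitude=1e-3, hold_time=5.0,
                            ramp_time=0.0, dt=0.05)
        stds = []
        for n in (10, 20, 40):
            taus = []
            for seed in range(10):
                micro = generate_random_microstructure(n, n, 0.5, seed=seed)
                tr = simulate_relaxation(micro, healthy, cancerous, prot)
                taus.append(fit_prony_1term(tr).tau_hm)
            stds.append(np.std(taus))
        assert stds[0] > stds[1] > stds[2]


class TestParametricSuite:
    def test_row_count_and_null_cells(self, healthy, cancerous):
        cfg = SuiteConfig(pairs=[(healthy, cancerous)], fractions=[0.0],
                          t_exps=[5.0], seeds=[1, 2], nx=10, ny=10)
        df = run_parametric_suite(cfg)
        assert len(df) == 2
        assert (df["status"] == "ok").all()
        assert (df["estimated_fraction"] < 0.02).all()

    def test_fitted_tau_increases_with_fraction(self, healthy, cancerous):
        cfg = SuiteConfig(pairs=[(healthy, cancerous)],
                          fractions=[0.2, 0.4, 0.6, 0.8], t_exps=[5.0],
                          seeds=[1, 2, 3], nx=16, ny=16,
                          rule_fraction_step=0.05)
        df = run_parametric_suite(cfg)
        mean_tau = df.groupby("target_fraction")["fitted_tau_s"].mean()
        assert np.all(np.diff(mean_tau.to_numpy()) > 0)
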