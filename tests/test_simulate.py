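"""Generators: determinism, analytic anchors, and oracle comparisons."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from chronospeckle import simulate
from chronospeckle.simulate import (
    ComponentSpec,
    SignalSpec,
    SimScenario,
    gen_damped_sinusoid,
    gen_expression_timecourse,
    gen_frap_trace,
    gen_read_set,
    gen_speckle_image,
)


class TestDampedSinusoid:
    def test_cosine_anchors(self):
        """Unit 12-h cosine at 2-h sampling: 1 at t=0, -1 at half period."""
        scen = SimScenario(n_samples=24, noise_sd=0.0)
        ts = gen_damped_sinusoid([ComponentSpec(1.0, 12.0)], scen)
        assert ts.values[0] == pytest.approx(1.0)
        assert ts.values[3] == pytest.approx(-1.0)  # t = 6 h = T/2

    def test_empty_components_give_constant_baseline(self):
        ts = gen_damped_sinusoid([], SimScenario(), baseline=5.0)
        np.testing.assert_allclose(ts.values, 5.0)

    def test_damped_value_at_sample_12(self):
        """A=1, T=24, d=0.9: value at sample 12 (t=24 h) is 0.9**12."""
        ts = gen_damped_sinusoid([ComponentSpec(1.0, 24.0, 0.9)], SimScenario())
        assert ts.values[12] == pytest.approx(0.9**12)

    def test_seed_determinism(self):
        scen = SimScenario(noise_sd=0.3, seed=17)
        a = gen_damped_sinusoid([ComponentSpec(1.0, 12.0)], scen)
        b = gen_damped_sinusoid([ComponentSpec(1.0, 12.0)], scen)
        assert np.array_equal(a.values, b.values)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ComponentSpec(1.0, -12.0)
        with pytest.raises(ValueError):
            SimScenario(dt=0.0)


class TestExpressionTimecourse:
    def test_steady_state_stays_flat(self):
        """kp*p = kd*m at t=0 keeps m constant forever."""
        tc, _ = gen_expression_timecourse(
            SignalSpec((), 0.1), SignalSpec((), 1.0), 0.1, SimScenario()
        )
        np.testing.assert_allclose(tc.mature.values, 1.0, rtol=1e-9)

    def test_pure_decay(self):
        """kp = 0 with m0 = 1: m(t) = exp(-kd t)."""
        tc, _ = gen_expression_timecourse(
            SignalSpec((), 0.0), SignalSpec((), 1.0), 0.1, SimScenario(), m0=1.0
        )
        np.testing.assert_allclose(
            tc.mature.values, np.exp(-0.1 * tc.mature.times), rtol=1e-7
        )

    def test_against_adaptive_integrator_oracle(self):
        """Fixed-step RK4 matches an adaptive solver to < 0.1% relative."""
        kp_spec = SignalSpec((ComponentSpec(0.15, 12.0),), 0.3)
        scen = SimScenario()

        def kp_of(t):
            return 0.3 + 0.15 * np.cos(2 * np.pi * t / 12.0)

        m0 = kp_of(0.0) * 1.0 / 0.1
        sol = solve_ivp(
            lambda t, m: kp_of(t) * 1.0 - 0.1 * m,
            (0.0, 46.0),
            [m0],
            t_eval=scen.times,
            rtol=1e-10,
            atol=1e-12,
        )
        tc, _ = gen_expression_timecourse(kp_spec, SignalSpec((), 1.0), 0.1, scen)
        rel = np.abs(tc.mature.values - sol.y[0]) / np.abs(sol.y[0])
        assert rel.max() < 1e-3

    def test_fine_grid_model_residual(self):
        """Central-difference residual of the ODE on the fine grid is tiny."""
        kp_spec = SignalSpec((ComponentSpec(0.15, 12.0),), 0.3)
        _, _, fine = gen_expression_timecourse(
            kp_spec, SignalSpec((), 1.0), 0.1, SimScenario(), return_fine=True
        )
        t, p, m, kp = fine["t"], fine["p"], fine["m"], fine["kp"]
        dm = (m[2:] - m[:-2]) / (t[2:] - t[:-2])
        resid = dm - (kp[1:-1] * p[1:-1] - 0.1 * m[1:-1])
        assert np.max(np.abs(resid)) < 1e-3 * np.max(np.abs(m))

    def test_noise_is_multiplicative_and_seeded(self):
        scen = SimScenario(noise_sd=0.2, seed=5)
        tc1, _ = gen_expression_timecourse(
            SignalSpec((), 0.1), SignalSpec((), 1.0), 0.1, scen
        )
        tc2, _ = gen_expression_timecourse(
            SignalSpec((), 0.1), SignalSpec((), 1.0), 0.1, scen
        )
        assert np.array_equal(tc1.pre.values, tc2.pre.values)
        assert (tc1.pre.values > 0).all()  # log-normal keeps positivity

    def test_negative_kd_rejected(self):
        with pytest.raises(ValueError):
            gen_expression_timecourse(
                SignalSpec((), 0.1), SignalSpec((), 1.0), -0.1, SimScenario()
            )

    def test_negative_signal_clipped_with_warning(self):
        spec = SignalSpec((ComponentSpec(2.0, 12.0),), 0.5)  # dips below zero
        with pytest.warns(UserWarning, match="clipping"):
            gen_expression_timecourse(spec, SignalSpec((), 1.0), 0.1, SimScenario())


class TestSpeckleImages:
    def test_nucleation_truth_is_analytic_disks(self):
        img = gen_speckle_image("nucleation", n_nuclei=1, seed=2)
        assert len(img.regions) > 0
        for r in img.regions:
            assert r.sphericity == 1.0

    def test_nucleation_labels_disjoint(self):
        img = gen_speckle_image("nucleation", n_nuclei=2, seed=3)
        # one label per true region, and labels partition the speckle pixels
        labels = set(np.unique(img.labels)) - {0}
        assert len(labels) == len(img.regions)

    def test_spinodal_contains_low_sphericity_network(self):
        img = gen_speckle_image("spinodal", n_nuclei=2, seed=4)
        assert min(r.sphericity for r in img.regions) < 0.6

    def test_spinodal_network_spans_nucleus(self):
        """At least one region's bounding box spans >= 30% of its nucleus."""
        img = gen_speckle_image("spinodal", n_nuclei=1, seed=5)
        nuc = img.nucleus_mask == 1
        ys, xs = np.nonzero(nuc)
        nuc_diam = max(ys.max() - ys.min(), xs.max() - xs.min())
        spans = []
        for lab in np.unique(img.labels):
            if lab == 0:
                continue
            ys, xs = np.nonzero(img.labels == lab)
            spans.append(max(ys.max() - ys.min(), xs.max() - xs.min()))
        assert max(spans) >= 0.3 * nuc_diam

    def test_seed_gives_bit_identical_images(self):
        a = gen_speckle_image("nucleation", n_nuclei=2, seed=9)
        b = gen_speckle_image("nucleation", n_nuclei=2, seed=9)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.labels, b.labels)

    def test_overcrowding_raises(self):
        with pytest.raises(RuntimeError):
            gen_speckle_image(
                "nucleation",
                n_nuclei=1,
                shape=(64, 64),
                speckles_per_nucleus=200,
                radius_range=(5.0, 8.0),
                seed=0,
                max_retries=500,
            )

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            gen_speckle_image("nucleation", shape=(32, 32))


class TestFrapTraces:
    def test_half_plateau_gain_at_half_life(self):
        """Single model with k = ln2/10: normalized gain at t=10 s is A/2."""
        k = math.log(2) / 10.0
        trace, truth = gen_frap_trace(
            "single", (k,), (0.6,), offset=0.2, frame_interval=1.0, n_frames=40
        )
        from chronospeckle.frap import normalize_frap

        norm = normalize_frap(trace)
        i10 = np.argmin(np.abs(norm.times - 10.0))
        assert norm.times[i10] == pytest.approx(10.0)
        assert norm.values[i10] - 0.2 == pytest.approx(0.3, rel=1e-9)
        assert truth.half_life == pytest.approx(10.0)

    def test_noiseless_recovery_is_monotone_to_plateau(self):
        trace, truth = gen_frap_trace("single", (0.1,), (0.5,), offset=0.2)
        from chronospeckle.frap import normalize_frap

        norm = normalize_frap(trace)
        assert (np.diff(norm.values) >= -1e-12).all()
        assert norm.values[-1] < 0.7  # approaches but never exceeds plateau

    def test_seed_reproducibility(self):
        a, _ = gen_frap_trace("single", noise_sd=0.05, seed=3)
        b, _ = gen_frap_trace("single", noise_sd=0.05, seed=3)
        assert np.array_equal(a.bleached, b.bleached)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            gen_frap_trace("single", (0.0,), (0.5,))
        with pytest.raises(ValueError):
            gen_frap_trace("triple")


class TestReadSet:
    def test_expected_counts_structure(self):
        genes = simulate.default_gene_models()
        _, expected = gen_read_set(genes, 5, 0, 0, 0, seed=1)
        for gid in expected:
            assert expected[gid] == {"exon": 5, "intron": 0}

    def test_junction_reads_counted_as_intron(self):
        genes = simulate.default_gene_models()
        reads, expected = gen_read_set(genes, 0, 3, 0, 0, seed=2)
        from chronospeckle.genomic import count_gene

        for gene in genes:
            counts = count_gene(reads, gene)
            assert counts.intron_reads == 3
            assert expected[gene.gene_id]["intron"] == 3

    def test_split_reads_counted_once_as_exon(self):
        genes = simulate.default_gene_models()
        reads, _ = gen_read_set(genes, 0, 0, 0, 2, seed=3)
        from chronospeckle.genomic import count_gene

        for gene in genes:
            counts = count_gene(reads, gene)
            assert counts.exon_reads == 2
            assert counts.intron_reads == 0

    def test_oversized_read_rejected(self):
        from chronospeckle.genomic import GeneModel

        tiny = [GeneModel("t", "chr1", "+", ((0, 30), (60, 90)))]
        with pytest.raises(ValueError):
            gen_read_set(tiny, 1, 0, 0, 0, read_len=50, seed=0)
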