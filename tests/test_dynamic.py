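"""Windowed circular correlation, the dFC recurrence matrix, and fluidity."""

import numpy as np
import pytest

from fluidconn.dynamic import (
    DFCMatrix,
    WindowSpec,
    circular_correlation,
    dfc_matrix,
    fc_stream,
    fluidity,
    n_windows,
)
from fluidconn.signals import BandSpec, PhaseMatrix, RegionTimeSeries, bandpass, instantaneous_phase
from fluidconn.synthetic import SimulationConfig, simulate_subject_signals

from oracles import ccor_direct, dfc_direct, fluidity_direct


def _phases(data, fs=100.0, **kw):
    return PhaseMatrix(phases=np.asarray(data), fs=fs, **kw)


class TestCircularCorrelation:
    def test_identical_phases(self, rng):
        p = rng.uniform(-np.pi, np.pi, 200)
        assert circular_correlation(p, p) == pytest.approx(1.0, abs=1e-12)

    def test_negated_phases(self, rng):
        p = rng.uniform(-np.pi, np.pi, 200)
        assert circular_correlation(p, -p) == pytest.approx(-1.0, abs=1e-12)

    def test_independent_phases_near_zero_and_match_oracle(self, rng):
        p = rng.uniform(-np.pi, np.pi, 1000)
        q = rng.uniform(-np.pi, np.pi, 1000)
        val = circular_correlation(p, q)
        assert abs(val) < 0.1
        assert val == pytest.approx(ccor_direct(p, q), abs=1e-12)

    def test_wrap_invariance(self, rng):
        """Adding 2*pi*k to phases must not change the statistic."""
        p = rng.uniform(-np.pi, np.pi, 300)
        q = rng.uniform(-np.pi, np.pi, 300)
        shifted = p + 2 * np.pi * rng.integers(-3, 4, size=300)
        assert circular_correlation(shifted, q) == pytest.approx(
            circular_correlation(p, q), abs=1e-10
        )

    def test_constant_phase_sentinel(self):
        p = np.zeros(50)
        q = np.linspace(-1, 1, 50)
        assert np.isnan(circular_correlation(p, q))

    def test_rejects_short_or_mismatched(self):
        with pytest.raises(ValueError):
            circular_correlation(np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError):
            circular_correlation(np.zeros(10), np.zeros(11))

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 100))
            p = rng.uniform(-np.pi, np.pi, n)
            q = rng.uniform(-np.pi, np.pi, n)
            assert circular_correlation(p, q) == pytest.approx(
                ccor_direct(p, q), abs=1e-12
            )


class TestWindowing:
    def test_window_count_seven_minutes_at_1khz(self):
        assert n_windows(420_000, 1000.0, WindowSpec(1.0, 0.1)) == 4191

    @pytest.mark.parametrize(
        "samples,fs,length,step,expected",
        [
            (1000, 100.0, 1.0, 0.5, 19),
            (1000, 100.0, 1.0, 1.0, 10),
            (99, 100.0, 1.0, 0.1, 0),
        ],
    )
    def test_window_count_arithmetic(self, samples, fs, length, step, expected):
        assert n_windows(samples, fs, WindowSpec(length, step)) == expected

    def test_invalid_window_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(1.0, 1.5)
        with pytest.raises(ValueError):
            WindowSpec(0.02, 0.01).in_samples(100.0)

    def test_stream_matches_pairwise_ccor(self, rng):
        phases = _phases(rng.uniform(-np.pi, np.pi, size=(4, 500)))
        stream = fc_stream(phases, WindowSpec(1.0, 0.5))
        length, step = WindowSpec(1.0, 0.5).in_samples(100.0)
        for w, start in enumerate(stream.window_starts):
            seg = phases.phases[:, start : start + length]
            for i in range(4):
                for j in range(i + 1, 4):
                    assert stream.matrices[w, i, j] == pytest.approx(
                        ccor_direct(seg[i], seg[j]), abs=1e-12
                    )
            assert np.allclose(stream.matrices[w], stream.matrices[w].T)
            assert np.allclose(np.diag(stream.matrices[w]), 1.0)

    def test_stationary_periodic_windows_identical(self):
        """Tones at odd-integer frequencies repeat exactly across 1 s steps."""
        fs = 100.0
        t = np.arange(int(10 * fs)) / fs
        data = np.vstack(
            [np.cos(2 * np.pi * f * t + th) for f, th in ((1, 0.0), (3, 1.0), (5, 2.0))]
        )
        phases = instantaneous_phase(RegionTimeSeries(data, fs=fs))
        stream = fc_stream(phases, WindowSpec(1.5, 1.0))
        ref = stream.matrices[1]
        for w in range(1, stream.n_windows - 1):  # interior (Hilbert edges)
            assert np.allclose(stream.matrices[w], ref, atol=1e-6)

    def test_degenerate_window_flagged(self):
        phases = np.vstack(
            [np.zeros(300), np.linspace(0, 20, 300), np.linspace(0, 10, 300)]
        )
        stream = fc_stream(_phases(phases), WindowSpec(1.0, 1.0))
        assert stream.flagged.all()  # constant-phase region degenerates every window

    def test_state_sequence_recovered_from_ccor_trace(self):
        """Window-wise CCor between two oscillators whose coupling alternates
        ON/OFF every 5 s classifies the known state sequence (transition
        windows excluded)."""
        fs, dwell, total_s = 100.0, 5.0, 60.0
        n, dt = int(total_s * fs), 1.0 / fs
        rng = np.random.default_rng(3)
        omega = 2 * np.pi * np.array([1.2, 1.6])
        coupling, alpha = 20.0, 0.5
        states = (np.arange(n) // int(dwell * fs)) % 2  # 0 = coupled, 1 = off
        phi = rng.uniform(-np.pi, np.pi, 2)
        phases = np.empty((2, n))
        for t in range(n):
            k = coupling if states[t] == 0 else 0.0
            step = omega + k * np.sin(phi[::-1] - phi - alpha)
            phi = phi + dt * step + rng.normal(0, 0.05, 2) * np.sqrt(dt)
            phases[:, t] = phi
        pm = PhaseMatrix(phases=np.mod(phases + np.pi, 2 * np.pi) - np.pi, fs=fs)
        spec = WindowSpec(1.0, 0.1)
        stream = fc_stream(pm, spec)
        length, _ = spec.in_samples(fs)
        clean = np.array(
            [np.all(states[s : s + length] == states[s])
             for s in stream.window_starts]
        )
        trace = stream.matrices[:, 0, 1]
        true = states[stream.window_starts]
        m_on = trace[clean & (true == 0)].mean()
        m_off = trace[clean & (true == 1)].mean()
        pred = np.where(trace > (m_on + m_off) / 2, 0, 1)
        assert np.mean(pred[clean] == true[clean]) >= 0.95


class TestDFC:
    def test_identical_windows_all_ones(self, rng):
        base = rng.uniform(-np.pi, np.pi, size=(5, 100))
        tiled = np.tile(base, (1, 5))
        stream = fc_stream(_phases(tiled), WindowSpec(1.0, 1.0))
        d = dfc_matrix(stream)
        assert np.allclose(d.values, 1.0, atol=1e-9)

    def test_alternating_two_patterns_block_structure(self, rng):
        a = rng.uniform(-np.pi, np.pi, size=(3, 100))
        b = rng.uniform(-np.pi, np.pi, size=(3, 100))
        seq = np.concatenate([a, b, a, b], axis=1)
        stream = fc_stream(_phases(seq), WindowSpec(1.0, 1.0))
        d = dfc_matrix(stream)
        oracle = dfc_direct(list(stream.matrices))
        assert np.allclose(d.values, oracle, atol=1e-12)
        assert d.values[0, 2] == pytest.approx(1.0, abs=1e-10)
        assert d.values[1, 3] == pytest.approx(1.0, abs=1e-10)
        assert d.values[0, 1] == pytest.approx(d.values[2, 3], abs=1e-10)

    def test_random_windows_match_bruteforce(self, rng):
        phases = _phases(rng.uniform(-np.pi, np.pi, size=(10, 1000)))
        stream = fc_stream(phases, WindowSpec(1.0, 1.0))
        d = dfc_matrix(stream)
        assert np.allclose(d.values, dfc_direct(list(stream.matrices)), atol=1e-10)

    def test_zero_variance_window_excluded(self, rng):
        good = rng.uniform(-np.pi, np.pi, size=(3, 300))
        stream = fc_stream(_phases(good), WindowSpec(1.0, 1.0))
        stream.matrices[1] = np.ones_like(stream.matrices[1])  # constant pattern
        d = dfc_matrix(stream)
        assert 1 not in d.window_indices
        assert d.values.shape == (2, 2)


class TestFluidity:
    def test_constant_dfc_zero(self):
        d = DFCMatrix(values=np.ones((4, 4)), window_indices=np.arange(4))
        assert fluidity(d).value == 0.0

    def test_matches_direct_variance(self, rng):
        vals = rng.uniform(-1, 1, size=(6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        d = DFCMatrix(values=vals, window_indices=np.arange(6))
        assert fluidity(d).value == pytest.approx(fluidity_direct(vals), abs=1e-12)

    def test_extreme_upper_triangle(self):
        """Upper-triangle values of +/-1 in equal numbers give variance 1."""
        vals = np.array(
            [[1.0, 1.0, 1.0, -1.0],
             [1.0, 1.0, -1.0, 1.0],
             [1.0, -1.0, 1.0, -1.0],
             [-1.0, 1.0, -1.0, 1.0]]
        )
        d = DFCMatrix(values=vals, window_indices=np.arange(4))
        assert fluidity(d).value == pytest.approx(1.0, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            vals = rng.uniform(-1, 1, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 1.0)
            f = fluidity(DFCMatrix(values=vals, window_indices=np.arange(n))).value
            assert 0.0 <= f <= 1.0

    def test_region_permutation_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(8, 800))
        f1 = fluidity(dfc_matrix(fc_stream(_phases(phases), WindowSpec(1.0, 0.5)))).value
        perm = rng.permutation(8)
        f2 = fluidity(
            dfc_matrix(fc_stream(_phases(phases[perm]), WindowSpec(1.0, 0.5)))
        ).value
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_time_reversal_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(6, 600))
        stream = fc_stream(_phases(phases), WindowSpec(1.0, 1.0))
        forward = fluidity(dfc_matrix(stream)).value
        rev = stream.matrices[::-1].copy()
        stream.matrices = rev
        backward = fluidity(dfc_matrix(stream)).value
        assert forward == pytest.approx(backward, abs=1e-12)

    def test_metastable_exceeds_stationary(self):
        band = BandSpec("delta", 0.1, 4.0)

        def mean_fluidity(n_states, seeds):
            vals = []
            for seed in seeds:
                cfg = SimulationConfig(
                    n_regions=10, fs=128.0, duration=20.0, bands=(band,),
                    n_states=n_states, dwell_mean=3.0, coupling_strength=0.8,
                    noise_sd=0.3, seed=seed,
                )
                ts = simulate_subject_signals(cfg, "HC")
                ph = instantaneous_phase(bandpass(ts, band))
                vals.append(fluidity(dfc_matrix(fc_stream(ph, WindowSpec(1.0, 0.1)))).value)
            return np.mean(vals)

        seeds = range(20)
        assert mean_fluidity(3, seeds) > mean_fluidity(1, seeds)
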