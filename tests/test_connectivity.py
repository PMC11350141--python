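"""Connectivity graphs: correlation windows, surrogate thresholding,
degree metrics (with brute-force oracle), Fisher averaging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogvasc import connectivity as conn
from cogvasc.io import make_task_design


@pytest.fixture(scope="module")
def design():
    return make_task_design(seed=0)


class TestBlockCorrelation:
    def test_identical_channels_give_r_one(self, design, rng):
        x = rng.standard_normal(1600)
        hbt = np.vstack([x, x, rng.standard_normal(1600)])
        r = conn.block_correlation(hbt, design, "1b", 3.9)
        assert r[0, 0] == pytest.approx(1.0)
        assert r[0, 1] == pytest.approx(1.0)

    def test_independent_channels_null_distribution(self, design):
        """White-noise pairs: mean r ~ 0, SD ~ 1/sqrt(n-1)."""
        n_block = int(round(72.0 * 3.9))
        rs = []
        for s in range(300):
            x = np.random.default_rng(s).standard_normal((2, 1600))
            rs.append(conn.block_correlation(x, design, "0b_1", 3.9)[0, 1])
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 3.0 / np.sqrt(len(rs) * (n_block - 1))
        assert rs.std() == pytest.approx(1.0 / np.sqrt(n_block - 1), rel=0.15)

    def test_block_beyond_record_rejected(self, design, rng):
        with pytest.raises(ValueError, match="beyond the record"):
            conn.block_correlation(rng.standard_normal((2, 100)), design, "2b", 3.9)


class TestSurrogateThreshold:
    def test_negative_r_always_zeroed(self, rng):
        x = rng.standard_normal((2, 281))
        r = np.array([[1.0, -0.9], [-0.9, 1.0]])
        out = conn.surrogate_threshold(r, x, seed=0)
        assert out[0, 1] == 0.0

    def test_perfectly_coupled_channels_retained(self, rng):
        x = np.cumsum(rng.standard_normal(281))
        hbt = np.vstack([x, x + 1e-6 * rng.standard_normal(281)])
        r = np.corrcoef(hbt)
        out = conn.surrogate_threshold(r, hbt, seed=1)
        assert out[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_insufficient_surrogates_rejected(self, rng):
        x = rng.standard_normal((2, 100))
        with pytest.raises(ValueError, match="n_surr"):
            conn.surrogate_threshold(np.eye(2), x, alpha=0.05, n_surr=10)

    def test_parametric_alternative(self, rng):
        x = rng.standard_normal((3, 281))
        r = np.corrcoef(x)
        out = conn.surrogate_threshold(r, x, method="parametric")
        assert out.shape == (3, 3)
        assert (np.diag(out) == 0).all()

    def test_calibration_under_independence(self):
        """Retained-edge fraction ~ alpha for independent band-limited
        channels when shifts are drawn over the full session."""
        from scipy import signal as sig

        sos = sig.butter(4, 0.4, btype="low", fs=3.9, output="sos")
        w0, n = 400, 281
        fracs = []
        for s in range(60):
            noise = np.random.default_rng(s).standard_normal((6, 1500))
            x = sig.sosfiltfilt(sos, noise, axis=-1)
            seg = x[:, w0:w0 + n]
            r = np.corrcoef(seg)
            out = conn.surrogate_threshold(
                r, seg, seed=s, full_series=x, window_start=w0
            )
            iu = np.triu_indices(6, 1)
            fracs.append((out[iu] > 0).mean())
        assert 0.02 < np.mean(fracs) < 0.08


def brute_force_metrics(r_star, ldl_idx):
    """Independent enumeration of the degree/strength metrics."""
    n = r_star.shape[0]
    deg = [sum(1 for j in range(n) if j != i and r_star[i, j] > 0)
           for i in range(n)]
    stren = [sum(r_star[i, j] for j in range(n) if j != i) for i in range(n)]
    max_w = max((r_star[i, j] for i in range(n) for j in range(n) if i != j),
                default=0.0)
    norm_deg = [d / (n - 1) for d in deg]
    denom = (n - 1) * max_w if max_w > 0 else 1.0
    norm_str = [s / denom for s in stren]
    d_bar = sum(norm_deg) / n
    wd_bar = sum(norm_str) / n
    d_ldp = sum(norm_deg[i] for i in ldl_idx) / len(ldl_idx) if ldl_idx else 0.0
    wd_ldp = sum(norm_str[i] for i in ldl_idx) / len(ldl_idx) if ldl_idx else 0.0
    return deg, stren, d_bar, wd_bar, d_ldp, wd_ldp


class TestGraphMetrics:
    def test_complete_graph_normalizes_to_one(self):
        n = 5
        A = np.full((n, n), 0.4)
        np.fill_diagonal(A, 0.0)
        m = conn.graph_metrics(A, tuple(f"c{i}" for i in range(n)), ("c0",))
        assert m.d_bar == pytest.approx(1.0)
        assert m.wd_bar == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        m = conn.graph_metrics(np.zeros((4, 4)),
                               ("a", "b", "c", "d"), ("a",))
        assert m.d_bar == m.wd_bar == m.d_ldp == m.wd_ldp == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError, match="2 nodes"):
            conn.graph_metrics(np.zeros((1, 1)), ("a",))

    def test_hand_enumerated_example(self):
        """4 nodes, edges {(0,1): 0.5, (1,2): 0.25}."""
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.5
        A[1, 2] = A[2, 1] = 0.25
        m = conn.graph_metrics(A, ("a", "b", "c", "d"), ("a",))
        assert list(m.degree) == [1, 2, 1, 0]
        assert m.d_bar == pytest.approx((1 / 3 + 2 / 3 + 1 / 3 + 0) / 4)
        # strengths (0.5, 0.75, 0.25, 0) / (3 * 0.5)
        assert m.wd_bar == pytest.approx((0.5 + 0.75 + 0.25 + 0) / 1.5 / 4)
        assert m.d_ldp == pytest.approx(1 / 3)

    def test_exhaustive_small_graphs_match_brute_force(self):
        """All edge subsets of K4 (and a weighted K5 sample) match the
        independent enumeration."""
        weights = [0.3, 0.55, 0.8]
        pairs4 = list(itertools.combinations(range(4), 2))
        for mask in range(2 ** len(pairs4)):
            A = np.zeros((4, 4))
            for b, (i, j) in enumerate(pairs4):
                if mask >> b & 1:
                    w = weights[(i + j) % 3]
                    A[i, j] = A[j, i] = w
            m = conn.graph_metrics(A, ("a", "b", "c", "d"), ("a", "b"))
            deg, stren, d_bar, wd_bar, d_ldp, wd_ldp = brute_force_metrics(
                A, [0, 1]
            )
            assert list(m.degree) == deg
            np.testing.assert_allclose(m.strength, stren)
            assert m.d_bar == pytest.approx(d_bar)
            assert m.wd_bar == pytest.approx(wd_bar)
            assert m.d_ldp == pytest.approx(d_ldp)
            assert m.wd_ldp == pytest.approx(wd_ldp)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**15 - 1),
           st.integers(min_value=0, max_value=10**6))
    def test_random_graphs_bounded_and_match_oracle(self, mask, wseed):
        """Property: every normalized metric lies in [0, 1] and matches the
        brute-force oracle, for random graphs on 6 nodes."""
        n = 6
        pairs = list(itertools.combinations(range(n), 2))
        rng = np.random.default_rng(wseed)
        A = np.zeros((n, n))
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                A[i, j] = A[j, i] = rng.uniform(0.05, 1.0)
        labels = tuple(f"c{i}" for i in range(n))
        m = conn.graph_metrics(A, labels, ("c0", "c1", "c2"))
        for v in (m.d_bar, m.wd_bar, m.d_ldp, m.wd_ldp):
            assert 0.0 <= v <= 1.0
        _, _, d_bar, wd_bar, d_ldp, wd_ldp = brute_force_metrics(A, [0, 1, 2])
        assert m.d_bar == pytest.approx(d_bar)
        assert m.wd_bar == pytest.approx(wd_bar)
        assert m.wd_ldp == pytest.approx(wd_ldp)

    def test_possible_normalization_variant(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 0.5
        m = conn.graph_metrics(A, ("a", "b", "c"), ("a",),
                               weighted_normalization="possible")
        assert m.wd_bar == pytest.approx((0.25 + 0.25 + 0.0) / 3)


class TestAveraging:
    def test_task_average_of_constants(self):
        vals = {"0b_1": {"d_bar": 0.4}, "2b": {"d_bar": 0.4}}
        assert conn.task_average(vals)["d_bar"] == pytest.approx(0.4)

    def test_task_average_arithmetic(self):
        vals = {c: {"m": v} for c, v in
                zip(("0b_1", "0b_2", "1b", "2b"), (0.2, 0.4, 0.6, 0.8))}
        assert conn.task_average(vals)["m"] == pytest.approx(0.5)

    def test_task_average_available_mean(self):
        vals = {"0b_1": {"m": 0.2}, "1b": {"m": 0.6}}
        assert conn.task_average(vals)["m"] == pytest.approx(0.4)

    def test_fisher_average_identity_cases(self):
        z, r = conn.fisher_average([np.zeros((3, 3))] * 4)
        np.testing.assert_allclose(r, 0.0)
        mats = [np.full((2, 2), 0.5) for _ in range(3)]
        _, r = conn.fisher_average(mats)
        np.testing.assert_allclose(r, 0.5, atol=1e-12)

    def test_fisher_average_is_not_arithmetic_mean(self):
        a = np.array([[0.0, 0.3], [0.3, 0.0]])
        b = np.array([[0.0, 0.9], [0.9, 0.0]])
        _, r = conn.fisher_average([a, b])
        expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.9)) / 2.0)
        assert r[0, 1] == pytest.approx(expected)
        assert r[0, 1] != pytest.approx(0.6, abs=0.01)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            conn.fisher_average([np.zeros((2, 2)), np.zeros((3, 3))])


class TestMonotoneCoupling:
    def test_wd_bar_increases_with_planted_coupling(self, design):
        """Group-mean normalized strength is strictly ordered in the
        planted mixing weight."""
        from cogvasc.simulate import SimConfig, simulate_cohort, \
            simulate_fnirs_session
        from cogvasc import preprocess as pre

        from conftest import noiseless_config

        means = []
        for w in (0.0, 0.3, 0.6, 0.9):
            cfg = noiseless_config()
            cfg.fc_signal_amp = 0.2
            cfg.noise = dict(cfg.noise, white_sd=0.01)
            cfg.fc_coupling = {(g, r): w for g in ("CN", "MCI")
                               for r in ("LDLPFC", "other", "reference")}
            for key in cfg.hrf_amplitude:
                cfg.hrf_amplitude[key] = {
                    c: 0.0 for c in cfg.hrf_amplitude[key]}
            cfg.montage = cfg.montage.subset(
                ["F3-F5", "F3-F1", "F3-FC3", "F4-F6", "F4-F2", "Fz-F1"])
            cohort = simulate_cohort(cfg)
            vals = []
            for s in range(10):
                rec = simulate_fnirs_session(
                    cohort.iloc[0], design, cfg, seed=700 + s)
                fc = pre.fc_preprocess(rec)
                _, _, avg = conn.subject_connectivity(
                    fc, design, cfg.montage, seed=s)
                vals.append(avg["wd_bar"])
            means.append(np.mean(vals))
        assert means == sorted(means)
        assert means[-1] - means[0] > 0.2
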