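import math
import warnings
from itertools import permutations

import numpy as np
import pytest
from scipy.signal import hilbert

from addnet.fc_measures import (
    FCMatrix,
    OrdinalPatternConfig,
    aec,
    fc_matrix,
    jpe,
    pli,
    plt,
    roi_means,
    symbolize,
    whole_brain_mean,
)
from addnet.spectral import FC_BANDS, bandpass, edge_trim_slice

FS = 500.0


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the implementation
# ---------------------------------------------------------------------------

def oracle_pli(px, py):
    total = 0.0
    for a, b in zip(px, py):
        s = math.sin(a - b)
        total += (s > 0) - (s < 0)
    return abs(total / len(px))


def oracle_plt(px, py, fs):
    signs = []
    for a, b in zip(px, py):
        s = math.sin(a - b)
        signs.append((s > 0) - (s < 0))
    nonzero = [s for s in signs if s != 0]
    if not nonzero:
        return 0.0
    changes = sum(1 for u, v in zip(nonzero[:-1], nonzero[1:]) if u != v)
    t_mean = (len(signs) / fs) / (changes + 1)
    return 1.0 - math.exp(-t_mean)


def oracle_symbol(window):
    # rank from highest (1) to lowest (n); earlier sample wins ties
    order = sorted(range(len(window)), key=lambda i: (-window[i], i))
    return tuple(order)


def oracle_jpe(x, y, n=4, tau=1):
    perms = list(permutations(range(n)))
    span = (n - 1) * tau
    pairs = {}
    kept = 0
    for t in range(len(x) - span):
        sx = oracle_symbol([x[t + k * tau] for k in range(n)])
        sy = oracle_symbol([y[t + k * tau] for k in range(n)])
        if sy == sx or sy == sx[::-1]:
            continue
        pairs[(sx, sy)] = pairs.get((sx, sy), 0) + 1
        kept += 1
    if kept == 0:
        return 1.0
    h = -sum((c / kept) * math.log(c / kept) for c in pairs.values())
    return 1.0 - h / math.log((math.factorial(n) - 1) ** 2)


def oracle_aec(x, y, corrected):
    def corr(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float((u @ v) / math.sqrt((u @ u) * (v @ v)))

    tr = edge_trim_slice(len(x))
    if not corrected:
        return corr(np.abs(hilbert(x))[tr], np.abs(hilbert(y))[tr])
    vals = []
    for a, b in ((x, y), (y, x)):
        resid = b - (np.dot(a, b) / np.dot(a, a)) * a
        env_r = np.abs(hilbert(resid))[tr]
        if env_r.max() < 1e-10 * np.abs(hilbert(b))[tr].max():
            vals.append(0.0)
        else:
            vals.append(corr(np.abs(hilbert(a))[tr], env_r))
    return float(np.mean(vals))


@pytest.fixture()
def filtered_pair(rng):
    x = bandpass(rng.standard_normal(1024), FC_BANDS["alpha"], FS)
    y = bandpass(rng.standard_normal(1024), FC_BANDS["alpha"], FS)
    return x, y


class TestPLI:
    def test_constant_lag(self):
        ph = np.linspace(0, 40 * np.pi, 2048)
        assert pli(ph + np.pi / 2, ph) == 1.0

    def test_identical_phases_zero(self):
        ph = np.linspace(0, 40 * np.pi, 2048)
        assert pli(ph, ph) == 0.0

    def test_independent_phases_near_zero(self):
        vals = [
            pli(
                np.random.default_rng(2 * s).uniform(-np.pi, np.pi, 4096),
                np.random.default_rng(2 * s + 1).uniform(-np.pi, np.pi, 4096),
            )
            for s in range(30)
        ]
        assert np.mean(vals) < 3 / math.sqrt(4096)

    def test_matches_oracle_exactly(self, rng):
        px = rng.uniform(-np.pi, np.pi, 1024)
        py = rng.uniform(-np.pi, np.pi, 1024)
        assert pli(px, py) == pytest.approx(oracle_pli(px, py), abs=1e-14)

    def test_swap_symmetric(self, rng):
        px = rng.uniform(-np.pi, np.pi, 512)
        py = rng.uniform(-np.pi, np.pi, 512)
        assert pli(px, py) == pli(py, px)


class TestPLT:
    def test_identical_zero(self):
        ph = np.linspace(0, 40 * np.pi, 4096)
        assert plt(ph, ph, FS) == 0.0

    def test_constant_lag_full_epoch(self):
        ph = np.linspace(0, 40 * np.pi, 4096)
        expected = 1 - math.exp(-4096 / FS)
        assert plt(ph + np.pi / 4, ph, FS) == pytest.approx(expected)
        assert plt(ph + np.pi / 4, ph, FS) == pytest.approx(0.99972, abs=2e-4)

    def test_alternating_every_sample(self):
        n = 4096
        dphi = np.where(np.arange(n) % 2 == 0, 0.3, -0.3)
        expected = 1 - math.exp(-1 / FS)
        assert plt(dphi, np.zeros(n), FS) == pytest.approx(expected)
        assert expected == pytest.approx(0.001998, abs=1e-5)

    def test_matches_oracle(self, rng):
        for _ in range(10):
            px = rng.uniform(-np.pi, np.pi, 1024)
            py = rng.uniform(-np.pi, np.pi, 1024)
            assert plt(px, py, FS) == pytest.approx(oracle_plt(px, py, FS), abs=1e-12)

    def test_depends_only_on_sign_change_times(self, rng):
        # scaling the magnitude of the phase difference leaves PLT unchanged
        dphi = rng.uniform(-1.0, 1.0, 2048)
        z = np.zeros(2048)
        assert plt(dphi, z, FS) == plt(0.5 * dphi, z, FS)

    def test_swap_symmetric(self, rng):
        px = rng.uniform(-np.pi, np.pi, 512)
        py = rng.uniform(-np.pi, np.pi, 512)
        assert plt(px, py, FS) == plt(py, px, FS)

    def test_complete_interval_convention(self):
        # one sign change at the middle: truncated counts 2 intervals,
        # complete has none and falls back to the full window
        dphi = np.concatenate([np.full(512, 0.5), np.full(512, -0.5)])
        z = np.zeros(1024)
        assert plt(dphi, z, FS, boundary="truncated") == pytest.approx(
            1 - math.exp(-1024 / FS / 2)
        )
        assert plt(dphi, z, FS, boundary="complete") == pytest.approx(
            1 - math.exp(-1024 / FS)
        )


class TestSymbolize:
    def test_oracle_agreement(self, rng):
        cfg = OrdinalPatternConfig()
        x = rng.standard_normal(200)
        codes = symbolize(x, cfg)
        perms = list(permutations(range(4)))
        for t in range(len(codes)):
            assert perms[codes[t]] == oracle_symbol(list(x[t : t + 4]))

    def test_tau_2(self, rng):
        cfg = OrdinalPatternConfig(n=3, tau=2)
        x = rng.standard_normal(50)
        codes = symbolize(x, cfg)
        assert len(codes) == 50 - 4
        perms = list(permutations(range(3)))
        assert perms[codes[0]] == oracle_symbol([x[0], x[2], x[4]])

    def test_tie_break_earlier_ranks_higher(self):
        codes = symbolize(np.array([1.0, 1.0, 0.0, 2.0, 5.0]), OrdinalPatternConfig())
        perms = list(permutations(range(4)))
        assert perms[codes[0]] == (3, 0, 1, 2)  # sample 3 highest, tie 0 before 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            symbolize(np.zeros(4), OrdinalPatternConfig())


class TestJPE:
    def test_normalization_constant(self):
        cfg = OrdinalPatternConfig(n=4)
        assert cfg.max_entropy == pytest.approx(math.log(529))
        assert math.factorial(4) ** 2 - 2 * math.factorial(4) + 1 == 529

    def test_independent_noise_near_zero(self, rng):
        vals = [
            jpe(
                np.random.default_rng(100 + 2 * s).standard_normal(4096),
                np.random.default_rng(101 + 2 * s).standard_normal(4096),
            )
            for s in range(5)
        ]
        assert max(vals) < 0.05

    def test_lagged_copy_exceeds_independent(self, rng):
        x = rng.standard_normal(4096)
        y_ind = rng.standard_normal(4096)
        lagged = np.roll(x, 1)
        assert jpe(x, lagged) > jpe(x, y_ind)

    def test_matches_oracle(self, rng):
        x = rng.standard_normal(300)
        y = 0.6 * x + 0.8 * rng.standard_normal(300)
        assert jpe(x, y) == pytest.approx(oracle_jpe(list(x), list(y)), abs=1e-12)

    def test_degenerate_identical_inputs(self, rng):
        x = rng.standard_normal(256)
        with pytest.warns(UserWarning, match="degenerate"):
            assert jpe(x, x) == 1.0

    def test_literal_variant_sign(self, rng):
        x = rng.standard_normal(512)
        y = rng.standard_normal(512)
        assert jpe(x, y, literal=True) == pytest.approx(jpe(x, y) - 1.0)

    def test_swap_symmetric(self, rng):
        x = rng.standard_normal(512)
        y = rng.standard_normal(512)
        assert jpe(x, y) == pytest.approx(jpe(y, x), abs=1e-12)


class TestAEC:
    def test_self_correlation_one(self, filtered_pair):
        x, _ = filtered_pair
        assert aec(x, x) == pytest.approx(1.0)

    def test_scaled_copy_corrected_zero(self, filtered_pair):
        x, _ = filtered_pair
        assert aec(x, 0.5 * x, corrected=True) == 0.0

    def test_independent_noise_null_band(self):
        vals = []
        for s in range(20):
            r = np.random.default_rng(500 + s)
            x = bandpass(r.standard_normal(4096), FC_BANDS["alpha"], FS)
            y = bandpass(r.standard_normal(4096), FC_BANDS["alpha"], FS)
            vals.append(aec(x, y, corrected=True))
        assert abs(np.mean(vals)) < 3 / math.sqrt(4096)

    def test_matches_oracle(self, filtered_pair):
        x, y = filtered_pair
        for corrected in (False, True):
            assert aec(x, y, corrected=corrected) == pytest.approx(
                oracle_aec(x, y, corrected), abs=1e-12
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            aec(np.ones(512), np.ones(512))


class TestVolumeConductionNull:
    def test_affine_copy_invisible_to_all(self, rng):
        x = bandpass(rng.standard_normal(2048), FC_BANDS["theta"], FS)
        y = 2.0 * x  # alpha > 0 scaling
        from addnet.spectral import analytic

        pa, pb = analytic(x).phase, analytic(y).phase
        assert pli(pa, pb) == 0.0
        assert plt(pa, pb, FS) == 0.0
        assert aec(x, y, corrected=True) == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert jpe(x, y) == 1.0


class TestCouplingMonotonicity:
    def test_pli_plt_jpe_increase_with_coupling(self):
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        curves = {"PLI": [], "PLT": [], "JPE": []}
        from addnet.spectral import analytic

        for c in levels:
            acc = {k: [] for k in curves}
            for s in range(8):
                r = np.random.default_rng(900 + s)
                base = r.standard_normal(2100)
                noise = r.standard_normal(2100)
                x = bandpass(base[:2048], FC_BANDS["alpha"], FS)
                ylag = c * np.roll(base, 3)[:2048] + (1 - c) * noise[:2048]
                y = bandpass(ylag, FC_BANDS["alpha"], FS)
                pa, pb = analytic(x).phase, analytic(y).phase
                acc["PLI"].append(pli(pa, pb))
                acc["PLT"].append(plt(pa, pb, FS))
                acc["JPE"].append(jpe(x, y))
            for k in curves:
                curves[k].append(np.mean(acc[k]))
        for k, vals in curves.items():
            assert vals[-1] > vals[0], k
            # non-decreasing within Monte-Carlo tolerance
            assert all(b >= a - 0.02 for a, b in zip(vals, vals[1:])), (k, vals)


class TestFCMatrix:
    def test_three_channels_mirrored(self, rng):
        sig = rng.standard_normal((1024, 3))
        m = fc_matrix(sig, "PLI", FC_BANDS["theta"], FS)
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_permutation_equivariance(self, rng):
        sig = rng.standard_normal((1024, 4))
        perm = [2, 0, 3, 1]
        a = fc_matrix(sig, "PLT", FC_BANDS["alpha"], FS).values
        b = fc_matrix(sig[:, perm], "PLT", FC_BANDS["alpha"], FS).values
        assert np.allclose(a[np.ix_(perm, perm)], b, atol=1e-12)

    @pytest.mark.parametrize("measure", ["AEC", "AECc", "PLI", "PLT", "JPE"])
    def test_matches_looped_pairwise_oracle(self, rng, measure):
        from addnet.spectral import analytic

        sig = rng.standard_normal((1024, 5))
        band = FC_BANDS["theta"]
        m = fc_matrix(sig, measure, band, FS).values
        xf = bandpass(sig, band, FS)
        tr = edge_trim_slice(1024)
        for i in range(5):
            for j in range(i + 1, 5):
                if measure in ("PLI", "PLT"):
                    pa = analytic(xf[:, i]).phase[tr]
                    pb = analytic(xf[:, j]).phase[tr]
                    exp = pli(pa, pb) if measure == "PLI" else plt(pa, pb, FS)
                elif measure == "JPE":
                    exp = jpe(xf[:, i], xf[:, j])
                else:
                    exp = aec(xf[:, i], xf[:, j], corrected=measure == "AECc")
                assert m[i, j] == pytest.approx(exp, abs=1e-10), (measure, i, j)

    def test_range_invariants(self, rng):
        sig = rng.standard_normal((1024, 4))
        for measure in ("PLI", "PLT", "JPE"):
            v = fc_matrix(sig, measure, FC_BANDS["alpha"], FS).values
            assert (v >= 0).all() and (v <= 1).all()
        v = fc_matrix(sig, "AECc", FC_BANDS["alpha"], FS).values
        assert (v >= -1).all() and (v <= 1).all()

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            FCMatrix("PLI", FC_BANDS["theta"], np.array([[0, 1.0], [0.5, 0]]))

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            fc_matrix(rng.standard_normal((1024, 1)), "PLI", FC_BANDS["theta"], FS)


class TestROISummaries:
    def test_constant_matrix(self):
        v = np.full((4, 4), 0.7)
        np.fill_diagonal(v, 0)
        m = FCMatrix("PLI", FC_BANDS["theta"], v)
        assert np.allclose(roi_means(m), 0.7)
        assert whole_brain_mean(m) == pytest.approx(0.7)

    def test_three_by_three_pairs(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.2
        v[0, 2] = v[2, 0] = 0.4
        v[1, 2] = v[2, 1] = 0.6
        m = FCMatrix("PLI", FC_BANDS["theta"], v)
        assert whole_brain_mean(m) == pytest.approx(0.4)

    def test_roi_means_average_to_whole_brain(self, rng):
        v = rng.uniform(0, 1, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = FCMatrix("PLT", FC_BANDS["theta"], v)
        assert roi_means(m).mean() == pytest.approx(whole_brain_mean(m))
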