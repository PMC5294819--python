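"""The 178-value feature bank: registry structure, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from accelhar.features import (
    FOURIER_PREFIX,
    HIST_PREFIX,
    N_FEATURES,
    build_dataset,
    extract_features,
    feature_names,
)
from conftest import make_clip, random_clip

NAMES = feature_names()
IDX = {n: i for i, n in enumerate(NAMES)}


def brute_force_dft_magnitudes(x: np.ndarray, k: int) -> np.ndarray:
    """O(N^2) DFT magnitude oracle, independent of any FFT library."""
    n = x.size
    out = np.empty(k)
    for j in range(k):
        re = sum(x[m] * np.cos(-2.0 * np.pi * j * m / n) for m in range(n))
        im = sum(x[m] * np.sin(-2.0 * np.pi * j * m / n) for m in range(n))
        out[j] = np.hypot(re, im)
    return out


class TestRegistry:
    def test_length_and_uniqueness(self):
        assert len(NAMES) == 178
        assert len(set(NAMES)) == 178

    def test_group_sizes_match_feature_bank_layout(self):
        def count(pred):
            return sum(pred(n) for n in NAMES)

        assert count(lambda n: n.startswith("mean_") and n != "mean_accel_magnitude") == 3
        assert count(lambda n: n.startswith("absmean_")) == 3
        assert count(lambda n: n.startswith(("std_", "skew_", "kurt_"))) == 9 + 12
        assert count(lambda n: n.startswith("rms_") and "smooth" not in n) == 3
        assert count(lambda n: "smooth" in n) == 6
        assert count(lambda n: n.startswith(("min_", "max_", "absmin_", "absmax_"))) == 12
        assert count(lambda n: n.startswith(HIST_PREFIX)) == 27
        assert count(lambda n: n.startswith(FOURIER_PREFIX)) == 96
        assert count(lambda n: n.startswith("crossmean_")) == 3
        assert count(lambda n: n.startswith("abs_crossmean_")) == 3
        assert "mean_accel_magnitude" in NAMES


class TestDegenerateClips:
    def test_all_zero_clip(self):
        fv = extract_features(make_clip(np.zeros((3, 1000)))).as_dict()
        for axis in "xyz":
            assert fv[f"mean_{axis}"] == 0
            assert fv[f"std_{axis}"] == 0
            assert fv[f"skew_{axis}"] == 0
            assert fv[f"kurt_{axis}"] == 0
            assert fv[f"rms_{axis}"] == 0
            assert fv[f"min_{axis}"] == fv[f"max_{axis}"] == 0
            assert fv[f"{HIST_PREFIX}{axis}_0"] == 1000
            hist = [v for k, v in fv.items() if k.startswith(f"{HIST_PREFIX}{axis}_")]
            assert sum(hist) == 1000
        assert all(v == 0 for k, v in fv.items() if k.startswith(FOURIER_PREFIX))
        assert fv["mean_accel_magnitude"] == 0
        assert all(fv[f"crossmean_{s}"] == 0 for s in ("xy", "xz", "yz"))

    def test_constant_clip(self):
        data = np.zeros((3, 1000))
        data[0] = 1.0
        fv = extract_features(make_clip(data)).as_dict()
        assert fv["mean_x"] == fv["absmean_x"] == 1.0
        assert fv["rms_x"] == pytest.approx(1.0)
        assert fv["rms_smooth5_x"] == pytest.approx(1.0)
        assert fv["rms_smooth10_x"] == pytest.approx(1.0)
        assert fv["min_x"] == fv["max_x"] == 1.0
        assert fv["std_x"] == 0.0
        assert fv["mean_accel_magnitude"] == pytest.approx(1.0)
        assert all(fv[f"crossmean_{s}"] == 0 for s in ("xy", "xz", "yz"))

    def test_short_clip_rejected(self):
        with pytest.raises(ValueError, match="32"):
            extract_features(make_clip(np.zeros((3, 20))))

    def test_non_finite_rejected(self):
        data = np.zeros((3, 100))
        data[1, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            extract_features(make_clip(data))


class TestSinusoidClip:
    def setup_method(self):
        t = np.arange(1000) / 100.0
        data = np.zeros((3, 1000))
        data[0] = np.sin(2.0 * np.pi * 2.0 * t)
        self.fv = extract_features(make_clip(data)).as_dict()
        self.x = data[0]

    def test_rms_matches_closed_form(self):
        # exactly 20 full periods on the grid -> RMS = 1/sqrt(2)
        assert self.fv["rms_x"] == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_dominant_fourier_bin(self):
        # 2 Hz on a 0.1 Hz grid -> coefficient index 20
        mags = [self.fv[f"{FOURIER_PREFIX}x_{k:02d}"] for k in range(32)]
        assert int(np.argmax(mags)) == 20
        assert mags[20] == pytest.approx(500.0, rel=1e-9)

    def test_histogram_symmetry(self):
        for b in range(1, 5):
            lo = self.fv[f"{HIST_PREFIX}x_{-b}"]
            hi = self.fv[f"{HIST_PREFIX}x_{b}"]
            assert abs(lo - hi) <= 1


class TestOracles:
    def test_fourier_block_matches_brute_force_dft(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            clip = random_clip(rng, n=32)
            fv = extract_features(clip)
            for ai, axis in enumerate("xyz"):
                expected = brute_force_dft_magnitudes(clip.data[ai], 32)
                got = np.array([fv.values[IDX[f"{FOURIER_PREFIX}{axis}_{k:02d}"]] for k in range(32)])
                assert np.allclose(got, expected, rtol=1e-9, atol=1e-9)

    def test_histogram_counts_conserve_sample_total(self):
        rng = np.random.default_rng(10)
        for i in range(1000):
            n = int(rng.integers(32, 200))
            fv = extract_features(random_clip(rng, n=n, scale=rng.uniform(0.01, 3.0)))
            for axis in "xyz":
                counts = [fv.values[IDX[f"{HIST_PREFIX}{axis}_{b}"]] for b in range(-4, 5)]
                assert sum(counts) == n
                assert all(c >= 0 and float(c).is_integer() for c in counts)

    def test_population_moment_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(50)   :
            fv = extract_features(random_clip(rng, n=500)).as_dict()
            for axis in "xyz":
                lhs = fv[f"std_{axis}"] ** 2 + fv[f"mean_{axis}"] ** 2
                assert lhs == pytest.approx(fv[f"rms_{axis}"] ** 2, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(c=st.floats(min_value=0.05, max_value=20.0), seed=st.integers(0, 2**16))
    def test_affine_response(self, c, seed):
        clip = random_clip(np.random.default_rng(seed), n=200)
        base = extract_features(clip).as_dict()
        scaled = extract_features(make_clip(c * clip.data)).as_dict()
        for name in NAMES:
            if name.startswith(("skew", "kurt", HIST_PREFIX)):
                assert scaled[name] == pytest.approx(base[name], rel=1e-6, abs=1e-9)
            elif name.startswith(("crossmean_", "abs_crossmean_")) or name.startswith("std_") and name.split("_")[1] in ("xy", "xz", "yz"):
                pass  # quadratic features checked below
            elif name.startswith(("mean_", "absmean_", "std_", "rms_", "min_", "max_", "absmin_", "absmax_", FOURIER_PREFIX)):
                assert scaled[name] == pytest.approx(c * base[name], rel=1e-9, abs=1e-12)
        for s in ("xy", "xz", "yz"):
            assert scaled[f"crossmean_{s}"] == pytest.approx(c**2 * base[f"crossmean_{s}"], rel=1e-9)
            assert scaled[f"abs_crossmean_{s}"] == pytest.approx(c**2 * base[f"abs_crossmean_{s}"], rel=1e-9)


class TestBuildDataset:
    def test_single_clip_shape(self):
        ds = build_dataset([make_clip(np.random.default_rng(0).normal(size=(3, 100)))])
        assert ds.matrix.shape == (1, N_FEATURES)

    def test_row_order_follows_clip_order(self):
        rng = np.random.default_rng(1)
        clips = [random_clip(rng, n=100) for _ in range(6)]
        fwd = build_dataset(clips)
        rev = build_dataset(clips[::-1])
        assert np.array_equal(fwd.matrix, rev.matrix[::-1])

    def test_heterogeneous_lengths_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="heterogeneous"):
            build_dataset([random_clip(rng, n=100), random_clip(rng, n=200)])

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        ds = build_dataset([random_clip(rng, n=100) for _ in range(4)])
        p = tmp_path / "features.csv"
        ds.to_csv(p)
        back = type(ds).from_csv(p)
        assert np.allclose(back.matrix, ds.matrix)
        assert back.labels == ds.labels
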