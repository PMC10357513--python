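import numpy as np
import pytest
from scipy import stats

from haptic_eeg.bands import BANDS
from haptic_eeg.features import (assemble_dataset, dasm, dcau, de_features,
                                 differential_entropy, psd_features,
                                 FeatureTensor)
from haptic_eeg.montage import ElectrodePair
from haptic_eeg.preprocess import SessionSegment, band_decompose

GAUSS_DE = 0.5 * np.log(2 * np.pi * np.e)  # DE of a unit-variance Gaussian


def _segment(data, fs=200.0, names=None, **kw):
    names = names or tuple(f"ch{i}" for i in range(data.shape[0]))
    defaults = dict(subject=0, session=0, emotion="joy", pattern="haptic1",
                    condition="haptic")
    defaults.update(kw)
    return SessionSegment(np.asarray(data), fs, names, **defaults)


class TestDifferentialEntropy:
    def test_unit_variance_closed_form(self, rng):
        x = rng.standard_normal((400, 200))
        de = differential_entropy(x.var(axis=1))
        assert de.mean() == pytest.approx(GAUSS_DE, abs=0.03)

    def test_amplitude_doubling_adds_ln2(self, rng):
        x = rng.standard_normal((3, 1000))
        d1 = differential_entropy(x.var(axis=1))
        d2 = differential_entropy((2 * x).var(axis=1))
        assert np.allclose(d2 - d1, np.log(2), atol=1e-12)

    def test_zero_variance_floored_finite(self):
        de = differential_entropy(np.zeros(4))
        assert np.all(np.isfinite(de))

    def test_monotone_in_band_energy(self, rng):
        sigmas = rng.uniform(0.1, 10, 50)
        de = differential_entropy(sigmas ** 2)
        assert stats.spearmanr(de, np.log(sigmas ** 2)).statistic == \
            pytest.approx(1.0)


class TestPSD:
    def test_zero_signal_zero_psd(self):
        seg = _segment(np.zeros((2, 1000)))
        assert np.all(psd_features(seg).values == 0)

    def test_alpha_tone_dominates_alpha_band(self):
        fs = 200.0
        t = np.arange(2000) / fs
        seg = _segment(np.sin(2 * np.pi * 10 * t)[None, :], fs)
        tensor = psd_features(seg)
        bands = dict(zip(tensor.band_axis, tensor.values.mean(axis=0)[0]))
        for other in ("delta", "theta", "beta", "gamma"):
            assert bands["alpha"] > 10 * bands[other]

    def test_window_count(self):
        seg = _segment(np.random.default_rng(0).normal(size=(3, 2000)))
        assert psd_features(seg).n_windows == 10

    def test_short_segment_warns_empty(self):
        seg = _segment(np.zeros((2, 100)))
        with pytest.warns(RuntimeWarning):
            tensor = psd_features(seg)
        assert tensor.n_windows == 0


class TestDEFeatures:
    def test_de_equals_closed_form_on_band_windows(self, rng):
        seg = _segment(rng.normal(0, 3, (4, 2000)))
        bands = band_decompose(seg)
        de = de_features(bands)
        assert de.values.shape == (10, 4, 5)
        # independently recompute one cell
        win = bands[2].samples[1, 400:600]
        expected = 0.5 * np.log(2 * np.pi * np.e * win.var())
        assert de.values[2, 1, 2] == pytest.approx(expected, rel=1e-12)

    def test_channel_permutation_equivariance(self, rng):
        data = rng.normal(size=(4, 1000))
        de1 = de_features(band_decompose(_segment(data)))
        perm = [2, 0, 3, 1]
        names = tuple(f"ch{i}" for i in range(4))
        de2 = de_features(band_decompose(_segment(
            data[perm], names=tuple(names[i] for i in perm))))
        for new_idx, old_idx in enumerate(perm):
            assert np.allclose(de2.values[:, new_idx, :], de1.values[:, old_idx, :])

    def test_rank_agreement_with_log_psd(self, rng):
        # DE tracks logarithmic spectral energy band by band across
        # stationary segments of different amplitude
        des, log_es = [], []
        for sigma in np.geomspace(0.2, 20.0, 10):
            seg = _segment(rng.normal(0, sigma, (1, 2000)))
            des.append(de_features(band_decompose(seg)).values.mean(axis=(0, 1)))
            log_es.append(np.log(psd_features(seg).values).mean(axis=(0, 1)))
        des, log_es = np.array(des), np.array(log_es)
        for b in range(5):
            rho = stats.spearmanr(des[:, b], log_es[:, b]).statistic
            assert rho == pytest.approx(1.0)


class TestAsymmetryFeatures:
    @pytest.fixture
    def pairs(self):
        return [ElectrodePair("L1", "R1", "hemispheric"),
                ElectrodePair("L2", "R2", "hemispheric")]

    def test_mirrored_signal_gives_zero(self, rng, pairs):
        half = rng.normal(size=(2, 1500))
        data = np.vstack([half, half])  # L1, L2 identical to R1, R2
        de = de_features(band_decompose(_segment(
            data, names=("L1", "L2", "R1", "R2"))))
        out = dasm(de, pairs)
        assert np.allclose(out.values, 0.0, atol=1e-10)
        assert out.units_axis == ("L1-R1", "L2-R2")

    def test_swapping_sides_negates(self, rng, pairs):
        data = rng.normal(size=(4, 1500)) * np.array([[1], [2], [3], [4.]])
        de = de_features(band_decompose(_segment(
            data, names=("L1", "L2", "R1", "R2"))))
        fwd = dasm(de, pairs).values
        swapped = [ElectrodePair("R1", "L1", "hemispheric"),
                   ElectrodePair("R2", "L2", "hemispheric")]
        assert np.allclose(dasm(de, swapped).values, -fwd)

    def test_toy_variances_match_hand_computation(self, rng):
        left = rng.normal(0, 2.0, (1, 1000))
        right = rng.normal(0, 0.5, (1, 1000))
        seg = _segment(np.vstack([left, right]), names=("F1", "P1"))
        bands = band_decompose(seg)
        de = de_features(bands)
        out = dcau(de, [ElectrodePair("F1", "P1", "frontal-posterior")])
        for b_idx in range(5):
            lv = bands[b_idx].samples[0, :200].var()
            rv = bands[b_idx].samples[1, :200].var()
            hand = 0.5 * np.log(lv / rv)
            assert out.values[0, 0, b_idx] == pytest.approx(hand, rel=1e-10)

    def test_dasm_requires_de_tensor(self, pairs):
        t = FeatureTensor("PSD", np.zeros((1, 4, 5)),
                          ("L1", "L2", "R1", "R2"),
                          tuple(b.name for b in BANDS))
        with pytest.raises(ValueError):
            dasm(t, pairs)


class TestAssembleDataset:
    @pytest.fixture
    def tensors(self, rng):
        out = []
        for sess, emo in [(0, "joy"), (1, "fear")]:
            vals = rng.normal(size=(6, 63, 5))
            out.append((FeatureTensor("DE", vals,
                                      tuple(f"c{i}" for i in range(63)),
                                      tuple(b.name for b in BANDS)),
                        sess, emo))
        return out

    def test_single_band_width(self, tensors):
        ds = assemble_dataset(tensors, band_selection="gamma")
        assert ds.X.shape == (12, 63)
        assert set(ds.y) == {"joy", "fear"}

    def test_total_concatenates_bands(self, tensors):
        ds = assemble_dataset(tensors, band_selection="total")
        assert ds.X.shape == (12, 315)

    def test_pair_feature_total_width(self, rng):
        t = FeatureTensor("DASM", rng.normal(size=(4, 28, 5)),
                          tuple(f"p{i}" for i in range(28)),
                          tuple(b.name for b in BANDS))
        ds = assemble_dataset([(t, 0, "joy")], band_selection="total")
        assert ds.X.shape == (4, 140)

    def test_window_averaging(self, tensors):
        ds = assemble_dataset(tensors, band_selection="gamma",
                              average_windows=True)
        assert ds.X.shape == (2, 63)

    def test_mixed_kinds_rejected(self, tensors, rng):
        psd = FeatureTensor("PSD", rng.normal(size=(6, 63, 5)) ** 2,
                            tensors[0][0].units_axis, tensors[0][0].band_axis)
        with pytest.raises(ValueError):
            assemble_dataset(tensors + [(psd, 2, "sadness")])
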