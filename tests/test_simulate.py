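import numpy as np
import pytest

from etongue.classical import split_dataset, train_svm
from etongue.features import build_feature_table
from etongue.preprocess import fit_normalization
from etongue.simulate import (
    ELECTRODE_NAMES,
    ElectrodeParams,
    SimulationConfig,
    VintageEffect,
    class_multipliers,
    default_config,
    default_electrode_params,
    simulate_dataset,
    simulate_sample,
)


class TestDefaultElectrodeParams:
    def test_six_named_electrodes(self):
        params = default_electrode_params()
        assert [p.name for p in params] == list(ELECTRODE_NAMES)

    def test_uniform_28_mA_baseline(self):
        assert all(p.baseline == 28.0 for p in default_electrode_params())

    def test_distinct_conductance_tau_pairs(self):
        pairs = {(p.conductance, p.transient_tau) for p in default_electrode_params()}
        assert len(pairs) == 6


def _flat_config(**overrides):
    """All-signal-terms-off config for closed-form checks."""
    electrodes = tuple(
        ElectrodeParams(
            name=n,
            baseline=28.0,
            conductance=overrides.get("conductance", 0.0),
            transient_amplitude=overrides.get("transient_amplitude", 0.0),
            transient_tau=0.02,
            noise_sd=overrides.get("noise_sd", 0.0),
        )
        for n in ELECTRODE_NAMES
    )
    return SimulationConfig(
        classes=(2016, 2017),
        n_per_class=2,
        electrodes=electrodes,
        effect=VintageEffect(delta=0.0, modulation_seed=1),
        noise_seed=5,
    )


class TestSignalModel:
    def test_all_terms_off_gives_constant_baseline(self):
        rec = simulate_sample(_flat_config(), 2016, np.random.default_rng(0))
        np.testing.assert_array_equal(rec.currents, 28.0)

    def test_ohmic_plateau_value_closed_form(self):
        # conductance g, no transient, no noise: plateau at +1 V reads baseline + g
        cfg = _flat_config(conductance=3.0)
        rec = simulate_sample(cfg, 2016, np.random.default_rng(0))
        # +1.0 V is plateau index 40 (last ladder level), samples 1600:1640
        np.testing.assert_allclose(rec.currents[:, 1600:1640], 31.0, rtol=1e-12)
        # recovery plateaus read the bare baseline
        np.testing.assert_allclose(rec.currents[:, 1640:1680], 28.0, rtol=1e-12)

    def test_record_shape_6x1680(self):
        rec = simulate_sample(default_config(), 2016, np.random.default_rng(0))
        assert rec.currents.shape == (6, 1680)

    def test_unknown_class_label_rejected(self):
        with pytest.raises(KeyError):
            simulate_sample(default_config(), 1999, np.random.default_rng(0))

    def test_transient_decays_from_step_edge(self):
        cfg = _flat_config(transient_amplitude=0.0)
        electrodes = tuple(
            ElectrodeParams(name=n, conductance=0.0, transient_amplitude=2.0,
                            transient_tau=0.02, noise_sd=0.0)
            for n in ELECTRODE_NAMES
        )
        cfg = SimulationConfig(classes=cfg.classes, n_per_class=2,
                               electrodes=electrodes, effect=cfg.effect, noise_seed=5)
        rec = simulate_sample(cfg, 2016, np.random.default_rng(0))
        # first plateau: step from 0 V to -1 V, amplitude a*(V_p - V_prev) = -2 mA at t=0
        assert rec.currents[0, 0] == pytest.approx(28.0 - 2.0)
        # decays monotonically back toward the baseline within the plateau
        seg = rec.currents[0, :40]
        assert np.all(np.diff(seg) > 0)
        assert seg[-1] == pytest.approx(28.0 - 2.0 * np.exp(-39 * 0.0025 / 0.02), rel=1e-9)


class TestVintageEffect:
    def test_delta_zero_multipliers_exactly_one(self):
        eff = VintageEffect(delta=0.0, modulation_seed=3)
        for e in range(6):
            for c in range(5):
                assert class_multipliers(eff, e, c) == (1.0, 1.0)

    def test_multipliers_deterministic_and_bounded(self):
        eff = VintageEffect(delta=0.2, modulation_seed=3)
        a = class_multipliers(eff, 2, 4)
        assert a == class_multipliers(eff, 2, 4)
        assert a != class_multipliers(eff, 2, 3)
        assert all(0.8 <= m <= 1.2 for m in a)


class TestDataset:
    def test_counts_and_shape(self, small_dataset, small_X):
        assert len(small_dataset) == 24
        assert small_X.shape == (24, 6 * 1680)
        labels, counts = np.unique(small_dataset.y, return_counts=True)
        np.testing.assert_array_equal(labels, [2018, 2019, 2020])
        assert np.all(counts == 8)

    def test_identical_config_bitwise_reproducible(self, small_config, small_X):
        again = simulate_dataset(small_config)
        np.testing.assert_array_equal(again.X_concat, small_X)

    def test_concat_is_electrode_major(self, small_dataset, small_X):
        rec = small_dataset.records[0]
        np.testing.assert_array_equal(small_X[0, :1680], rec.currents[0])
        np.testing.assert_array_equal(small_X[0, 1680:3360], rec.currents[1])

    def test_offset_copy_shifts_every_sample(self, small_dataset):
        shifted = small_dataset.with_offset(5.0)
        np.testing.assert_allclose(
            shifted.X_concat - small_dataset.X_concat, 5.0, rtol=0, atol=1e-12
        )


class TestStatisticalStructure:
    def test_null_effect_grand_means_converge(self):
        """With delta=0, per-class grand mean currents agree within 5*sd/sqrt(n)."""
        cfg = default_config(delta=0.0, noise_sd=0.05, n_per_class=200, noise_seed=77)
        ds = simulate_dataset(cfg)
        X, y = ds.X_concat, ds.y
        grand = np.array([X[y == c].mean() for c in cfg.classes])
        spread = np.abs(grand[:, None] - grand[None, :]).max()
        assert spread < 5 * 0.05 / np.sqrt(200)

    def test_linearity_of_plateau_means_without_transient(self):
        """No transient, no noise: plateau-mean current is exactly affine in voltage."""
        electrodes = tuple(
            ElectrodeParams(name=n, conductance=g, transient_amplitude=0.0,
                            transient_tau=0.02, noise_sd=0.0)
            for n, g in zip(ELECTRODE_NAMES, (5.0, 6.5, 3.5, 5.5, 7.0, 4.2))
        )
        cfg = SimulationConfig(classes=(2016,), n_per_class=1, electrodes=electrodes,
                               effect=VintageEffect(delta=0.0), noise_seed=1)
        rec = simulate_dataset(cfg).records[0]
        from etongue.waveform import WaveformSpec, build_waveform

        w = build_waveform(WaveformSpec())
        V = w.plateau_levels
        for e in range(6):
            means = rec.currents[e].reshape(42, 40).mean(axis=1)
            coef = np.polyfit(V, means, 1)
            resid = means - np.polyval(coef, V)
            assert np.abs(resid).max() < 1e-10

    def test_separability_increases_with_delta(self):
        """Classifier label recovery is monotone in the effect size dial."""
        accs = []
        for delta in (0.0, 0.05, 0.2):
            cfg = default_config(delta=delta, noise_sd=0.05, n_per_class=30,
                                 noise_seed=9, modulation_seed=5)
            ds = simulate_dataset(cfg)
            sp = split_dataset(ds.y, 0.8, seed=1)
            stats = fit_normalization(ds.X_concat[sp.train_rows])
            tab = build_feature_table(ds, "AREA", stats)
            clf = train_svm(tab.matrix[sp.train_rows], ds.y[sp.train_rows], seed=1)
            accs.append(
                float(np.mean(clf.predict(tab.matrix[sp.test_rows]) == ds.y[sp.test_rows]))
            )
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] > 0.9
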