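import math

import numpy as np
import pandas as pd
import pytest

from rhizotrans import (
    NormalizationError,
    PipelineConfig,
    SignalMatrix,
    SpikeInNormalization,
    SyntheticConfig,
    anchor_normalize,
    fit_spike_curve,
    generate_dataset,
    interpolate_to_concentration,
    normalize,
    percentile_normalize,
    validate_annotation,
)
from rhizotrans.normalize import SpikeCurve


def spike_ann(concs, names=None, extra_probes=()):
    rows = []
    for i, c in enumerate(concs):
        name = (names or {}).get(i, f"sp{i}")
        rows.append({"probe_id": f"s{i}", "is_control": True, "is_spike": True,
                     "spike_name": name, "spike_log_conc": c})
    for p in extra_probes:
        rows.append({"probe_id": p, "gene_id_v1": f"g_{p}",
                     "is_control": False, "is_spike": False})
    return validate_annotation(pd.DataFrame(rows))


class TestAnchorNormalize:
    def test_shifts_from_anchor_signals(self):
        """Anchors at log10 3.5 and 4.1 get shifts +0.33 and -0.27; both end
        at 3.83 with every other probe shifted by the same sample factor."""
        ann = spike_ann([3.83, 1.0], names={0: "E1A_r60_a20"}, extra_probes=["g1"])
        values = pd.DataFrame({
            "a": [10 ** 3.5, 10.0, 100.0],
            "b": [10 ** 4.1, 10.0, 100.0],
        }, index=["s0", "s1", "g1"])
        m = SignalMatrix(values, pd.Series({"a": "Tv", "b": "Tv"}))
        out = anchor_normalize(m, ann)
        np.testing.assert_allclose(np.log10(out.values.loc["s0"]), 3.83, atol=1e-12)
        np.testing.assert_allclose(out.values.loc["g1", "a"], 100 * 10 ** 0.33)
        np.testing.assert_allclose(out.values.loc["g1", "b"], 100 * 10 ** -0.27)

    def test_fixed_point_when_already_anchored(self):
        ann = spike_ann([3.83, 1.0], names={0: "E1A_r60_a20"}, extra_probes=["g1"])
        values = pd.DataFrame({"a": [10 ** 3.83, 5.0, 50.0]}, index=["s0", "s1", "g1"])
        m = SignalMatrix(values, pd.Series({"a": "Tv"}))
        out = anchor_normalize(m, ann)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_within_sample_ratios_preserved(self):
        ann = spike_ann([3.83], names={0: "E1A_r60_a20"}, extra_probes=["g1", "g2"])
        values = pd.DataFrame({"a": [123.0, 30.0, 90.0]}, index=["s0", "g1", "g2"])
        m = SignalMatrix(values, pd.Series({"a": "Tv"}))
        out = anchor_normalize(m, ann)
        assert out.values.loc["g2", "a"] / out.values.loc["g1", "a"] == pytest.approx(3.0)

    def test_missing_anchor_names_sample(self):
        ann = spike_ann([1.0, 2.0])
        values = pd.DataFrame({"a": [10.0, 20.0]}, index=["s0", "s1"])
        m = SignalMatrix(values, pd.Series({"a": "Tv"}))
        with pytest.raises(NormalizationError, match="E1A_r60_a20"):
            anchor_normalize(m, ann)


class TestSpikeCurve:
    def test_linear_interpolation_midpoint(self):
        curve = SpikeCurve("s", np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))
        assert curve(1.5) == pytest.approx(0.5)

    def test_terminal_extension(self):
        curve = SpikeCurve("s", np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 3.0]))
        assert curve(0.0) == pytest.approx(-1.0)   # slope 1 below
        assert curve(4.0) == pytest.approx(5.0)    # slope 2 above

    def test_proportional_spikes_give_offset_identity(self):
        """Signals proportional to concentration -> curve is identity up to
        a constant offset."""
        concs = [1.0, 2.0, 3.0, 4.0]
        ann = spike_ann(concs)
        sample = pd.Series({f"s{i}": 10 ** (c + 0.7) for i, c in enumerate(concs)})
        curve = fit_spike_curve(sample, ann, "a")
        x = np.linspace(1.5, 4.5, 7)
        np.testing.assert_allclose(curve(x), x - 0.7, atol=1e-9)

    def test_replicate_probes_averaged_and_knots_recovered(self):
        rows = []
        for r, off in ((1, 0.1), (2, -0.1)):
            for i, c in enumerate([1.0, 2.0, 3.0]):
                suffix = "" if r == 1 else f".r{r}"
                rows.append({"probe_id": f"s{i}{suffix}", "is_control": True,
                             "is_spike": True, "spike_name": f"sp{i}",
                             "spike_log_conc": c})
        ann = validate_annotation(pd.DataFrame(rows))
        sample = pd.Series({f"s{i}{s}": 10 ** (c + off)
                            for (s, off) in (("", 0.1), (".r2", -0.1))
                            for i, c in enumerate([1.0, 2.0, 3.0])})
        curve = fit_spike_curve(sample, ann, "a")
        # replicate log-mean cancels the +/-0.1 offsets: knots at (c, c)
        np.testing.assert_allclose(curve.log_signal, [1.0, 2.0, 3.0], atol=1e-12)
        np.testing.assert_allclose([curve(k) for k in (1.0, 2.0, 3.0)],
                                   [1.0, 2.0, 3.0], atol=1e-9)

    def test_noisy_knots_evaluate_to_own_concentration(self):
        rng = np.random.default_rng(0)
        concs = list(np.linspace(0.8, 5.3, 10))
        ann = spike_ann(concs)
        sample = pd.Series({f"s{i}": 10 ** (c + rng.normal(0, 0.05))
                            for i, c in enumerate(concs)})
        curve = fit_spike_curve(sample, ann, "a")
        for x, y in curve.knots:
            assert curve(x) == pytest.approx(y, abs=1e-9)

    def test_non_monotone_sequence_repaired(self):
        concs = [1.0, 2.0, 3.0]
        ann = spike_ann(concs)
        # middle spike dimmer than the first: violates monotonicity
        sample = pd.Series({"s0": 100.0, "s1": 50.0, "s2": 1000.0})
        curve = fit_spike_curve(sample, ann, "a")
        assert np.all(np.diff(curve.log_signal) > 0)

    def test_fewer_than_two_spikes_rejected(self):
        ann = spike_ann([1.0])
        with pytest.raises(NormalizationError, match="fewer than 2"):
            fit_spike_curve(pd.Series({"s0": 10.0}), ann, "a")


class TestInterpolate:
    def test_identity_curve_is_identity(self, tiny_matrix):
        curves = {s: SpikeCurve(s, np.array([0.0, 6.0]), np.array([0.0, 6.0]))
                  for s in tiny_matrix.sample_ids}
        out = interpolate_to_concentration(tiny_matrix, curves)
        np.testing.assert_allclose(out.values, tiny_matrix.values, rtol=1e-12)

    def test_offset_curves_cancel_equal_concentration(self):
        """Two samples whose curves differ only by a log-signal offset map a
        gene of equal true concentration to equal values."""
        values = pd.DataFrame({"a": [100.0], "b": [1000.0]}, index=["g1"])
        m = SignalMatrix(values, pd.Series({"a": "Tv", "b": "Tv"}))
        curves = {
            "a": SpikeCurve("a", np.array([0.0, 6.0]), np.array([0.0, 6.0])),
            "b": SpikeCurve("b", np.array([1.0, 7.0]), np.array([0.0, 6.0])),
        }
        out = interpolate_to_concentration(m, curves)
        assert out.values.loc["g1", "a"] == pytest.approx(out.values.loc["g1", "b"])


class TestPercentileNormalize:
    def test_identical_samples_unchanged(self):
        values = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]},
                              index=["g1", "g2", "g3", "g4"])
        ann = spike_ann([], extra_probes=["g1", "g2", "g3", "g4"])
        m = SignalMatrix(values, pd.Series({"a": "Tv", "b": "Tv"}))
        out = percentile_normalize(m, ann)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-12)

    def test_quantiles_100_and_400_meet_at_200(self):
        """75th percentiles (100, 400) imply factors (2, 0.5) around the
        geometric mean 200; both samples end with 75th percentile 200."""
        base = np.array([25.0, 50.0, 75.0, 100.0, 125.0])  # q75 = 100 exactly
        values = pd.DataFrame({"a": base, "b": 4 * base},
                              index=["g1", "g2", "g3", "g4", "g5"])
        ann = spike_ann([], extra_probes=["g1", "g2", "g3", "g4", "g5"])
        m = SignalMatrix(values, pd.Series({"a": "Tv", "b": "M+Tv"}))
        out = percentile_normalize(m, ann)
        q = out.values.quantile(0.75)
        np.testing.assert_allclose(q, 200.0, rtol=1e-12)
        np.testing.assert_allclose(out.values["a"], base * 2.0, rtol=1e-12)
        np.testing.assert_allclose(out.values["b"], 4 * base * 0.5, rtol=1e-12)

    def test_controls_excluded_from_quantile(self):
        ann = spike_ann([3.0], extra_probes=["g1", "g2", "g3"])
        values = pd.DataFrame({"a": [1e6, 10.0, 20.0, 30.0]},
                              index=["s0", "g1", "g2", "g3"])
        m = SignalMatrix(values, pd.Series({"a": "Tv"}))
        out = percentile_normalize(m, ann)
        # quantile computed over g1..g3 only (25), not dominated by the control
        np.testing.assert_allclose(
            out.values.loc["g1", "a"], 10.0, rtol=1e-12)


class TestFullChain:
    def zero_noise_cfg(self, **kw):
        base = dict(n_genes=500, n_duplicate_genes=10, n_other_controls=30,
                    noise_sd_high=0.0, noise_sd_low=0.0, baseline_sd=0.0,
                    n_shared_up=20, n_maize_up=0, n_tomato_up=0,
                    n_maize_vs_tomato=0, shared_lfc=math.log10(4), seed=11)
        base.update(kw)
        return SyntheticConfig(**base)

    def test_gains_fully_removed_zero_noise(self):
        m, ann, truth = generate_dataset(self.zero_noise_cfg())
        out = normalize(m, ann)
        null_probes = ["p_" + g for g in truth.index[truth["class"] == "null"]]
        vals = out.values.loc[null_probes]
        cv = vals.std(axis=1, ddof=0) / vals.mean(axis=1)
        assert float(cv.max()) < 1e-9

    def test_planted_fourfold_survives_normalization(self):
        m, ann, truth = generate_dataset(self.zero_noise_cfg())
        out = normalize(m, ann)
        probes = ["p_" + g for g in truth.index[truth["class"] == "shared_up"]]
        for cond in ("M+Tv", "T+Tv"):
            ratio = (out.values.loc[probes, out.samples_of(cond)].mean(axis=1)
                     / out.values.loc[probes, out.samples_of("Tv")].mean(axis=1))
            np.testing.assert_allclose(ratio, 4.0, atol=1e-6)

    def test_identical_samples_output_global_scale_only(self):
        cfg = self.zero_noise_cfg(gain_log_range=(0.0, 0.0), n_shared_up=0,
                                  shared_lfc=None)
        m, ann, _ = generate_dataset(cfg)
        out = normalize(m, ann)
        factors = out.values.iloc[:, 0] / m.values.iloc[:, 0]
        gene_rows = [p for p in m.probe_ids if not ann.at[p, "is_control"]]
        f = factors.loc[gene_rows]
        assert float(f.max() - f.min()) < 1e-9

    def test_rank_order_preserved_per_sample(self, small_dataset):
        m, ann, _ = small_dataset
        out = normalize(m, ann)
        for s in m.sample_ids:
            before = m.values[s].rank(method="first")
            after = out.values[s].rank(method="first")
            assert (before == after).all()

    def test_idempotence_with_consistent_spikes(self):
        """Once the spike panel exactly matches its concentrations (no
        measurement noise), a second normalization pass is the identity."""
        m, ann, _ = generate_dataset(self.zero_noise_cfg(baseline_sd=0.6))
        once = normalize(m, ann)
        twice = normalize(once, ann)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), rtol=1e-9)

    def test_noise_cv_reduced(self, small_dataset):
        m, ann, truth = small_dataset
        out = normalize(m, ann)
        null_probes = ["p_" + g for g in truth.index[truth["class"] == "null"]]

        def mean_cv(mat):
            vals = mat.values.loc[null_probes]
            return float((vals.std(axis=1, ddof=0) / vals.mean(axis=1)).mean())

        assert mean_cv(out) < mean_cv(m)

    def test_result_diagnostics_shape(self, small_dataset):
        m, ann, _ = small_dataset
        res = SpikeInNormalization(m, ann).fit()
        d = res.diagnostics()
        assert list(d.index) == list(m.sample_ids)
        assert res.normalized.scale == "normalized"
        assert set(res.curves) == set(m.sample_ids)
        assert "anchor_shift_log10" in d.columns
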