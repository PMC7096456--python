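"""Fusion arithmetic, evaluation metrics and the end-to-end pipeline."""

import numpy as np
import pytest

from mdwfuse import (
    PipelineConfig,
    default_benchmark,
    evaluate,
    fuse,
    generate_dataset,
    rank_split,
    run_mdw_pipeline,
)
from mdwfuse.mdweight import WeightMatrix


def pipeline_on_benchmark(seed, config=None):
    tables, ref, labels = generate_dataset(default_benchmark(seed=seed))
    plan = rank_split(ref.concentration, 15 / 78, sample_ids=ref.sample_ids)
    pairs = [
        (t.subset(plan.calibration_ids), t.subset(plan.validation_ids)) for t in tables
    ]
    result = run_mdw_pipeline(
        pairs, ref.subset(plan.calibration_ids), ref.subset(plan.validation_ids), config
    )
    return result, plan, labels


class TestFuse:
    def test_hand_cases(self):
        Y = np.array([[2.0, 3.0]])
        assert fuse(Y, np.array([[0.5, 0.5]]))[0] == pytest.approx(2.5)
        assert fuse(Y, np.array([[1.0, 0.0]]))[0] == pytest.approx(2.0)
        # weights derived from the published sample-1 distances (2.731, 2.454)
        assert fuse(np.array([[2.5, 2.7]]), np.array([[0.4733, 0.5267]]))[0] == pytest.approx(
            2.60534, abs=1e-5
        )

    def test_accepts_weight_matrix_and_checks_shapes(self):
        W = WeightMatrix(np.array([[0.25, 0.75]]), np.array([False]))
        assert fuse(np.array([[4.0, 8.0]]), W)[0] == pytest.approx(7.0)
        with pytest.raises(ValueError, match="shape"):
            fuse(np.ones((2, 2)), np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="sum"):
            fuse(np.ones((1, 2)), np.array([[0.9, 0.3]]))


class TestEvaluate:
    def test_hand_arithmetic(self):
        m = evaluate([1.0, 2.0, 3.0], [1.1, 1.9, 3.2])
        assert m.rmsep == pytest.approx(np.sqrt(0.06 / 3), abs=1e-5)
        assert m.bias == pytest.approx(0.2 / 3, abs=1e-5)

    def test_perfect_and_shifted_predictions(self, rng):
        y = rng.uniform(0, 5, size=20)
        m = evaluate(y, y)
        assert (m.rmsep, m.bias, m.slope) == pytest.approx((0.0, 0.0, 1.0), abs=1e-12)
        m = evaluate(y, y + 0.3)
        assert (m.rmsep, m.bias, m.slope) == pytest.approx((0.3, 0.3, 1.0), abs=1e-9)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        y = rng.uniform(0, 5, size=50)
        p = y + rng.normal(0, 0.2, size=50)
        m = evaluate(y, p)
        assert m.rmsep == pytest.approx(np.sqrt(np.mean((p - y) ** 2)), abs=1e-12)
        assert m.bias == pytest.approx(np.mean(p - y), abs=1e-12)
        assert m.rmsep >= abs(m.bias)
        cov = np.cov(y, p, ddof=1)
        assert m.slope == pytest.approx(cov[0, 1] / cov[0, 0], abs=1e-12)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestPipeline:
    def test_convexity_and_error_bound_per_sample(self, benchmark_run):
        result, _, _ = benchmark_run
        preds = result.per_sensor_predictions
        fused = result.fused_predictions
        assert np.all(fused >= preds.min(axis=1) - 1e-9)
        assert np.all(fused <= preds.max(axis=1) + 1e-9)
        errs = np.abs(preds - result.y_val[:, None])
        assert np.all(np.abs(fused - result.y_val) <= errs.max(axis=1) + 1e-9)

    def test_weights_normalized_and_log_populated(self, benchmark_run):
        result, _, _ = benchmark_run
        assert np.allclose(result.weights.weights.sum(axis=1), 1.0, atol=1e-12)
        for name in result.sensor_names:
            entry = result.log["sensors"][name]
            assert entry["n_lv"] >= 1
            assert entry["threshold"] > 0

    def test_sensor_permutation_leaves_fusion_unchanged(self):
        a, plan, _ = pipeline_on_benchmark(3)
        tables, ref, _ = generate_dataset(default_benchmark(seed=3))
        pairs = [
            (t.subset(plan.calibration_ids), t.subset(plan.validation_ids))
            for t in tables[::-1]
        ]
        b = run_mdw_pipeline(
            pairs, ref.subset(plan.calibration_ids), ref.subset(plan.validation_ids)
        )
        assert b.sensor_names == a.sensor_names[::-1]
        assert np.allclose(a.fused_predictions, b.fused_predictions, atol=1e-12)
        assert np.allclose(a.weights.weights, b.weights.weights[:, ::-1], atol=1e-12)

    def test_pure_noise_sensor_still_yields_valid_weights(self, rng):
        tables, ref, _ = generate_dataset(default_benchmark(seed=5))
        noise = tables[1]
        noise.absorbance = rng.normal(size=noise.absorbance.shape)
        plan = rank_split(ref.concentration, 15 / 78, sample_ids=ref.sample_ids)
        pairs = [
            (t.subset(plan.calibration_ids), t.subset(plan.validation_ids))
            for t in (tables[0], noise)
        ]
        result = run_mdw_pipeline(
            pairs, ref.subset(plan.calibration_ids), ref.subset(plan.validation_ids)
        )
        assert np.allclose(result.weights.weights.sum(axis=1), 1.0, atol=1e-12)
        preds = result.per_sensor_predictions
        assert np.all(result.fused_predictions >= preds.min(axis=1) - 1e-9)
        assert np.all(result.fused_predictions <= preds.max(axis=1) + 1e-9)

    def test_single_sensor_rejected(self):
        tables, ref, _ = generate_dataset(default_benchmark(seed=2))
        plan = rank_split(ref.concentration, 15 / 78, sample_ids=ref.sample_ids)
        pairs = [(tables[0].subset(plan.calibration_ids), tables[0].subset(plan.validation_ids))]
        with pytest.raises(ValueError, match="2 sensors"):
            run_mdw_pipeline(
                pairs, ref.subset(plan.calibration_ids), ref.subset(plan.validation_ids)
            )

    def test_sample_id_misalignment_rejected(self):
        tables, ref, _ = generate_dataset(default_benchmark(seed=2))
        plan = rank_split(ref.concentration, 15 / 78, sample_ids=ref.sample_ids)
        cal_ids = plan.calibration_ids
        shuffled = list(cal_ids[1:]) + [cal_ids[0]]
        pairs = [
            (tables[0].subset(cal_ids), tables[0].subset(plan.validation_ids)),
            (tables[1].subset(shuffled), tables[1].subset(plan.validation_ids)),
        ]
        with pytest.raises(ValueError, match="sample ids differ"):
            run_mdw_pipeline(
                pairs, ref.subset(cal_ids), ref.subset(plan.validation_ids)
            )

    def test_equal_quality_sensors_fused_not_worse_than_best(self):
        """With two equal-noise sensors, fusion tracks the better sensor.

        Averaged over 20 seeds the fused RMSEP stays within 2% of the
        better sensor's mean RMSEP.
        """
        import copy

        fused, best = [], []
        for seed in range(1, 21):
            cfg = default_benchmark(seed=seed)
            # exchangeable sensors: same bands, noise and artifact setup
            # (artifact sample sets stay disjoint)
            twin = copy.deepcopy(cfg.sensors[0])
            twin.name = "NIR2"
            cfg.sensors[1] = twin
            tables, ref, _ = generate_dataset(cfg)
            plan = rank_split(ref.concentration, 15 / 78, sample_ids=ref.sample_ids)
            pairs = [
                (t.subset(plan.calibration_ids), t.subset(plan.validation_ids))
                for t in tables
            ]
            result = run_mdw_pipeline(
                pairs, ref.subset(plan.calibration_ids), ref.subset(plan.validation_ids)
            )
            fused.append(result.metrics_fused.rmsep)
            best.append(min(m.rmsep for m in result.metrics_per_sensor))
        assert np.mean(fused) <= 1.02 * np.mean(best)
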