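"""Sample-to-sample and batch-to-batch updating cycles."""

import numpy as np
import pytest

from seedtrain.synthetic_data import (
    VariabilityConfig,
    generate_ensemble,
    generate_seed_train,
    nominal_parameters,
)
from seedtrain.workflow import (
    PriorState,
    WorkflowConfig,
    batch_to_batch_cycle,
    run_benchmark,
    sample_to_sample_cycle,
)


@pytest.fixture(scope="module")
def two_train_ensemble():
    records, truths = generate_ensemble(2, VariabilityConfig(), seed=11)
    return records, truths


def nominal_prior():
    return PriorState.shared(nominal_parameters(), 3)


class TestSampleToSampleCycle:
    def test_noiseless_record_near_zero_errors(self, noiseless_record):
        """With the prior equal to the generating parameters and clean
        data, every step's prediction error is essentially zero."""
        rec, _ = noiseless_record
        cfg = WorkflowConfig(objective="wlse", horizon_mode="growing", max_evals=300)
        steps, _ = sample_to_sample_cycle(rec, nominal_prior(), cfg)
        errs = [
            s.assessment.step_error["Xv"]
            for s in steps
            if "Xv" in s.assessment.step_error
        ]
        assert len(errs) >= 10
        assert max(errs) < 0.5

    def test_per_scale_updates_leave_other_scales_untouched(self, two_train_ensemble):
        records, _ = two_train_ensemble
        cfg = WorkflowConfig(
            objective="wlse",
            horizon_mode="per_scale_growing",
            parameter_sets="per_scale",
            max_evals=200,
        )
        steps, _ = sample_to_sample_cycle(records[0], nominal_prior(), cfg)
        scale1_steps = [s for s in steps if s.scale_pos == 0]
        nominal = nominal_parameters()
        for s in scale1_steps:
            assert s.prior_after.params_per_scale[1] == nominal
            assert s.prior_after.params_per_scale[2] == nominal

    def test_updated_parameters_become_next_prior(self, two_train_ensemble):
        records, _ = two_train_ensemble
        cfg = WorkflowConfig(objective="wlse", horizon_mode="growing", max_evals=200)
        steps, final = sample_to_sample_cycle(records[0], nominal_prior(), cfg)
        assert steps[-1].prior_after == final
        # priors chain step to step
        for a, b in zip(steps, steps[1:]):
            if not b.updated:
                assert b.prior_after == a.prior_after


class TestBatchToBatchCycle:
    def test_b0_runs_are_independent_and_order_invariant(self, two_train_ensemble):
        records, _ = two_train_ensemble
        cfg = WorkflowConfig(objective="wlse", horizon_mode="growing", max_evals=200)
        fwd, _ = batch_to_batch_cycle(records, cfg, nominal_prior())
        rev, _ = batch_to_batch_cycle(records[::-1], cfg, nominal_prior())
        by_id_fwd = {o.seed_train_id: o.summary("Xv") for o in fwd}
        by_id_rev = {o.seed_train_id: o.summary("Xv") for o in rev}
        assert by_id_fwd == by_id_rev

    def test_chained_prior_provenance(self, two_train_ensemble):
        records, _ = two_train_ensemble
        cfg = WorkflowConfig(
            objective="mhe",
            horizon_mode="per_scale_growing",
            parameter_sets="per_scale",
            arrival_cost_window_B=1,
            max_evals=200,
        )
        outputs, final = batch_to_batch_cycle(records, cfg, nominal_prior())
        # train 2's incoming prior is exactly train 1 reprocessed from nominal,
        # i.e. train 1's own final state (train 1 itself started from nominal)
        assert outputs[1].prior_before == outputs[0].prior_after
        assert final == outputs[-1].prior_after

    def test_learning_reduces_early_step_error(self):
        """Processing the same record twice with chained priors: the second
        pass starts from learned parameters and its first-update prediction
        is at least as good."""
        var = VariabilityConfig(measurement_cv=0.05, batch_mu_max_cv=0.0)
        records, _ = generate_ensemble(1, var, seed=21)
        twice = [records[0], records[0]]
        cfg = WorkflowConfig(
            objective="mhe",
            horizon_mode="per_scale_growing",
            parameter_sets="per_scale",
            arrival_cost_window_B=1,
            max_evals=300,
        )
        outputs, _ = batch_to_batch_cycle(twice, cfg, nominal_prior())
        first_errors = [o.steps[0].assessment.step_error["Xv"] for o in outputs]
        assert first_errors[1] <= first_errors[0] + 1e-9

    def test_window_depth_barely_matters(self):
        """Going 1 vs 2 seed trains back in the arrival-cost chain changes
        mean prediction performance only marginally (scaled-down ensemble
        of 3 chained trains)."""
        records, _ = generate_ensemble(3, VariabilityConfig(), seed=31)
        means = {}
        for B in (1, 2):
            cfg = WorkflowConfig(
                objective="mhe",
                horizon_mode="per_scale_growing",
                parameter_sets="per_scale",
                arrival_cost_window_B=B,
                max_evals=300,
            )
            outputs, _ = batch_to_batch_cycle(records, cfg, nominal_prior())
            means[B] = np.mean([o.summary("Xv")[0] for o in outputs])
        assert abs(means[1] - means[2]) < 2.0

    def test_empty_record_list_rejected(self):
        cfg = WorkflowConfig()
        with pytest.raises(ValueError):
            batch_to_batch_cycle([], cfg, nominal_prior())

    def test_determinism(self, two_train_ensemble):
        records, _ = two_train_ensemble
        cfg = WorkflowConfig(
            objective="mhe",
            horizon_mode="per_scale_growing",
            parameter_sets="per_scale",
            arrival_cost_window_B=1,
            max_evals=200,
        )
        out1, prior1 = batch_to_batch_cycle(records, cfg, nominal_prior())
        out2, prior2 = batch_to_batch_cycle(records, cfg, nominal_prior())
        assert prior1 == prior2
        for a, b in zip(out1, out2):
            for sa, sb in zip(a.steps, b.steps):
                assert sa.assessment.step_error == sb.assessment.step_error


class TestRunBenchmark:
    def test_single_noiseless_train_all_zero(self, noiseless_record):
        rec, _ = noiseless_record
        cfg = WorkflowConfig(objective="wlse", horizon_mode="growing", max_evals=200)
        table = run_benchmark([rec], {"wlse": cfg}, nominal_prior())
        assert len(table) == 1
        assert table.loc[0, "mean"] == pytest.approx(0.0, abs=0.5)
        assert table.loc[0, "max"] == pytest.approx(0.0, abs=0.5)

    def test_fair_comparison_alignment(self, noiseless_record):
        """With one config at fixed length n, all configs are summarized
        from the same first prediction horizon."""
        rec, _ = noiseless_record
        cfgs = {
            "growing": WorkflowConfig(objective="wlse", horizon_mode="growing", max_evals=100),
            "moving4": WorkflowConfig(
                objective="wlse",
                horizon_mode="moving",
                horizon_length=4,
                evaluation_start=4,
                max_evals=100,
            ),
        }
        table = run_benchmark([rec], cfgs, nominal_prior())
        assert set(table["config"]) == {"growing", "moving4"}
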