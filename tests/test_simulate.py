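import numpy as np
import pytest

from clinens import (
    AgeEffectSpec,
    GeneratorConfig,
    apply_age_effect,
    default_scheme,
    empirical_profiles,
    generate_cohort,
)
from clinens.simulate import ModelProfile

from conftest import _uniform_profile, small_config


def _one_task_config(models, n, r=0.0, prevalence=0.681, replicate_count=None):
    from clinens.dataset import TaskGroupScheme

    scheme = TaskGroupScheme(groups={"G0": frozenset({"T1"})})
    return GeneratorConfig(
        models=models,
        task_scheme=scheme,
        replicate_count=replicate_count or {},
        n_patients=n,
        prevalence=prevalence,
        cluster_correlation=r,
    )


class TestCohortMarginals:
    def test_prevalence_recovered_at_scale(self):
        cfg = small_config(n_patients=5000)
        ds = generate_cohort(cfg, seed=2)
        assert abs(ds.patients["label"].mean() - 0.681) < 0.02

    def test_ages_respect_truncation_and_location(self):
        ds = generate_cohort(small_config(n_patients=4000), seed=3)
        ages = ds.patients["age"]
        assert ages.min() >= 35.0 and ages.max() <= 83.0
        assert abs(ages.mean() - 66.63) < 1.0

    def test_profile_recovery(self):
        models = [_uniform_profile("m", "c", 0.9, 0.7, groups=("G0",))]
        ds = generate_cohort(_one_task_config(models, 10000), seed=4)
        prof = empirical_profiles(ds).set_index("model")
        assert abs(prof.loc["m", "sensitivity"] - 0.9) < 0.02
        assert abs(prof.loc["m", "specificity"] - 0.7) < 0.02

    def test_degenerate_probabilities_clamp(self):
        # Se=1/Sp=0 must produce a constant-1 rater without error even with r>0
        models = [_uniform_profile("always1", "c", 1.0, 0.0, groups=("G0",))]
        cfg = _one_task_config(models, 200, r=0.5)
        ds = generate_cohort(cfg, seed=5)
        assert set(ds.predictions["prediction"]) == {1}
        prof = empirical_profiles(ds).set_index("model")
        assert prof.loc["always1", "sensitivity"] == 1.0
        assert prof.loc["always1", "specificity"] == 0.0

    def test_independent_models_uncorrelated_within_label(self):
        models = [
            _uniform_profile("a", "c1", 0.8, 0.8, groups=("G0",)),
            _uniform_profile("b", "c2", 0.8, 0.8, groups=("G0",)),
        ]
        ds = generate_cohort(_one_task_config(models, 20000, r=0.0), seed=6)
        rows, P, names = ds.matrix()
        y = rows["label"].to_numpy()
        for cls in (0, 1):
            sub = P[y == cls]
            r = np.corrcoef(sub[:, 0], sub[:, 1])[0, 1]
            assert abs(r) < 0.03


class TestReplicates:
    def test_zero_flip_means_identical_replicates(self):
        models = [_uniform_profile("m", "c", 0.8, 0.8, groups=("G0",), flip=0.0)]
        ds = generate_cohort(_one_task_config(models, 100, replicate_count={"T1": 3}), seed=7)
        wide = ds.predictions.pivot_table(
            index=["patient_id", "task"], columns="replicate", values="prediction"
        )
        assert (wide.nunique(axis=1) == 1).all()

    def test_flip_rate_realized(self):
        models = [_uniform_profile("m", "c", 0.8, 0.8, groups=("G0",), flip=0.2)]
        ds = generate_cohort(_one_task_config(models, 5000, replicate_count={"T1": 2}), seed=8)
        wide = ds.predictions.pivot(
            index=["patient_id", "task"], columns="replicate", values="prediction"
        )
        flip_rate = (wide[1] != wide[2]).mean()
        assert abs(flip_rate - 0.2) < 0.02


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = small_config(n_patients=60)
        a = generate_cohort(cfg, seed=9)
        b = generate_cohort(cfg, seed=9)
        assert a.equals(b)

    def test_different_seed_differs(self):
        cfg = small_config(n_patients=120)
        a = generate_cohort(cfg, seed=9)
        b = generate_cohort(cfg, seed=10)
        assert not a.predictions["prediction"].equals(b.predictions["prediction"])


class TestAgeEffect:
    def test_empty_affected_set_is_identity(self, tiny_dataset):
        spec = AgeEffectSpec(affected_models=set(), slope=-0.3)
        out = apply_age_effect(tiny_dataset, spec, seed=1)
        assert out.equals(tiny_dataset)

    def test_unaffected_models_untouched(self, tiny_dataset):
        spec = AgeEffectSpec(affected_models={"m00"}, slope=0.0)
        out = apply_age_effect(tiny_dataset, spec, seed=1)
        for m in ("m01", "m02", "m03"):
            a = tiny_dataset.predictions[tiny_dataset.predictions["model"] == m]
            b = out.predictions[out.predictions["model"] == m]
            assert (a["prediction"].to_numpy() == b["prediction"].to_numpy()).all()

    def test_negative_slope_degrades_accuracy_above_pivot(self):
        cfg = small_config(n_patients=5000, n_models=2)
        ds = generate_cohort(cfg, seed=12)
        spec = AgeEffectSpec(affected_models=set(ds.models), slope=-0.25, pivot_age=66.0)
        out = apply_age_effect(ds, spec, seed=13)
        preds = out.predictions.merge(out.patients, on="patient_id")
        match = (preds["prediction"] == preds["label"]).to_numpy()
        old = (preds["age"] >= 66.0).to_numpy()
        assert match[~old].mean() - match[old].mean() > 0.1

    def test_unknown_affected_model_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="ghost"):
            apply_age_effect(tiny_dataset, AgeEffectSpec({"ghost"}, -0.1), seed=1)
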