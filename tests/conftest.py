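import numpy as np
import pytest

from clinens import GeneratorConfig, ModelProfile, TaskGroupScheme, default_scheme, generate_cohort


def _uniform_profile(name, cluster, se, sp, groups=("CAG", "CTA", "MULTI"), flip=0.0):
    return ModelProfile(
        model_name=name,
        cluster_id=cluster,
        se_by_group={g: se for g in groups},
        sp_by_group={g: sp for g in groups},
        replicate_flip=flip,
    )


def complementarity_config(n_patients=93, seed=0):
    """One aggressive near-perfect-sensitivity rater plus two independent
    conservative raters whose error patterns the ensemble can exploit."""
    return GeneratorConfig(
        models=[
            _uniform_profile("agg-A", "c1", se=1.0, sp=0.0),
            _uniform_profile("bal-B", "c2", se=0.62, sp=0.93),
            _uniform_profile("bal-C", "c3", se=0.62, sp=0.93),
        ],
        task_scheme=default_scheme(),
        replicate_count={},
        n_patients=n_patients,
        prevalence=0.681,
        cluster_correlation=0.0,
        seed=seed,
    )


def small_config(n_patients=93, n_models=4, tasks=("T1", "T2", "T3"), r=0.0, seed=0):
    """A small cohort of moderately aggressive raters for reduced-scale runs."""
    scheme = TaskGroupScheme(groups={f"G{i}": frozenset({t}) for i, t in enumerate(tasks)})
    rng = np.random.default_rng(12345)
    models = []
    for i in range(n_models):
        se = 0.85 + 0.1 * rng.random()
        sp = 0.15 + 0.2 * rng.random()
        models.append(_uniform_profile(f"m{i:02d}", f"c{i % 2}", se, sp, groups=scheme.groups))
    return GeneratorConfig(
        models=models,
        task_scheme=scheme,
        replicate_count={},
        n_patients=n_patients,
        prevalence=0.681,
        cluster_correlation=r,
        seed=seed,
    )


@pytest.fixture
def tiny_dataset():
    cfg = small_config(n_patients=40, n_models=4)
    return generate_cohort(cfg, seed=7)


@pytest.fixture
def default_cohort():
    from clinens import default_config

    return generate_cohort(default_config(), seed=11)
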