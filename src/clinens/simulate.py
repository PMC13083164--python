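"""Synthetic cohorts of binary rater predictions.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort with a fixed outcome prevalence, truncated-normal ages, and
per-rater binary predictions whose marginal sensitivity/specificity are
controlled per task group while inter-rater correlation follows a block
(cluster) structure.

Correlated binary predictions come from a Gaussian latent-threshold (copula)
construction: one shared standard-normal cluster factor per
(patient, cluster, task) is mixed with an idiosyncratic factor at weights
sqrt(r) vs sqrt(1-r) and thresholded separately for positive and negative
patients, so that marginally P(pred=1 | label=1) = Se and
P(pred=0 | label=0) = Sp for the task's group.  Se or Sp of exactly 0 or 1
are handled by clamping the threshold to +/-infinity, never by raising.

Replicates beyond the first equal replicate 1 with independent flips at the
per-rater rate ``replicate_flip``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri, expit, logit

from .dataset import PredictionDataset, TaskGroupScheme, default_scheme


@dataclass
class ModelProfile:
    """Marginal operating profile of one rater.

    ``se_by_group`` / ``sp_by_group`` map group label -> probability;
    ``cluster_id`` names the correlation block the rater belongs to;
    ``replicate_flip`` is the probability that a repeat query flips the
    first answer independently.
    """

    model_name: str
    cluster_id: str
    se_by_group: dict
    sp_by_group: dict
    replicate_flip: float = 0.0

    def validate(self):
        for d in (self.se_by_group, self.sp_by_group):
            for g, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} for {self.model_name}/{g} outside [0,1]")
        if not 0.0 <= self.replicate_flip <= 1.0:
            raise ValueError("replicate_flip outside [0,1]")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the reference study population: 93 patients, outcome
    prevalence 68.1%, age 66.63 +/- 9.30 years truncated to 35-83, 67.7%
    male.
    """

    models: list
    task_scheme: TaskGroupScheme = field(default_factory=default_scheme)
    replicate_count: dict = field(default_factory=dict)  # task -> count, default 1
    n_patients: int = 93
    prevalence: float = 0.681
    age_mean: float = 66.63
    age_sd: float = 9.30
    age_range: tuple = (35.0, 83.0)
    male_fraction: float = 0.677
    cluster_correlation: float = 0.45
    seed: int = 0

    def validate(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, p in [("prevalence", self.prevalence), ("male_fraction", self.male_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        if not 0.0 <= self.cluster_correlation < 1.0:
            raise ValueError("cluster_correlation must lie in [0,1)")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range min must be < max")
        for m in self.models:
            m.validate()

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path):
        doc = {
            "n_patients": self.n_patients,
            "prevalence": self.prevalence,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_range": list(self.age_range),
            "male_fraction": self.male_fraction,
            "cluster_correlation": self.cluster_correlation,
            "seed": self.seed,
            "replicate_count": dict(self.replicate_count),
            "task_scheme": {g: sorted(ts) for g, ts in self.task_scheme.groups.items()},
            "models": [
                {
                    "model_name": m.model_name,
                    "cluster_id": m.cluster_id,
                    "se_by_group": dict(m.se_by_group),
                    "sp_by_group": dict(m.sp_by_group),
                    "replicate_flip": m.replicate_flip,
                }
                for m in self.models
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, source) -> "GeneratorConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorConfig":
        scheme = TaskGroupScheme(
            groups={g: frozenset(ts) for g, ts in doc["task_scheme"].items()},
            description="loaded",
        )
        models = [ModelProfile(**m) for m in doc["models"]]
        cfg = cls(
            models=models,
            task_scheme=scheme,
            replicate_count=doc.get("replicate_count", {}),
            n_patients=int(doc.get("n_patients", 93)),
            prevalence=float(doc.get("prevalence", 0.681)),
            age_mean=float(doc.get("age_mean", 66.63)),
            age_sd=float(doc.get("age_sd", 9.30)),
            age_range=tuple(doc.get("age_range", (35.0, 83.0))),
            male_fraction=float(doc.get("male_fraction", 0.677)),
            cluster_correlation=float(doc.get("cluster_correlation", 0.45)),
            seed=int(doc.get("seed", 0)),
        )
        cfg.validate()
        return cfg


def default_config() -> GeneratorConfig:
    """The packaged 93-patient / 15-rater / 9-task default configuration."""
    ref = importlib.resources.files("clinens") / "config" / "default_cohort.yaml"
    with ref.open() as fh:
        return GeneratorConfig.from_yaml(fh)


@dataclass
class AgeEffectSpec:
    """Injected age-performance interaction.

    For affected raters each prediction is re-drawn so the probability of
    matching the label shifts on the logit scale by
    ``slope * (age - pivot_age)``.
    """

    affected_models: set
    slope: float
    pivot_age: float = 73.0


def _truncnorm(rng, n, mean, sd, lo, hi):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n, 64))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _threshold(p):
    # ndtri(0) / ndtri(1) are -inf / +inf already, but guard against NaN
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return ndtri(p)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> PredictionDataset:
    """Draw a full synthetic cohort; bit-reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    tasks = sorted(config.task_scheme.all_tasks())
    task_to_group = config.task_scheme.task_to_group()
    r = config.cluster_correlation

    ages = _truncnorm(rng, n, config.age_mean, config.age_sd, *config.age_range)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    labels = (rng.random(n) < config.prevalence).astype(int)
    patient_ids = [f"P{i+1:04d}" for i in range(n)]

    clusters = []
    for m in config.models:
        if m.cluster_id not in clusters:
            clusters.append(m.cluster_id)
    C = rng.standard_normal((n, len(clusters), len(tasks)))

    pid_col, model_col, task_col, rep_col, pred_col = [], [], [], [], []
    pos = labels == 1
    for m in config.models:
        ci = clusters.index(m.cluster_id)
        E = rng.standard_normal((n, len(tasks)))
        z = np.sqrt(r) * C[:, ci, :] + np.sqrt(1.0 - r) * E
        thr_pos = _threshold([m.se_by_group[task_to_group[t]] for t in tasks])
        thr_neg = _threshold([m.sp_by_group[task_to_group[t]] for t in tasks])
        # positives: pred=1 iff z <= Phi^-1(Se); negatives: pred=0 iff z <= Phi^-1(Sp)
        pred1 = np.where(pos[:, None], z <= thr_pos[None, :], z > thr_neg[None, :]).astype(np.int8)
        for ti, t in enumerate(tasks):
            n_rep = int(config.replicate_count.get(t, 1))
            reps = [pred1[:, ti]]
            for _ in range(1, n_rep):
                flip = (rng.random(n) < m.replicate_flip).astype(np.int8)
                reps.append(pred1[:, ti] ^ flip)
            for k, pk in enumerate(reps, start=1):
                pid_col.append(np.asarray(patient_ids))
                model_col.append(np.full(n, m.model_name, dtype=object))
                task_col.append(np.full(n, t, dtype=object))
                rep_col.append(np.full(n, k, dtype=int))
                pred_col.append(pk.astype(int))

    predictions = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_col),
            "model": np.concatenate(model_col),
            "task": np.concatenate(task_col),
            "replicate": np.concatenate(rep_col),
            "prediction": np.concatenate(pred_col),
        }
    )
    patients = pd.DataFrame(
        {"patient_id": patient_ids, "age": ages, "sex": sex, "label": labels}
    )
    return PredictionDataset(
        patients=patients,
        predictions=predictions,
        task_groups={t: task_to_group[t] for t in tasks},
    )


def empirical_profiles(dataset: PredictionDataset) -> pd.DataFrame:
    """Realized sensitivity/specificity per (model, group), replicate 1 only.

    A group with no positive (negative) patients reports NaN sensitivity
    (specificity) rather than 0.
    """
    preds = dataset.predictions[dataset.predictions["replicate"] == 1].copy()
    pat = dataset.patients.set_index("patient_id")
    preds["label"] = pat.loc[preds["patient_id"], "label"].to_numpy()
    preds["group"] = preds["task"].map(dataset.task_groups)
    rows = []
    for (m, g), sub in preds.groupby(["model", "group"]):
        p = sub[sub["label"] == 1]["prediction"]
        q = sub[sub["label"] == 0]["prediction"]
        rows.append(
            {
                "model": m,
                "group": g,
                "sensitivity": p.mean() if len(p) else np.nan,
                "specificity": 1.0 - q.mean() if len(q) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def apply_age_effect(
    dataset: PredictionDataset, spec: AgeEffectSpec, seed: int
) -> PredictionDataset:
    """Re-draw affected raters' predictions with an age-dependent match rate.

    The baseline match probability per (model, task, label) is estimated from
    the input dataset, shifted on the logit scale by
    ``slope * (age - pivot_age)``, and each prediction (every replicate) is
    re-drawn independently.  Unaffected raters are returned bit-identical.
    """
    missing = set(spec.affected_models) - set(dataset.models)
    if missing:
        raise ValueError(f"affected models not in dataset: {sorted(missing)}")
    if not spec.affected_models:
        return PredictionDataset(
            patients=dataset.patients.copy(),
            predictions=dataset.predictions.copy(),
            task_groups=dict(dataset.task_groups),
        )
    rng = np.random.default_rng(seed)
    preds = dataset.predictions.copy()
    pat = dataset.patients.set_index("patient_id")
    label = pat.loc[preds["patient_id"], "label"].to_numpy()
    age = pat.loc[preds["patient_id"], "age"].to_numpy()
    match = (preds["prediction"].to_numpy() == label).astype(float)

    affected = preds["model"].isin(spec.affected_models).to_numpy()
    key = pd.Series(
        list(zip(preds["model"], preds["task"], label)), index=preds.index
    )
    base = pd.Series(match, index=preds.index).groupby(key).transform("mean").to_numpy()
    base = np.clip(base, 1e-6, 1.0 - 1e-6)
    p = expit(logit(base) + spec.slope * (age - spec.pivot_age))
    # one uniform draw per row in canonical order so the result is seed-stable
    order = preds.sort_values(
        ["patient_id", "model", "task", "replicate"], kind="mergesort"
    ).index.to_numpy()
    u = np.empty(len(preds))
    u[order] = rng.random(len(preds))
    new_match = u < p
    new_pred = np.where(new_match, label, 1 - label)
    out = preds["prediction"].to_numpy().copy()
    out[affected] = new_pred[affected]
    preds["prediction"] = out
    return PredictionDataset(
        patients=dataset.patients.copy(),
        predictions=preds,
        task_groups=dict(dataset.task_groups),
    )
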