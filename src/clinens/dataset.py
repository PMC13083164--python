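"""Dataset contract for long-format binary prediction tables.

A prediction table has one row per (patient, model, task, replicate) holding a
binary recommendation (1 = intervention recommended), together with the
per-patient ground-truth label (1 = intervention actually performed), age in
years and sex.  Labels and covariates are repeated across rows and
cross-checked on load, because the endpoint is one actual-treatment outcome
per patient.

Task identifiers are free strings; the conventional nine-task layout T1..T9
is only the default grouping scheme (by input modality), never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order of the interchange CSV
COLUMNS = ["patient_id", "model", "task", "replicate", "prediction", "label", "age", "sex"]

#: columns that must be present in an input file (replicate may be omitted)
REQUIRED_COLUMNS = ["patient_id", "model", "task", "prediction", "label", "age", "sex"]


class DatasetError(ValueError):
    """Base class for dataset contract violations."""


class FormatError(DatasetError):
    """A structural problem with the file: missing column, bad header."""


class ConsistencyError(DatasetError):
    """Per-patient fields (label, age, sex) disagree across rows."""


@dataclass(frozen=True)
class TaskGroupScheme:
    """Partition of task ids into named groups.

    Groups must be disjoint; their union must cover every task of the dataset
    the scheme is applied to.
    """

    groups: dict  # group label -> frozenset of task ids
    description: str = ""

    def __post_init__(self):
        seen = {}
        for g, tasks in self.groups.items():
            for t in tasks:
                if t in seen:
                    raise DatasetError(
                        f"task {t!r} assigned to both groups {seen[t]!r} and {g!r}"
                    )
                seen[t] = g

    def group_of(self, task: str) -> str:
        for g, tasks in self.groups.items():
            if task in tasks:
                return g
        raise KeyError(f"task {task!r} not covered by scheme")

    def task_to_group(self) -> dict:
        return {t: g for g, tasks in self.groups.items() for t in tasks}

    def all_tasks(self) -> set:
        return {t for tasks in self.groups.values() for t in tasks}


def default_scheme() -> TaskGroupScheme:
    """Modality-based default: invasive angiography, CT angiography, multimodal."""
    return TaskGroupScheme(
        groups={
            "CAG": frozenset({"T1", "T4", "T7"}),
            "CTA": frozenset({"T2", "T5", "T8"}),
            "MULTI": frozenset({"T3", "T6", "T9"}),
        },
        description="input-modality triples",
    )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    invariant: str
    detail: str


@dataclass
class PredictionDataset:
    """Per-patient labels/covariates plus the (model, task, replicate) prediction grid.

    Attributes
    ----------
    patients : pandas.DataFrame
        Columns ``patient_id, age, sex, label``; one row per patient.
    predictions : pandas.DataFrame
        Columns ``patient_id, model, task, replicate, prediction``; one row
        per prediction.  ``replicate`` is 1-based.
    task_groups : dict
        Mapping task id -> group label covering every task present.
    """

    patients: pd.DataFrame
    predictions: pd.DataFrame
    task_groups: dict = field(default_factory=dict)

    # -- introspection -----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def models(self) -> list:
        return sorted(self.predictions["model"].unique())

    @property
    def tasks(self) -> list:
        return sorted(self.predictions["task"].unique())

    def replicate_counts(self) -> dict:
        """Max replicate index per (model, task)."""
        g = self.predictions.groupby(["model", "task"])["replicate"].max()
        return g.to_dict()

    def groups(self) -> list:
        return sorted(set(self.task_groups.values()))

    # -- canonical form ----------------------------------------------------
    def canonical_predictions(self) -> pd.DataFrame:
        out = self.predictions.sort_values(
            ["patient_id", "model", "task", "replicate"], kind="mergesort"
        ).reset_index(drop=True)
        return out[["patient_id", "model", "task", "replicate", "prediction"]]

    def canonical_patients(self) -> pd.DataFrame:
        out = self.patients.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
        return out[["patient_id", "age", "sex", "label"]]

    def equals(self, other: "PredictionDataset") -> bool:
        return (
            self.canonical_patients().equals(other.canonical_patients())
            and self.canonical_predictions().equals(other.canonical_predictions())
            and self.task_groups == other.task_groups
        )

    # -- matrix view -------------------------------------------------------
    def matrix(self, tasks=None, replicate: int = 1):
        """Replicate-`replicate` predictions as a (rows x models) matrix.

        Rows are (patient, task) pairs for the requested ``tasks`` (default:
        all).  Returns ``(rows, P, models)`` where ``rows`` is a DataFrame
        with columns ``patient_id, task, label, age, group`` aligned with the
        rows of the int matrix ``P``.
        """
        tasks = sorted(tasks) if tasks is not None else self.tasks
        sub = self.predictions[
            (self.predictions["replicate"] == replicate)
            & (self.predictions["task"].isin(tasks))
        ]
        wide = sub.pivot(index=["patient_id", "task"], columns="model", values="prediction")
        if wide.isna().any().any():
            raise DatasetError("incomplete (patient, model, task) grid in matrix view")
        models = sorted(wide.columns)
        wide = wide[models].sort_index()
        rows = wide.index.to_frame(index=False)
        pat = self.patients.set_index("patient_id")
        rows["label"] = pat.loc[rows["patient_id"], "label"].to_numpy()
        rows["age"] = pat.loc[rows["patient_id"], "age"].to_numpy()
        rows["group"] = rows["task"].map(self.task_groups)
        return rows, wide.to_numpy(dtype=np.int8), models


def validate_dataset(dataset: PredictionDataset) -> list:
    """Check every structural invariant; return a (possibly empty) report.

    Never raises: each violation names the invariant and the offending keys.
    """
    out = []
    pats = dataset.patients
    preds = dataset.predictions

    dup = pats["patient_id"][pats["patient_id"].duplicated()]
    for pid in dup.unique():
        out.append(Violation("uniqueness", f"duplicated patient_id {pid!r}"))

    bad = ~preds["prediction"].isin([0, 1])
    for idx in preds.index[bad]:
        out.append(
            Violation(
                "value_domain",
                f"prediction {preds.loc[idx, 'prediction']!r} outside {{0,1}} at row {idx}",
            )
        )
    badlab = ~pats["label"].isin([0, 1])
    for idx in pats.index[badlab]:
        out.append(
            Violation("value_domain", f"label {pats.loc[idx, 'label']!r} outside {{0,1}}")
        )

    if (preds["replicate"] < 1).any():
        out.append(Violation("replicate_index", "replicate index < 1 present"))

    dupkey = preds.duplicated(["patient_id", "model", "task", "replicate"])
    for _, row in preds[dupkey].iterrows():
        out.append(
            Violation(
                "uniqueness",
                "duplicated prediction row "
                f"({row['patient_id']!r}, {row['model']!r}, {row['task']!r}, rep {row['replicate']})",
            )
        )

    # shared grid: every (model, task) must cover all patients at replicates 1..max
    all_pat = set(pats["patient_id"])
    for (m, t), sub in preds.groupby(["model", "task"]):
        nrep = int(sub["replicate"].max())
        expected = nrep * len(all_pat)
        have = set(zip(sub["patient_id"], sub["replicate"]))
        if len(have) != expected:
            missing_pat = sorted(
                {p for p in all_pat for r in range(1, nrep + 1) if (p, r) not in have}
            )
            for p in missing_pat:
                out.append(Violation("incomplete grid", f"patient {p!r}, model {m!r}, task {t!r}"))

    covered = set(dataset.task_groups)
    for t in dataset.tasks:
        if t not in covered:
            out.append(Violation("task_cover", f"task {t!r} missing from task_groups"))
    return out


def _coerce_binary(series: pd.Series, name: str) -> pd.Series:
    vals = pd.to_numeric(series, errors="coerce")
    bad = ~vals.isin([0, 1]) | vals.isna()
    if bad.any():
        idx = int(series.index[bad][0])
        raise DatasetError(f"{name} value {series[idx]!r} outside {{0,1}} at row {idx}")
    return vals.astype(int)


def load_predictions(path, task_scheme: TaskGroupScheme | None = None) -> PredictionDataset:
    """Read a long-format prediction CSV and return a validated dataset.

    A missing ``replicate`` column defaults every row to replicate 1.  An
    absent ``task_scheme`` defaults to the modality scheme; tasks outside the
    scheme raise a :class:`FormatError`.
    """
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "model": str, "task": str, "sex": str},
        float_precision="round_trip",
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    df["prediction"] = _coerce_binary(df["prediction"], "prediction")
    df["label"] = _coerce_binary(df["label"], "label")
    df["age"] = pd.to_numeric(df["age"])

    per_pat = df.groupby("patient_id")[["label", "age", "sex"]].nunique()
    bad = per_pat[(per_pat > 1).any(axis=1)]
    if len(bad):
        pid = bad.index[0]
        raise ConsistencyError(
            f"patient {pid!r} has inconsistent label/age/sex across rows"
        )

    patients = (
        df.drop_duplicates("patient_id")[["patient_id", "age", "sex", "label"]]
        .reset_index(drop=True)
    )
    predictions = df[["patient_id", "model", "task", "replicate", "prediction"]].copy()

    scheme = task_scheme if task_scheme is not None else default_scheme()
    tasks = set(predictions["task"].unique())
    mapping = scheme.task_to_group()
    uncovered = tasks - set(mapping)
    if uncovered:
        raise FormatError(f"tasks {sorted(uncovered)} not covered by the task scheme")
    ds = PredictionDataset(
        patients=patients,
        predictions=predictions,
        task_groups={t: mapping[t] for t in tasks},
    )
    report = validate_dataset(ds)
    if report:
        raise DatasetError(
            "invalid dataset: " + "; ".join(f"[{v.invariant}] {v.detail}" for v in report[:5])
        )
    return ds


def write_predictions(dataset: PredictionDataset, path) -> None:
    """Write the canonical long-format CSV (deterministic row order)."""
    preds = dataset.canonical_predictions()
    pat = dataset.patients.set_index("patient_id")
    out = preds.copy()
    out["label"] = pat.loc[out["patient_id"], "label"].to_numpy()
    out["age"] = pat.loc[out["patient_id"], "age"].to_numpy()
    out["sex"] = pat.loc[out["patient_id"], "sex"].to_numpy()
    out[COLUMNS].to_csv(path, index=False, float_format="%.17g")
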