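"""Proteochemometric (PCM) and QSAR benchmarking harness.

Bioactivity records (target, compound SMILES, pChEMBL, first-publication
year) are featurized as [compound fingerprint | protein descriptor(s)] rows
and modelled with default-hyperparameter random forests, replicated over ten
fixed seeds.  Validation uses either a seeded 80:20 random split or a
temporal split at a cutoff year (older records train, newer test).  Metrics
are MCC for classification and Pearson r plus RMSE for regression; descriptor
sets are compared with independent two-sample t-tests, and train/test
chemical clustering is quantified with the asymmetric validation embedding
(AVE) bias on compound fingerprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "ACTIVITY_CUTOFF",
    "DEFAULT_SEEDS",
    "TEMPORAL_CUTOFF_YEAR",
    "BioactivityDataset",
    "Split",
    "ModelRunResult",
    "label_activity",
    "split_random",
    "split_temporal",
    "build_feature_table",
    "train_eval_rf",
    "qsar_baseline",
    "metric_mcc",
    "ave_bias",
    "compare_descriptors",
    "top_features",
    "run_benchmark",
]

#: pChEMBL at or above this value counts as active.
ACTIVITY_CUTOFF = 6.5

#: Temporal-split boundary: records first published before this year train.
TEMPORAL_CUTOFF_YEAR = 2013

#: The ten fixed replicate seeds used throughout the benchmark.
DEFAULT_SEEDS = (1234, 2345, 3456, 4567, 5678, 6879, 7890, 8901, 9012, 9999)


@dataclass
class BioactivityDataset:
    """Target-compound-pChEMBL-year records.

    Wraps a DataFrame with columns ``target_id``, ``SMILES``,
    ``pchembl_value``, ``year``; (target, compound) pairs are unique and
    pChEMBL values finite.
    """

    df: pd.DataFrame

    REQUIRED = ("target_id", "SMILES", "pchembl_value", "year")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"missing column {col!r}")
        if len(self.df) == 0:
            raise ValueError("empty dataset")
        if not np.isfinite(self.df["pchembl_value"].to_numpy(float)).all():
            raise ValueError("non-finite pChEMBL values")
        self.df = self.df.reset_index(drop=True)
        self.df["year"] = self.df["year"].astype(int)
        if self.df.duplicated(["target_id", "SMILES"]).any():
            raise ValueError("duplicate (target, compound) pairs")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, float, int]]
    ) -> "BioactivityDataset":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BioactivityDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def targets(self) -> list[str]:
        return sorted(self.df["target_id"].unique())

    def subset(self, rows: np.ndarray) -> "BioactivityDataset":
        return BioactivityDataset(self.df.iloc[rows].reset_index(drop=True))

    def for_target(self, target_id: str) -> "BioactivityDataset":
        mask = self.df["target_id"] == target_id
        if not mask.any():
            raise KeyError(f"target {target_id!r} not in dataset")
        return BioactivityDataset(self.df[mask].reset_index(drop=True))

    def labels(self, task: str) -> np.ndarray:
        y = self.df["pchembl_value"].to_numpy(float)
        return label_activity(y) if task == "classification" else y


def label_activity(pchembl) -> np.ndarray | bool:
    """Binary activity label: active iff pChEMBL >= 6.5 (boundary is active)."""
    arr = np.asarray(pchembl, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("missing/non-finite pChEMBL value")
    out = arr >= ACTIVITY_CUTOFF
    return bool(out) if np.isscalar(pchembl) else out


@dataclass(frozen=True)
class Split:
    """Row positions of an exact train/test partition of a dataset."""

    train_index: np.ndarray
    test_index: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        tr, te = set(self.train_index.tolist()), set(self.test_index.tolist())
        if tr & te:
            raise ValueError("train and test overlap")
        if len(tr) == 0 or len(te) == 0:
            raise ValueError("a split side is empty")


def split_random(
    data: BioactivityDataset, seed: int, train_fraction: float = 0.8
) -> Split:
    """Seeded shuffle into an 80:20 train/test partition."""
    n = len(data)
    if n < 5:
        raise ValueError("need at least 5 records for a random split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(n * train_fraction)
    return Split(
        train_index=np.sort(order[:n_train]),
        test_index=np.sort(order[n_train:]),
        kind="random",
    )


def split_temporal(
    data: BioactivityDataset, cutoff_year: int = TEMPORAL_CUTOFF_YEAR
) -> Split:
    """Deterministic split: years before the cutoff train, the rest test."""
    years = data.df["year"].to_numpy(int)
    train = np.flatnonzero(years < cutoff_year)
    test = np.flatnonzero(years >= cutoff_year)
    if len(train) == 0 or len(test) == 0:
        raise ValueError(
            f"temporal split at {cutoff_year} leaves an empty side "
            f"(years span {years.min()}..{years.max()})"
        )
    return Split(train_index=train, test_index=test, kind="temporal")


def _as_vector(desc) -> tuple[np.ndarray, list[str] | None]:
    """Accept DescriptorVector-like objects or plain arrays."""
    if hasattr(desc, "values") and hasattr(desc, "feature_names"):
        return np.asarray(desc.values, float), list(desc.feature_names)
    arr = np.asarray(desc, dtype=float)
    return arr, None


def build_feature_table(
    data: BioactivityDataset,
    protein_desc: Mapping[str, object] | None,
    compound_desc: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Row per record: [compound fingerprint | protein descriptor block(s)].

    ``protein_desc`` maps a target id to one descriptor or a list of
    descriptors (combination mode concatenates the blocks); ``None`` builds a
    compound-only (QSAR) table.  Column names are preserved so feature
    importances can be traced back.
    """
    smiles = data.df["SMILES"].tolist()
    targets = data.df["target_id"].tolist()
    missing = sorted({s for s in smiles if s not in compound_desc})
    if missing:
        raise KeyError(f"missing compound descriptors for {missing[:3]}...")
    fp0 = np.asarray(compound_desc[smiles[0]], dtype=float)
    fp_names = [f"ECFP6_{i}" for i in range(fp0.shape[0])]
    blocks = [np.vstack([np.asarray(compound_desc[s], dtype=float) for s in smiles])]
    names = list(fp_names)
    if protein_desc is not None:
        missing_t = sorted({t for t in targets if t not in protein_desc})
        if missing_t:
            raise KeyError(f"missing protein descriptors for {missing_t}")
        per_target: dict[str, tuple[np.ndarray, list[str]]] = {}
        for tid in set(targets):
            entry = protein_desc[tid]
            parts = entry if isinstance(entry, (list, tuple)) else [entry]
            vecs, block_names = [], []
            for bi, part in enumerate(parts):
                arr, pnames = _as_vector(part)
                if pnames is None:
                    pnames = [f"P{bi}_{i}" for i in range(arr.shape[0])]
                vecs.append(arr)
                block_names.extend(pnames)
            per_target[tid] = (np.concatenate(vecs), block_names)
        widths = {v[0].shape[0] for v in per_target.values()}
        if len(widths) != 1:
            raise ValueError(f"protein descriptor widths differ: {sorted(widths)}")
        any_names = next(iter(per_target.values()))[1]
        blocks.append(np.vstack([per_target[t][0] for t in targets]))
        names += any_names
    X = np.hstack(blocks)
    if len(names) != len(set(names)):
        names = [f"{nm}#{i}" for i, nm in enumerate(names)]
    return pd.DataFrame(X, columns=names)


@dataclass
class ModelRunResult:
    """One seeded random-forest run: test metrics, CV metrics, importances."""

    task: str
    split_kind: str
    descriptor_name: str
    seed: int
    metrics: dict[str, float]
    cv_metrics: list[dict[str, float]] = field(default_factory=list)
    feature_importances: pd.Series | None = None

    def __post_init__(self) -> None:
        for key, value in self.metrics.items():
            if key in ("mcc", "pearson_r") and not -1 - 1e-9 <= value <= 1 + 1e-9:
                raise ValueError(f"{key}={value} out of range")
            if key == "rmse" and value < 0:
                raise ValueError("negative RMSE")


def metric_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Any zero factor in the denominator (a degenerate observed or predicted
    class) maps to 0 by convention.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, bool)
    y_pred = np.asarray(y_pred, bool)
    tp = int((y_true & y_pred).sum())
    tn = int((~y_true & ~y_pred).sum())
    fp = int((~y_true & y_pred).sum())
    fn = int((y_true & ~y_pred).sum())
    return tp, tn, fp, fn


def _regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        r = 0.0  # correlation undefined for a constant side
    else:
        r = float(stats.pearsonr(y_true, y_pred)[0])
    return {"pearson_r": r, "rmse": rmse}


def _eval(task: str, y_true, y_pred) -> dict[str, float]:
    if task == "classification":
        return {"mcc": metric_mcc(*_confusion(y_true, y_pred))}
    return _regression_metrics(np.asarray(y_true, float), np.asarray(y_pred, float))


def train_eval_rf(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    task: str,
    seed: int,
    split: Split,
    descriptor_name: str = "",
    cv_folds: int = 5,
    cv: bool = True,
) -> ModelRunResult:
    """Default-hyperparameter random forest, seeded, with optional 5-fold CV.

    The seed drives both the fold shuffling of the cross-validation and the
    forest initialization; hyperparameters stay at library defaults.  Test
    metrics come from a forest trained on the full training side; impurity
    feature importances are taken from that same forest.
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(labels)
    tr, te = split.train_index, split.test_index
    if task == "classification" and len(np.unique(y[tr])) < 2:
        raise ValueError("training side has a single class")

    def make_model():
        cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
        return cls(random_state=seed)

    cv_metrics: list[dict[str, float]] = []
    if cv:
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for fold_train, fold_val in kf.split(tr):
            a, b = tr[fold_train], tr[fold_val]
            if task == "classification" and len(np.unique(y[a])) < 2:
                raise ValueError("a CV fold has a single training class")
            model = make_model().fit(X[a], y[a])
            cv_metrics.append(_eval(task, y[b], model.predict(X[b])))
    model = make_model().fit(X[tr], y[tr])
    metrics = _eval(task, y[te], model.predict(X[te]))
    importances = pd.Series(model.feature_importances_, index=matrix.columns)
    return ModelRunResult(
        task=task,
        split_kind=split.kind,
        descriptor_name=descriptor_name,
        seed=seed,
        metrics=metrics,
        cv_metrics=cv_metrics,
        feature_importances=importances,
    )


def qsar_baseline(
    data: BioactivityDataset,
    compound_desc: Mapping[str, np.ndarray],
    task: str,
    seed: int,
    split_rule: str | Callable[[BioactivityDataset, int], Split] = "random",
    metric: str | None = None,
    cv: bool = False,
) -> tuple[float, dict[str, float]]:
    """Single-target (compound-features-only) models, averaged over targets.

    One random forest per target; the per-target test metric is averaged with
    equal weight into a single baseline number.  ``split_rule`` is applied to
    each target's records independently.
    """
    metric = metric or ("mcc" if task == "classification" else "pearson_r")

    def rule(sub: BioactivityDataset) -> Split:
        if callable(split_rule):
            return split_rule(sub, seed)
        if split_rule == "random":
            return split_random(sub, seed)
        if split_rule == "temporal":
            return split_temporal(sub)
        raise ValueError(f"unknown split rule {split_rule!r}")

    per_target: dict[str, float] = {}
    for tid in data.targets:
        sub = data.for_target(tid)
        table = build_feature_table(sub, None, compound_desc)
        res = train_eval_rf(
            table, sub.labels(task), task, seed, rule(sub),
            descriptor_name="QSAR", cv=cv,
        )
        per_target[tid] = res.metrics[metric]
    return float(np.mean(list(per_target.values()))), per_target


def _nearness(queries: np.ndarray, pool: np.ndarray) -> float:
    """Mean over queries of (1 - nearest-neighbour Jaccard distance to pool).

    Equivalent to averaging, over a dense uniform grid of distance thresholds
    on [0, 1], the fraction of queries whose nearest pool member lies within
    the threshold (the thresholded formulation of the AVE definition).
    """
    q = np.asarray(queries, bool)
    p = np.asarray(pool, bool)
    inter = q.astype(np.float64) @ p.T.astype(np.float64)
    union = q.sum(1)[:, None] + p.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        jaccard = np.where(union > 0, inter / union, 1.0)
    nn_dist = 1.0 - jaccard.max(axis=1)
    return float(1.0 - nn_dist.mean())


def ave_bias(
    train_fps: np.ndarray,
    train_labels: np.ndarray,
    test_fps: np.ndarray,
    test_labels: np.ndarray,
) -> float:
    """Asymmetric validation embedding bias of a split, on compound fingerprints.

    ``AVE = [S(test actives, train actives) - S(test actives, train inactives)]
    + [S(test inactives, train inactives) - S(test inactives, train actives)]``
    where S is nearest-neighbour nearness (see ``_nearness``).  Near zero for
    exchangeable splits; positive when test compounds cluster with same-label
    training compounds.  Symmetric under swapping the two class labels
    everywhere.
    """
    train_labels = np.asarray(train_labels, bool)
    test_labels = np.asarray(test_labels, bool)
    if not (
        train_labels.any()
        and (~train_labels).any()
        and test_labels.any()
        and (~test_labels).any()
    ):
        raise ValueError("both splits must contain actives and inactives")
    ta, ti = train_fps[train_labels], train_fps[~train_labels]
    va, vi = test_fps[test_labels], test_fps[~test_labels]
    return (
        _nearness(va, ta) - _nearness(va, ti) + _nearness(vi, ti) - _nearness(vi, ta)
    )


def compare_descriptors(
    metrics_a: Sequence[float], metrics_b: Sequence[float]
) -> dict[str, object]:
    """Two-sided independent t-test between two seed-replicate metric sets.

    Returns both means with SD, the p-value and a star code: ``***`` for
    p < 0.001, ``**`` for p < 0.01, ``*`` for p < 0.05, ``ns`` otherwise.
    """
    a = np.asarray(metrics_a, float)
    b = np.asarray(metrics_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per side")
    if np.std(a) == 0 and np.std(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    stars = "ns"
    for threshold, code in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < threshold:
            stars = code
            break
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "p_value": p,
        "stars": stars,
    }


def top_features(results: Sequence[ModelRunResult], k: int = 25) -> pd.DataFrame:
    """Features ranked by seed-mean impurity importance (ties break by name).

    Returns a DataFrame with columns ``feature``, ``mean_importance``,
    ``sd_importance`` over the supplied seed replicates.
    """
    if not results:
        raise ValueError("no results given")
    frames = []
    names = None
    for res in results:
        if res.feature_importances is None:
            raise ValueError("a result lacks feature importances")
        if names is None:
            names = list(res.feature_importances.index)
        elif list(res.feature_importances.index) != names:
            raise ValueError("feature name sets differ across seeds")
        frames.append(res.feature_importances)
    stack = pd.concat(frames, axis=1)
    out = pd.DataFrame(
        {
            "feature": stack.index,
            "mean_importance": stack.mean(axis=1).to_numpy(),
            "sd_importance": stack.std(axis=1, ddof=0).to_numpy(),
        }
    )
    out = out.sort_values(
        ["mean_importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    return out.head(min(k, len(out)))


def run_benchmark(
    data: BioactivityDataset,
    protein_desc: Mapping[str, object],
    compound_desc: Mapping[str, np.ndarray],
    task: str = "regression",
    split_kind: str = "temporal",
    seeds: Sequence[int] = DEFAULT_SEEDS,
    descriptor_name: str = "3DDPD",
    cv: bool = True,
) -> tuple[list[ModelRunResult], pd.DataFrame]:
    """Seed-replicated PCM benchmark over one descriptor set.

    Returns the per-seed results plus a tidy table (task, split, descriptor,
    seed, metric, value) mirroring the usual supplementary-table layout.
    """
    table = build_feature_table(data, protein_desc, compound_desc)
    y = data.labels(task)
    results = []
    for seed in seeds:
        split = (
            split_random(data, seed)
            if split_kind == "random"
            else split_temporal(data)
        )
        results.append(
            train_eval_rf(
                table, y, task, seed, split, descriptor_name=descriptor_name, cv=cv
            )
        )
    rows = [
        (task, split_kind, descriptor_name, res.seed, metric, value)
        for res in results
        for metric, value in res.metrics.items()
    ]
    tidy = pd.DataFrame(
        rows, columns=["task", "split", "descriptor", "seed", "metric", "value"]
    )
    return results, tidy
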