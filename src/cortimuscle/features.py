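"""Predictor tables, classifier model search and evaluation.

Coupling vectors (M_sCoh or CD) become rows of a predictor table: binary
mode has one row per (subject, task, trial, sEMG channel) with 53 EEG
predictors and label ``is_task_related``; multitask mode concatenates the 4
sEMG channels' vectors per trial (4 x 53 = 212 predictors) with the task id
as label.  An 80/20 stratified split (or leave-one-subject-out) feeds a
budget-bounded model search over seven classifier families -- SVM, k-NN,
decision tree, tree ensemble, naive Bayes, discriminant analysis and
regularized linear -- selecting the (family, hyperparameters) pair that
minimizes k-fold cross-validated classification error, then refitting on
the full training set.  Evaluation reports the confusion counts and

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TN + TP) / (TN + FP + TP + FN)

as percentages (macro one-vs-rest sensitivity/specificity plus overall
accuracy in multitask mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .coherence import CouplingVector
from .simulate import EEG_MONTAGE_53

__all__ = [
    "FeatureTableError",
    "build_table",
    "predictor_columns",
    "split_train_test",
    "ModelSearchResult",
    "model_search",
    "EvalResult",
    "evaluate",
    "metrics_from_confusion",
    "leave_one_subject_out",
]

ID_COLUMNS = ["subject", "task", "trial", "emg_channel", "method", "band"]


class FeatureTableError(ValueError):
    pass


def _channel_names(p: int) -> list[str]:
    if p == len(EEG_MONTAGE_53):
        return list(EEG_MONTAGE_53)
    return [f"EEG{i}" for i in range(p)]


def predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS + ["label"]]


def build_table(coupling: Sequence[CouplingVector],
                mode: str = "binary") -> pd.DataFrame:
    """Assemble the predictor table from coupling vectors.

    ``binary``: label = is_task_related per (trial, sEMG channel).
    ``multitask``: one row per trial, 4 x p concatenated predictors,
    label = task id.
    """
    if not coupling:
        raise FeatureTableError("no coupling vectors given")
    methods = {v.method for v in coupling}
    bands = {v.band for v in coupling}
    if len(methods) > 1 or len(bands) > 1:
        raise FeatureTableError(
            f"mixed methods {methods} or bands {bands} in one table")
    p = len(coupling[0].values)
    names = _channel_names(p)
    if mode == "binary":
        rows = []
        for v in coupling:
            row = {"subject": v.subject_id, "task": v.task_id,
                   "trial": v.trial_id, "emg_channel": v.emg_channel,
                   "method": v.method, "band": v.band, "label": int(v.label)}
            row.update(zip(names, v.values))
            rows.append(row)
        cols = ID_COLUMNS + ["label"] + names
        return pd.DataFrame(rows)[cols]
    if mode == "multitask":
        by_trial: dict[tuple, dict[int, CouplingVector]] = {}
        for v in coupling:
            by_trial.setdefault((v.subject_id, v.task_id, v.trial_id),
                                {})[v.emg_channel] = v
        n_emg = max(max(d) for d in by_trial.values()) + 1
        rows = []
        for (subject, task, trial), d in sorted(by_trial.items()):
            if len(d) != n_emg:
                raise FeatureTableError(
                    f"trial ({subject}, {task}, {trial}) is missing sEMG "
                    f"channels: has {sorted(d)}")
            row = {"subject": subject, "task": task, "trial": trial,
                   "emg_channel": -1, "method": coupling[0].method,
                   "band": coupling[0].band, "label": int(task)}
            for m in range(n_emg):
                row.update({f"{name}_emg{m}": val
                            for name, val in zip(names, d[m].values)})
            rows.append(row)
        pred = [f"{name}_emg{m}" for m in range(n_emg) for name in names]
        cols = ID_COLUMNS + ["label"] + pred
        return pd.DataFrame(rows)[cols]
    raise FeatureTableError(f"unknown mode {mode!r}")


def split_train_test(table: pd.DataFrame, test_frac: float = 0.2,
                     stratify: Sequence[str] = ("label", "subject"),
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, seeded, disjoint train/test split of the feature table."""
    if not (0.0 < test_frac < 1.0):
        raise ValueError("test_frac must lie strictly between 0 and 1")
    strat = table[list(stratify)].astype(str).agg("|".join, axis=1)
    if strat.value_counts().min() < 2:
        strat = table["label"].astype(str)  # fall back to label-only strata
    train, test = train_test_split(table, test_size=test_frac,
                                   random_state=seed, stratify=strat)
    for part, name in ((train, "train"), (test, "test")):
        if part["label"].nunique() < table["label"].nunique():
            raise ValueError(f"a class is absent from the {name} split")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def _family_sampler(rng: np.random.Generator) -> list[tuple[str, dict]]:
    """One hyperparameter draw per classifier family."""
    return [
        ("svm", {"C": 10.0 ** rng.uniform(-2, 2),
                 "gamma": 10.0 ** rng.uniform(-3, 0),
                 "kernel": rng.choice(["rbf", "linear"])}),
        ("knn", {"n_neighbors": int(rng.integers(1, 26)),
                 "weights": rng.choice(["uniform", "distance"])}),
        ("tree", {"max_depth": int(rng.integers(2, 16)),
                  "min_samples_leaf": int(rng.integers(1, 11))}),
        ("ensemble", {"n_estimators": int(rng.integers(50, 201)),
                      "max_features": rng.choice(["sqrt", "log2"])}),
        ("naive_bayes", {"var_smoothing": 10.0 ** rng.uniform(-11, -6)}),
        ("discriminant", {"shrinkage": float(rng.uniform(0, 1))}),
        ("linear", {"C": 10.0 ** rng.uniform(-3, 2)}),
    ]


def _make_estimator(family: str, params: dict, seed: int):
    if family == "svm":
        return _scaled(SVC(C=params["C"], gamma=params["gamma"],
                           kernel=str(params["kernel"]), random_state=seed))
    if family == "knn":
        return _scaled(KNeighborsClassifier(
            n_neighbors=params["n_neighbors"], weights=str(params["weights"])))
    if family == "tree":
        return DecisionTreeClassifier(max_depth=params["max_depth"],
                                      min_samples_leaf=params["min_samples_leaf"],
                                      random_state=seed)
    if family == "ensemble":
        return RandomForestClassifier(n_estimators=params["n_estimators"],
                                      max_features=str(params["max_features"]),
                                      random_state=seed, n_jobs=1)
    if family == "naive_bayes":
        return GaussianNB(var_smoothing=params["var_smoothing"])
    if family == "discriminant":
        return _scaled(LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=params["shrinkage"]))
    if family == "linear":
        return _scaled(LogisticRegression(C=params["C"], max_iter=2000,
                                          random_state=seed))
    raise ValueError(f"unknown family {family!r}")


FAMILIES = ("svm", "knn", "tree", "ensemble", "naive_bayes",
            "discriminant", "linear")


@dataclass
class ModelSearchResult:
    model: object
    family: str
    params: dict
    cv_error: float
    cv_loss_trace: list[tuple[str, float]] = field(default_factory=list)

    def describe(self) -> str:
        return f"{self.family}({self.params})"


def model_search(X: np.ndarray, y: np.ndarray, k: int = 5,
                 budget: int = 28, seed: int = 0) -> ModelSearchResult:
    """Budget-bounded search over families x sampled hyperparameters.

    Every family is tried at least once (round-robin over seeded draws);
    the candidate with the lowest k-fold cross-validated classification
    error wins and is refit on all rows.  Deterministic given ``seed``.
    """
    if budget < len(FAMILIES):
        raise ValueError(
            f"budget {budget} is below the number of families {len(FAMILIES)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"need at least k={k} rows per class; smallest class has "
            f"{counts.min()}")
    rng = np.random.default_rng(seed)
    candidates: list[tuple[str, dict]] = []
    while len(candidates) < budget:
        candidates.extend(_family_sampler(rng))
    candidates = candidates[:budget]
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    best = None
    trace: list[tuple[str, float]] = []
    for i, (family, params) in enumerate(candidates):
        est = _make_estimator(family, params, seed)
        err = 1.0 - cross_val_score(est, X, y, cv=cv,
                                    scoring="accuracy").mean()
        trace.append((family, float(err)))
        if best is None or err < best[0]:
            best = (err, family, params)
    err, family, params = best
    model = _make_estimator(family, params, seed)
    model.fit(X, y)
    return ModelSearchResult(model=model, family=family, params=params,
                             cv_error=float(err), cv_loss_trace=trace)


@dataclass
class EvalResult:
    confusion: np.ndarray          # 2x2 [[TN, FP], [FN, TP]] or KxK
    sensitivity: float             # percent
    specificity: float             # percent
    accuracy: float                # percent
    best_model: str = ""
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0


def metrics_from_confusion(tp: int, tn: int, fp: int,
                           fn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent from the counts."""
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tn + tp) / (tn + fp + tp + fn)
    return sens, spec, acc


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             description: str = "") -> EvalResult:
    """Confusion counts and percentage metrics on held-out rows."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(np.asarray(X_test, dtype=float))
    classes = np.unique(np.concatenate([y_test, pred]))
    if set(classes) <= {0, 1}:
        tp = int(np.sum((pred == 1) & (y_test == 1)))
        tn = int(np.sum((pred == 0) & (y_test == 0)))
        fp = int(np.sum((pred == 1) & (y_test == 0)))
        fn = int(np.sum((pred == 0) & (y_test == 1)))
        sens, spec, acc = metrics_from_confusion(tp, tn, fp, fn)
        return EvalResult(confusion=np.array([[tn, fp], [fn, tp]]),
                          sensitivity=sens, specificity=spec, accuracy=acc,
                          best_model=description, tp=tp, tn=tn, fp=fp, fn=fn)
    # multiclass: macro one-vs-rest sensitivity/specificity, overall accuracy
    K = len(classes)
    conf = np.zeros((K, K), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, pr in zip(y_test, pred):
        conf[index[t], index[pr]] += 1
    sens_k, spec_k = [], []
    total = conf.sum()
    for i in range(K):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        s, p, _ = metrics_from_confusion(tp, tn, fp, fn)
        sens_k.append(s)
        spec_k.append(p)
    acc = 100.0 * np.trace(conf) / total
    return EvalResult(confusion=conf, sensitivity=float(np.mean(sens_k)),
                      specificity=float(np.mean(spec_k)), accuracy=float(acc),
                      best_model=description)


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = predictor_columns(table)
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy()


def train_and_evaluate(train: pd.DataFrame, test: pd.DataFrame, k: int = 5,
                       budget: int = 28, seed: int = 0) -> EvalResult:
    """Model search on ``train``, metrics on ``test``."""
    Xtr, ytr = _xy(train)
    Xte, yte = _xy(test)
    res = model_search(Xtr, ytr, k=k, budget=budget, seed=seed)
    return evaluate(res.model, Xte, yte, description=res.describe())


def leave_one_subject_out(
    tables: pd.DataFrame | Sequence[tuple[int, pd.DataFrame]] | Mapping[int, pd.DataFrame],
    k: int = 5, budget: int = 28, seed: int = 0,
) -> dict[int, EvalResult]:
    """One model search + evaluation per held-out subject.

    Accepts the combined feature table or per-subject tables; duplicate
    subject ids in a sequence are an error.  Training rows never include
    the held-out subject (audited by id).
    """
    if isinstance(tables, pd.DataFrame):
        per_subject = {int(s): g for s, g in tables.groupby("subject")}
    elif isinstance(tables, Mapping):
        per_subject = {int(s): t for s, t in tables.items()}
    else:
        per_subject = {}
        for s, t in tables:
            if int(s) in per_subject:
                raise ValueError(f"duplicate subject id {s}")
            per_subject[int(s)] = t
    if len(per_subject) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    results: dict[int, EvalResult] = {}
    for held_out in sorted(per_subject):
        test = per_subject[held_out]
        train = pd.concat([t for s, t in per_subject.items() if s != held_out],
                          ignore_index=True)
        assert held_out not in set(train["subject"]), "subject leakage"
        if test["label"].nunique() < 2 and test["label"].nunique() < train["label"].nunique():
            # single-class held-out subject: metrics partially undefined
            Xtr, ytr = _xy(train)
            res = model_search(Xtr, ytr, k=k, budget=budget, seed=seed)
            ev = evaluate(res.model, *_xy(test), description=res.describe())
            ev.best_model += " [single-class test subject]"
            results[held_out] = ev
            continue
        results[held_out] = train_and_evaluate(train, test, k=k,
                                               budget=budget, seed=seed)
    return results


def summarize_loso(results: Mapping[int, EvalResult]) -> pd.DataFrame:
    """Per-subject metric table with a mean/SD footer."""
    rows = [{"subject": s, "sensitivity": r.sensitivity,
             "specificity": r.specificity, "accuracy": r.accuracy,
             "best_model": r.best_model} for s, r in sorted(results.items())]
    df = pd.DataFrame(rows)
    return df
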