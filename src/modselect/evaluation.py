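"""Classification evaluation: subject-level nested CV for six FBN schemes.

The unit of prediction is a scan, but folds are assigned by *subject*: all
scans of a subject land on one side of every split, so train and test are
independent even when subjects have repeat scans.

Six schemes are compared, differing in feature granularity and selector:

* ``global``      - global clustering coefficient (1 feature, no selection)
* ``node-ttest``  - node statistics filtered by a two-sample t-test
* ``node-lasso``  - node statistics selected by flat LASSO
* ``edge-ttest``  - edge weights filtered by a two-sample t-test
* ``edge-lasso``  - edge weights selected by flat LASSO
* ``mlfs``        - edge weights selected by the modularity-induced group
                    LASSO, with modules discovered by signed spectral
                    clustering of the mean control-group network of the
                    training fold only.

Every scheme feeds a linear SVM (C = 1).  The selector hyperparameter (a
p-value threshold for the t-test; a fraction of lambda_max for the LASSO
variants) is chosen by an inner subject-level CV on the training fold,
maximising inner accuracy with ties broken toward the sparser model.
Metrics are ACC/SEN/SPE in percent plus AUC from the SVM decision values.

A leakage audit trail records, for every outer fold, exactly which scans the
module partition, the feature selection and the classifier were fitted on;
tests assert these are training-fold scans only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .grouping import build_design, vectorize_edges
from .modules import ModulePartition, consensus_partition
from .netstats import global_clustering, node_statistics
from .selection import GroupLasso, lasso_select, ttest_select

__all__ = [
    "CohortManifest",
    "EvaluationReport",
    "SCHEMES",
    "DEFAULT_GRID",
    "subject_kfold",
    "compute_metrics",
    "nested_cv",
    "repeated_evaluation",
    "bootstrap_ensemble",
]

SCHEMES = ("global", "node-ttest", "node-lasso", "edge-ttest", "edge-lasso", "mlfs")
# the 11 candidate hyperparameter values swept in the inner CV
DEFAULT_GRID = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class CohortManifest:
    """Scan-to-subject-to-label mapping for one cohort.

    ``scans`` is a list of (scan_id, subject_id, label); ``positive`` and
    ``negative`` designate the two class labels (positive = patients).
    """

    scans: list[tuple[str, str, str]]
    positive: str
    negative: str

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        labels = set()
        for scan_id, subject, label in self.scans:
            labels.add(label)
            if subject in seen and seen[subject] != label:
                raise ValueError(f"subject {subject} has conflicting labels")
            seen[subject] = label
        if labels - {self.positive, self.negative}:
            raise ValueError(f"unknown labels: {labels - {self.positive, self.negative}}")
        if self.positive not in labels or self.negative not in labels:
            raise ValueError("both classes must be present")

    @property
    def scan_ids(self) -> list[str]:
        return [s for s, _, _ in self.scans]

    @property
    def subjects(self) -> dict[str, str]:
        return {subj: lab for _, subj, lab in self.scans}

    def label_of(self, scan_id: str) -> str:
        for s, _, lab in self.scans:
            if s == scan_id:
                return lab
        raise KeyError(scan_id)

    def y(self, scan_ids) -> np.ndarray:
        """Labels coded +1 (positive class) / -1 for the given scans."""
        lab = {s: l for s, _, l in self.scans}
        return np.array([1.0 if lab[s] == self.positive else -1.0 for s in scan_ids])

    def subject_of(self, scan_id: str) -> str:
        for s, subj, _ in self.scans:
            if s == scan_id:
                return subj
        raise KeyError(scan_id)

    def swapped(self) -> "CohortManifest":
        """Same cohort with the positive/negative designation reversed."""
        return CohortManifest(list(self.scans), self.negative, self.positive)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scans, columns=["scan_id", "subject_id", "label"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, positive: str, negative: str):
        scans = [
            (str(r.scan_id), str(r.subject_id), str(r.label)) for r in df.itertuples()
        ]
        return cls(scans, positive, negative)


def subject_kfold(M: CohortManifest, folds: int, seed: int):
    """Subject-level k-fold split: scans of one subject never straddle folds.

    Subjects are shuffled within class and dealt round-robin into folds with
    a running pointer across classes, so fold subject counts differ by at
    most one and classes stay balanced.  Returns a list of
    (train_scan_ids, test_scan_ids) pairs.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    subjects = M.subjects
    if len(subjects) < folds:
        raise ValueError(f"need at least {folds} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    fold_subjects: list[list[str]] = [[] for _ in range(folds)]
    pointer = 0
    for label in sorted({lab for lab in subjects.values()}):
        members = sorted(s for s, lab in subjects.items() if lab == label)
        rng.shuffle(members)
        for s in members:
            fold_subjects[pointer % folds].append(s)
            pointer += 1
    by_subject: dict[str, list[str]] = {}
    for scan_id, subj, _ in M.scans:
        by_subject.setdefault(subj, []).append(scan_id)
    splits = []
    for f in range(folds):
        test_subj = set(fold_subjects[f])
        test = [s for s, subj, _ in M.scans if subj in test_subj]
        train = [s for s, subj, _ in M.scans if subj not in test_subj]
        splits.append((train, test))
    return splits


def compute_metrics(y_true, y_pred, scores=None):
    """ACC/SEN/SPE/AUC in percent from +1/-1 labels and decision scores.

    SEN is the recall of the positive (+1, patient) class, SPE of the
    negative class.  AUC uses the trapezoidal ROC on ``scores``; with a
    single class in ``y_true`` AUC is reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    acc = 100.0 * np.mean(y_true == y_pred)
    pos, neg = y_true > 0, y_true < 0
    sen = 100.0 * np.mean(y_pred[pos] > 0) if pos.any() else np.nan
    spe = 100.0 * np.mean(y_pred[neg] < 0) if neg.any() else np.nan
    auc = np.nan
    if scores is not None and pos.any() and neg.any():
        auc = 100.0 * roc_auc_score(y_true > 0, np.asarray(scores, dtype=float))
    return float(acc), float(sen), float(spe), float(auc)


# ---------------------------------------------------------------------------
# scheme fitting


@dataclass
class SchemeConfig:
    """One of the six comparison schemes plus its knobs."""

    name: str
    k_modules: int = 4
    node_statistic: str = "LCC"
    estimator_tag: str = "pearson_z"
    group_weight: str = "sqrt"

    def __post_init__(self) -> None:
        if self.name not in SCHEMES:
            raise ValueError(f"unknown scheme {self.name!r}; choose from {SCHEMES}")

    @property
    def needs_partition(self) -> bool:
        return self.name == "mlfs"

    @property
    def sparser_is_larger(self) -> bool:
        """Whether a larger hyperparameter value means a sparser model."""
        return self.name in ("node-lasso", "edge-lasso", "mlfs")


class _FeatureCache:
    """Per-cohort feature matrices, computed once per scheme granularity."""

    def __init__(self, networks: dict[str, np.ndarray], node_statistic: str):
        self.networks = networks
        self.node_statistic = node_statistic
        self._cache: dict[str, dict[str, np.ndarray]] = {}

    def features(self, kind: str) -> dict[str, np.ndarray]:
        if kind not in self._cache:
            if kind == "global":
                feats = {s: np.array([global_clustering(W)]) for s, W in self.networks.items()}
            elif kind == "node":
                feats = {
                    s: node_statistics(W, self.node_statistic)
                    for s, W in self.networks.items()
                }
            elif kind == "edge":
                feats = {s: vectorize_edges(W) for s, W in self.networks.items()}
            else:
                raise ValueError(kind)
            self._cache[kind] = feats
        return self._cache[kind]


@dataclass
class _FittedScheme:
    """A trained selection + SVM pipeline for one training set."""

    scheme: SchemeConfig
    feature_kind: str
    selected: np.ndarray
    svm: SVC | None
    majority: float
    design_meta: object = None

    def _matrix(self, cache: _FeatureCache, scan_ids) -> np.ndarray:
        feats = cache.features(self.feature_kind)
        return np.stack([feats[s] for s in scan_ids])

    def predict(self, cache: _FeatureCache, scan_ids):
        if self.svm is None:  # degenerate empty selection: majority vote
            pred = np.full(len(scan_ids), self.majority)
            return pred, np.zeros(len(scan_ids))
        X = self._matrix(cache, scan_ids)[:, self.selected]
        return self.svm.predict(X), self.svm.decision_function(X)


def _fit_scheme(scheme: SchemeConfig, cache: _FeatureCache, manifest: CohortManifest,
                train_ids, param: float, partition: ModulePartition | None,
                audit: list | None = None) -> _FittedScheme:
    kind = {"global": "global", "node-ttest": "node", "node-lasso": "node",
            "edge-ttest": "edge", "edge-lasso": "edge", "mlfs": "edge"}[scheme.name]
    feats = cache.features(kind)
    X = np.stack([feats[s] for s in train_ids])
    y = manifest.y(train_ids)

    if scheme.name == "global":
        selected = np.arange(X.shape[1])
    elif scheme.name in ("node-ttest", "edge-ttest"):
        selected = ttest_select(X, y, alpha=param)
    elif scheme.name in ("node-lasso", "edge-lasso"):
        model = GroupLasso(y, X)
        lam = max(param, 1e-6) * model.lambda_max
        selected = model.fit(lam).selected
    else:  # mlfs: group LASSO on the partition-grouped edge ordering
        assert partition is not None
        nets = [cache.networks[s] for s in train_ids]
        design = build_design(nets, partition)
        model = GroupLasso(y, design, group_weight=scheme.group_weight)
        lam = max(param, 1e-6) * model.lambda_max
        res = model.fit(lam)
        # map grouped feature indices back to plain edge-vector indices
        m = partition.n_nodes
        flat_index = {}
        pos = 0
        for i in range(m):
            for j in range(i + 1, m):
                flat_index[(i, j)] = pos
                pos += 1
        selected = np.array(
            sorted(flat_index[design.edge_map[int(j)]] for j in res.selected), dtype=int
        )
    if audit is not None:
        audit.append(("selection", tuple(train_ids)))
    if len(selected) == 0:
        majority = 1.0 if (y > 0).sum() >= (y < 0).sum() else -1.0
        return _FittedScheme(scheme, kind, selected, None, majority)
    svm = SVC(kernel="linear", C=1.0)
    svm.fit(X[:, selected], y)
    if audit is not None:
        audit.append(("classifier", tuple(train_ids)))
    return _FittedScheme(scheme, kind, selected, svm, 0.0)


def _inner_select_param(scheme, cache, manifest, train_ids, grid, inner_folds,
                        seed, partition):
    """Inner subject-level CV over the hyperparameter grid; returns best value."""
    if scheme.name == "global" or len(grid) == 1:  # nothing to tune
        return grid[0], np.full(len(grid), np.nan)
    sub_manifest = CohortManifest(
        [s for s in manifest.scans if s[0] in set(train_ids)],
        manifest.positive, manifest.negative,
    )
    inner_splits = subject_kfold(sub_manifest, inner_folds, seed)
    accs = []
    for param in grid:
        correct = total = 0
        for inner_train, inner_val in inner_splits:
            yv = manifest.y(inner_val)
            if len(np.unique(manifest.y(inner_train))) < 2:
                continue  # degenerate inner fold; skip (stratified dealing avoids this)
            fitted = _fit_scheme(scheme, cache, manifest, inner_train, param, partition)
            pred, _ = fitted.predict(cache, inner_val)
            correct += int((pred == yv).sum())
            total += len(yv)
        accs.append(correct / total if total else 0.0)
    accs = np.array(accs)
    best = np.flatnonzero(accs == accs.max())
    # ties go to the sparser model: larger lambda, smaller alpha
    idx = best[-1] if scheme.sparser_is_larger else best[0]
    return grid[idx], accs


@dataclass
class FoldOutcome:
    """Per-outer-fold artefacts of a nested-CV run."""

    train_ids: list[str]
    test_ids: list[str]
    param: float
    selected: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    partition: ModulePartition | None = None
    audit: list = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Per-repetition metrics with summaries and paired significance tests.

    ``metrics`` is a tidy DataFrame with columns method, repetition, ACC,
    SEN, SPE, AUC (percent).
    """

    metrics: pd.DataFrame
    folds: dict = field(default_factory=dict)
    stable_features: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric per method."""
        return self.metrics.groupby("method")[["ACC", "SEN", "SPE", "AUC"]].agg(
            ["mean", "std"]
        )

    def paired_tests(self, reference: str) -> pd.DataFrame:
        """Paired two-sided t-tests of per-repetition ACC vs ``reference``.

        A method paired with itself (or with a constant zero difference) is
        flagged degenerate and never significant.
        """
        ref = self.metrics[self.metrics.method == reference].sort_values("repetition")
        rows = []
        for method in self.metrics.method.unique():
            if method == reference:
                rows.append((method, np.nan, np.nan, False, True))
                continue
            other = self.metrics[self.metrics.method == method].sort_values("repetition")
            diff = ref.ACC.to_numpy() - other.ACC.to_numpy()
            if np.allclose(diff, 0.0):
                # identical per-repetition results: no evidence either way
                rows.append((method, np.nan, np.nan, False, True))
                continue
            if np.std(diff) == 0:
                # constant nonzero offset: infinitely strong paired evidence
                t = np.inf * np.sign(diff[0])
                rows.append((method, float(t), 0.0, True, False))
                continue
            t, p = stats.ttest_rel(ref.ACC.to_numpy(), other.ACC.to_numpy())
            rows.append((method, float(t), float(p), bool(p < 0.05), False))
        return pd.DataFrame(
            rows, columns=["method", "t", "p", "significant", "degenerate"]
        )


def nested_cv(networks: dict[str, np.ndarray], manifest: CohortManifest,
              scheme: SchemeConfig, grid=DEFAULT_GRID, folds: int = 5,
              inner_folds: int = 5, seed: int = 0, splits=None,
              collect_audit: bool = False):
    """Nested subject-level cross-validation of one scheme.

    Outer folds estimate generalisation; an inner CV on each training fold
    picks the selector hyperparameter.  For the ``mlfs`` scheme the module
    partition is discovered from the *training-fold control-class* networks
    only.  Returns (EvaluationReport-row metrics tuple, list of FoldOutcome).
    """
    cache = _FeatureCache(networks, scheme.node_statistic)
    if splits is None:
        splits = subject_kfold(manifest, folds, seed)
    outcomes = []
    y_true_all, y_pred_all, scores_all = [], [], []
    for fold_i, (train_ids, test_ids) in enumerate(splits):
        audit: list = []
        partition = None
        if scheme.needs_partition:
            controls = [
                s for s in train_ids if manifest.label_of(s) == manifest.negative
            ]
            partition = consensus_partition(
                [networks[s] for s in controls], scheme.k_modules, seed=seed
            )
            audit.append(("partition", tuple(controls)))
        param, _ = _inner_select_param(
            scheme, cache, manifest, train_ids, grid, inner_folds,
            seed + 1000 + fold_i, partition,
        )
        fitted = _fit_scheme(
            scheme, cache, manifest, train_ids, param, partition, audit=audit,
        )
        pred, scores = fitted.predict(cache, test_ids)
        y_true = manifest.y(test_ids)
        outcomes.append(FoldOutcome(
            list(train_ids), list(test_ids), param, fitted.selected,
            y_true, pred, scores, partition, audit,
        ))
        y_true_all.append(y_true)
        y_pred_all.append(pred)
        scores_all.append(scores)
    metrics = compute_metrics(
        np.concatenate(y_true_all), np.concatenate(y_pred_all),
        np.concatenate(scores_all),
    )
    return metrics, outcomes


def stable_features(outcomes) -> set:
    """Features selected in every fold (the most discriminative set)."""
    sets = [set(map(int, o.selected)) for o in outcomes]
    return set.intersection(*sets) if sets else set()


def repeated_evaluation(networks, manifest, schemes, grid=DEFAULT_GRID,
                        reps: int = 10, folds: int = 5, inner_folds: int = 5,
                        base_seed: int = 0, cohort_factory=None) -> EvaluationReport:
    """Repeat the fold partition and nested CV; all schemes share each
    repetition's fold assignment (pairing for the significance tests).

    ``cohort_factory(rep_seed) -> (networks, manifest)``, when given,
    regenerates the cohort each repetition (simulation studies); otherwise
    the fixed cohort is re-partitioned only, as with a real dataset.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    rows = []
    fold_log: dict = {}
    for rep in range(reps):
        rep_seed = base_seed + rep
        if cohort_factory is not None:
            networks_r, manifest_r = cohort_factory(rep_seed)
        else:
            networks_r, manifest_r = networks, manifest
        splits = subject_kfold(manifest_r, folds, rep_seed)
        for scheme in schemes:
            (acc, sen, spe, auc), outcomes = nested_cv(
                networks_r, manifest_r, scheme, grid, folds, inner_folds,
                seed=rep_seed, splits=splits,
            )
            rows.append({"method": scheme.name, "repetition": rep,
                         "ACC": acc, "SEN": sen, "SPE": spe, "AUC": auc})
            fold_log[(scheme.name, rep)] = outcomes
    report = EvaluationReport(pd.DataFrame(rows), fold_log)
    for scheme in schemes:
        last = fold_log[(scheme.name, reps - 1)]
        report.stable_features[scheme.name] = stable_features(last)
    return report


def bootstrap_ensemble(networks, manifest, scheme: SchemeConfig, n_boot: int = 10,
                       grid=DEFAULT_GRID, folds: int = 5, inner_folds: int = 5,
                       seed: int = 0, resample: bool = True):
    """Nested CV with a bagged classifier per outer fold.

    Each outer fold draws ``n_boot`` bootstrap resamples of the *training
    subjects* (same subject count, with replacement), trains one selection +
    SVM per resample at the fold's inner-CV-chosen hyperparameter, and
    aggregates test predictions by majority vote (scores: mean decision
    value).  With ``resample=False`` and n_boot=1 this reduces to plain
    nested CV.  A resample missing a class is redrawn (capped retries).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cache = _FeatureCache(networks, scheme.node_statistic)
    rng = np.random.default_rng(seed)
    splits = subject_kfold(manifest, folds, seed)
    y_true_all, y_pred_all, scores_all = [], [], []
    for fold_i, (train_ids, test_ids) in enumerate(splits):
        partition = None
        if scheme.needs_partition:
            controls = [s for s in train_ids if manifest.label_of(s) == manifest.negative]
            partition = consensus_partition(
                [networks[s] for s in controls], scheme.k_modules, seed=seed
            )
        param, _ = _inner_select_param(
            scheme, cache, manifest, train_ids, grid, inner_folds,
            seed + 1000 + fold_i, partition,
        )
        subjects = sorted({manifest.subject_of(s) for s in train_ids})
        by_subject: dict[str, list[str]] = {}
        for s in train_ids:
            by_subject.setdefault(manifest.subject_of(s), []).append(s)
        votes = np.zeros(len(test_ids))
        score_sum = np.zeros(len(test_ids))
        for b in range(n_boot):
            if resample:
                for _ in range(100):
                    draw = rng.choice(subjects, size=len(subjects), replace=True)
                    ids = [s for subj in draw for s in by_subject[subj]]
                    if len(np.unique(manifest.y(ids))) == 2:
                        break
                else:
                    raise RuntimeError("could not draw a two-class bootstrap sample")
            else:
                ids = list(train_ids)
            fitted = _fit_scheme(scheme, cache, manifest, ids, param, partition)
            pred, scores = fitted.predict(cache, test_ids)
            votes += pred
            score_sum += scores
        y_pred = np.where(votes >= 0, 1.0, -1.0)
        y_true_all.append(manifest.y(test_ids))
        y_pred_all.append(y_pred)
        scores_all.append(score_sum / n_boot)
    return compute_metrics(
        np.concatenate(y_true_all), np.concatenate(y_pred_all),
        np.concatenate(scores_all),
    )
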