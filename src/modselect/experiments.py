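"""Canned validation experiments for the pipeline.

Each function regenerates its inputs from the synthetic generators, runs the
relevant pipeline stage and measures the outcome.  They back both the
property-based test suite and the reproduction script, so the measured
quantities are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.metrics import adjusted_rand_score

from .evaluation import SchemeConfig, nested_cv, repeated_evaluation
from .fbn import ConnectivityMatrix, add_edge_noise
from .grouping import vectorize_grouped
from .modules import (
    ModulePartition,
    signed_normalized_laplacian,
    signed_spectral_clustering,
    sncut,
)
from .selection import GroupLasso
from .synthetic import (
    SyntheticSpec,
    generate_cohort,
    generate_edge_cohort,
    sbm_network,
    worked_example,
)

__all__ = [
    "edge_dimension",
    "laplacian_spectrum_extremes",
    "sncut_optimality_ratio",
    "planted_partition_ari",
    "solver_checks",
    "worked_example_support",
    "null_calibration",
    "paired_test_rejection_rate",
    "leakage_audit",
    "noise_robustness",
]


def edge_dimension(m: int = 116, K: int = 10, seed: int = 0) -> int:
    """Length of the grouped edge vector for an m-region network."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=m)
    labels[:K] = np.arange(K)
    P = ModulePartition(labels, K)
    vec, design = vectorize_grouped(np.zeros((m, m)), P)
    assert design.group_sizes.sum() == len(vec)
    return len(vec)


def laplacian_spectrum_extremes(n_networks: int = 1000, max_m: int = 50,
                                seed: int = 0):
    """(min, max) eigenvalue over many random signed normalized Laplacians."""
    rng = np.random.default_rng(seed)
    lo, hi = np.inf, -np.inf
    for _ in range(n_networks):
        m = int(rng.integers(4, max_m + 1))
        A = rng.uniform(-1, 1, size=(m, m))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0.0)
        lam = signed_normalized_laplacian(W).eigenvalues()
        lo, hi = min(lo, lam.min()), max(hi, lam.max())
    return float(lo), float(hi)


def _partitions_into_k(m: int, K: int):
    def rec(i, labels, used):
        if i == m:
            if used == K:
                yield np.array(labels)
            return
        if used + (m - i) < K:
            return
        for lab in range(min(used + 1, K)):
            labels.append(lab)
            yield from rec(i + 1, labels, max(used, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def sncut_optimality_ratio(n_instances: int = 50, seed: int = 0) -> float:
    """Worst ratio of the spectral partition's sNcut to the exhaustive
    minimum over signed planted-partition instances with m <= 8, K <= 3."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        m = int(rng.choice([6, 7, 8]))
        K = int(rng.choice([2, 3]))
        sigma = float(rng.choice([0.05, 0.1, 0.2]))
        W = sbm_network(m, K, within=0.5, between=-0.2, sigma=sigma,
                        seed=int(rng.integers(2**31)))
        P = signed_spectral_clustering(W, K, seed=0)
        val = sncut(W, P)
        best = min(sncut(W, ModulePartition(lab, K))
                   for lab in _partitions_into_k(m, K))
        worst = max(worst, val / best if best > 1e-12 else 1.0)
    return float(worst)


def planted_partition_ari(m: int = 60, K: int = 4, within: float = 0.4,
                          between: float = -0.1, sigma: float = 0.1,
                          n_seeds: int = 20, seed: int = 0) -> float:
    """Mean adjusted Rand index of signed spectral clustering on the signed
    stochastic block model."""
    rng = np.random.default_rng(seed)
    truth = np.concatenate(
        [np.full(len(b), k) for k, b in enumerate(np.array_split(np.arange(m), K))]
    )
    aris = []
    for _ in range(n_seeds):
        W = sbm_network(m, K, within, between, sigma, seed=int(rng.integers(2**31)))
        P = signed_spectral_clustering(W, K, seed=0)
        aris.append(adjusted_rand_score(truth, P.labels))
    return float(np.mean(aris))


def solver_checks(n_instances: int = 20, n: int = 50, d: int = 100,
                  seed: int = 0) -> dict:
    """Solver correctness: KKT residual ratio, exact zero at lambda_max and
    worst coefficient gap to an independent coordinate-descent L1 oracle."""
    rng = np.random.default_rng(seed)
    worst_gap = 0.0
    worst_kkt = 0.0
    zero_ok = True
    for _ in range(n_instances):
        X = rng.standard_normal((n, d))
        y = np.sign(rng.standard_normal(n))
        model = GroupLasso(y, X)
        lmax = model.lambda_max
        lam = 0.3 * lmax
        res = model.fit(lam, tol=1e-14, max_iter=50000)
        scale = np.abs(X.T @ (y - y.mean())).max()
        worst_kkt = max(worst_kkt, res.kkt_residual / scale)
        oracle = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-14,
                       max_iter=500000).fit(X, y - y.mean())
        worst_gap = max(worst_gap, float(np.abs(res.params - oracle.coef_).max()))
        zero_ok = zero_ok and bool(np.all(model.fit(lmax).params == 0))
    return {"kkt_ratio": worst_kkt, "lasso_gap": worst_gap, "zero_at_lambda_max": zero_ok}


def worked_example_support(seed: int = 0) -> dict:
    """MLFS support recovery on the bundled worked-example cohort.

    Runs nested CV (penalty chosen by the inner CV) and reports, per outer
    fold, whether all planted edges were selected and how many edges were
    selected in total.
    """
    cohort, _ = worked_example()
    nets = cohort.networks()
    scheme = SchemeConfig("mlfs", k_modules=cohort.spec.K_true)
    (acc, sen, spe, auc), outcomes = nested_cv(nets, cohort.manifest, scheme,
                                               seed=seed)
    m = cohort.spec.m
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    planted = {tuple(e) for e in cohort.effect_edges}
    per_fold = []
    for o in outcomes:
        sel = {pairs[int(j)] for j in o.selected}
        per_fold.append({"n_selected": len(sel), "planted_recovered": planted <= sel})
    return {
        "acc": acc,
        "auc": auc,
        "max_selected": max(f["n_selected"] for f in per_fold),
        "all_planted_recovered": all(f["planted_recovered"] for f in per_fold),
        "folds": per_fold,
    }


def _null_cohort_factory(m=16, K=4, n_per_class=20, edge_sigma=0.1):
    def factory(rep_seed):
        spec = SyntheticSpec(m=m, K_true=K, n_per_class=n_per_class,
                             effect_size=0.0, subject_sigma=0.05, seed=rep_seed)
        cohort = generate_edge_cohort(spec, edge_sigma=edge_sigma)
        return cohort.networks(), cohort.manifest

    return factory


def null_calibration(reps: int = 10, seed: int = 0, m: int = 16) -> dict:
    """Mean ACC (+/- SE) of all six schemes on null cohorts.

    Every repetition draws a fresh cohort with no class effect, so each
    scheme should sit at chance.  Returns per-scheme mean ACC, SE and the
    within-band flag |mean - 50| <= 2 SE.
    """
    schemes = [SchemeConfig(name, k_modules=4) for name in
               ("global", "node-ttest", "node-lasso", "edge-ttest",
                "edge-lasso", "mlfs")]
    report = repeated_evaluation(None, None, schemes, reps=reps, base_seed=seed,
                                 cohort_factory=_null_cohort_factory(m=m))
    out = {}
    for name in [s.name for s in schemes]:
        acc = report.metrics[report.metrics.method == name].ACC.to_numpy()
        mean = float(acc.mean())
        se = float(acc.std(ddof=1) / np.sqrt(len(acc)))
        out[name] = {"mean_acc": mean, "se": se,
                     "within_band": bool(abs(mean - 50.0) <= 2 * se)}
    return out


def paired_test_rejection_rate(n_meta: int = 200, reps: int = 5,
                               seed: int = 0) -> float:
    """Fraction of meta-repetitions in which the paired t-test between two
    null methods rejects at p < 0.05 (should be ~5%)."""
    schemes = [SchemeConfig("edge-ttest"), SchemeConfig("node-ttest")]
    factory = _null_cohort_factory(m=12)
    rejections = 0
    for meta in range(n_meta):
        base = seed + 100_000 + meta * 1_000
        report = repeated_evaluation(None, None, schemes, grid=(0.05,),
                                     reps=reps, base_seed=base,
                                     cohort_factory=factory)
        row = report.paired_tests("edge-ttest").set_index("method").loc["node-ttest"]
        if bool(row.significant):
            rejections += 1
    return rejections / n_meta


def leakage_audit(seed: int = 0) -> dict:
    """Audit one nested-CV run: every fitted artefact (module partition,
    selected features, classifier) must derive from training-fold scans only,
    and train/test subject sets must be disjoint."""
    spec = SyntheticSpec(m=12, K_true=3, n_per_class=12, scans_per_subject=2,
                         seed=seed)
    cohort = generate_cohort(spec)
    nets = cohort.networks()
    manifest = cohort.manifest
    _, outcomes = nested_cv(nets, manifest, SchemeConfig("mlfs", k_modules=3),
                            seed=seed)
    clean = True
    for o in outcomes:
        train, test = set(o.train_ids), set(o.test_ids)
        train_subj = {manifest.subject_of(s) for s in train}
        test_subj = {manifest.subject_of(s) for s in test}
        if train_subj & test_subj:
            clean = False
        for _, scans in o.audit:
            if not set(scans) <= train:
                clean = False
        sources = dict(o.audit)
        if not all(manifest.label_of(s) == manifest.negative
                   for s in sources["partition"]):
            clean = False
    return {"clean": clean, "n_folds": len(outcomes)}


def noise_robustness(sigmas=(0.0, 0.1, 0.2, 0.4, 0.8), reps: int = 5,
                     seed: int = 0) -> dict:
    """Mean MLFS accuracy on the worked-example cohort after adding
    symmetric Gaussian edge noise of each SD to every network."""
    cohort, _ = worked_example()
    nets = cohort.networks()
    scheme = SchemeConfig("mlfs", k_modules=cohort.spec.K_true)
    out = {}
    for sigma in sigmas:
        accs = []
        for rep in range(reps):
            noisy = {
                s: add_edge_noise(ConnectivityMatrix(nets[s]), sigma,
                                  seed=seed + rep * 10_007 + i).W
                for i, s in enumerate(sorted(nets))
            }
            (acc, *_), _ = nested_cv(noisy, cohort.manifest, scheme,
                                     seed=seed + rep)
            accs.append(acc)
        out[float(sigma)] = float(np.mean(accs))
    return out
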