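"""Subject-level CV, metrics, pairing and the bootstrap ensemble."""

import numpy as np
import pandas as pd
import pytest

from modselect import (
    CohortManifest,
    EvaluationReport,
    SchemeConfig,
    SyntheticSpec,
    bootstrap_ensemble,
    compute_metrics,
    generate_edge_cohort,
    nested_cv,
    subject_kfold,
)


def toy_manifest(n_subjects=20, scans_per_subject=2):
    scans = []
    for s in range(n_subjects):
        label = "patient" if s % 2 else "control"
        for r in range(scans_per_subject):
            scans.append((f"s{s}_r{r}", f"s{s}", label))
    return CohortManifest(scans, "patient", "control")


class TestSubjectKFold:
    def test_no_subject_straddles_folds(self):
        M = toy_manifest()
        for train, test in subject_kfold(M, 5, seed=0):
            train_subj = {M.subject_of(s) for s in train}
            test_subj = {M.subject_of(s) for s in test}
            assert train_subj.isdisjoint(test_subj)

    def test_test_folds_cover_every_scan_once(self):
        M = toy_manifest()
        seen = []
        for _, test in subject_kfold(M, 5, seed=1):
            seen.extend(test)
        assert sorted(seen) == sorted(M.scan_ids)

    def test_fold_sizes_174_subjects(self):
        scans = [(f"x{s}", f"x{s}", "patient" if s < 87 else "control")
                 for s in range(174)]
        M = CohortManifest(scans, "patient", "control")
        sizes = sorted(len(test) for _, test in subject_kfold(M, 5, seed=3))
        assert set(sizes) <= {34, 35}
        assert sum(sizes) == 174

    def test_deterministic_and_validates(self):
        M = toy_manifest(6, 1)
        a = subject_kfold(M, 3, seed=5)
        b = subject_kfold(M, 3, seed=5)
        assert a == b
        with pytest.raises(ValueError):
            subject_kfold(M, 7, seed=0)

    def test_conflicting_subject_labels_rejected(self):
        with pytest.raises(ValueError):
            CohortManifest(
                [("a1", "a", "patient"), ("a2", "a", "control"),
                 ("b1", "b", "control")],
                "patient", "control",
            )


class TestMetrics:
    def test_confusion_count_arithmetic(self):
        # TP=3 TN=4 FP=1 FN=2
        y_true = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, 1, -1, -1, -1, -1, -1, -1, 1])
        acc, sen, spe, _ = compute_metrics(y_true, y_pred)
        assert acc == pytest.approx(70.0)
        assert sen == pytest.approx(60.0)
        assert spe == pytest.approx(80.0)

    def test_perfect_scores_auc(self):
        y = np.array([1, -1, 1, -1, 1.0])
        _, _, _, auc = compute_metrics(y, y, scores=y)
        assert auc == pytest.approx(100.0)

    def test_random_scores_auc_near_half(self, rng):
        y = np.repeat([1.0, -1.0], 1000)
        scores = rng.standard_normal(2000)
        _, _, _, auc = compute_metrics(y, np.sign(scores), scores)
        assert abs(auc - 50.0) < 5.0

    def test_acc_identity_from_class_rates(self, rng):
        y_true = np.repeat([1.0, -1.0], [30, 20])
        y_pred = np.where(rng.random(50) < 0.7, y_true, -y_true)
        acc, sen, spe, _ = compute_metrics(y_true, y_pred)
        assert acc == pytest.approx((sen * 30 + spe * 20) / 50)


@pytest.fixture(scope="module")
def separable_cohort():
    spec = SyntheticSpec(m=12, K_true=3, n_per_class=15, effect_size=-0.6,
                         subject_sigma=0.01, seed=11)
    cohort = generate_edge_cohort(spec, edge_sigma=0.02)
    return cohort.networks(), cohort.manifest


@pytest.fixture(scope="module")
def boot_cohort():
    spec = SyntheticSpec(m=10, K_true=2, n_per_class=12, effect_size=-0.4,
                         seed=21)
    c = generate_edge_cohort(spec, edge_sigma=0.1)
    return c.networks(), c.manifest


class TestNestedCV:
    def test_separable_classes_perfect_metrics(self, separable_cohort):
        nets, manifest = separable_cohort
        (acc, sen, spe, auc), _ = nested_cv(
            nets, manifest, SchemeConfig("edge-ttest"), seed=0
        )
        assert acc == 100.0 and auc == 100.0

    def test_class_swap_exchanges_sen_spe(self):
        spec = SyntheticSpec(m=12, K_true=3, n_per_class=15, effect_size=-0.25,
                             subject_sigma=0.05, seed=12)
        cohort = generate_edge_cohort(spec, edge_sigma=0.25)
        nets, manifest = cohort.networks(), cohort.manifest
        (_, sen, spe, _), _ = nested_cv(nets, manifest, SchemeConfig("edge-ttest"),
                                        seed=0)
        (_, sen2, spe2, _), _ = nested_cv(nets, manifest.swapped(),
                                          SchemeConfig("edge-ttest"), seed=0)
        assert sen == pytest.approx(spe2)
        assert spe == pytest.approx(sen2)

    def test_mlfs_partition_uses_training_controls_only(self, separable_cohort):
        nets, manifest = separable_cohort
        _, outcomes = nested_cv(nets, manifest, SchemeConfig("mlfs", k_modules=3),
                                seed=0)
        for o in outcomes:
            sources = dict(o.audit)
            part_scans = set(sources["partition"])
            assert part_scans <= set(o.train_ids)
            assert all(manifest.label_of(s) == "control" for s in part_scans)
            assert set(sources["selection"]) <= set(o.train_ids)
            assert set(sources["classifier"]) <= set(o.train_ids)


class TestPairedTests:
    def make_report(self, acc_a, acc_b):
        rows = []
        for r, (a, b) in enumerate(zip(acc_a, acc_b)):
            rows.append({"method": "A", "repetition": r, "ACC": a,
                         "SEN": a, "SPE": a, "AUC": a})
            rows.append({"method": "B", "repetition": r, "ACC": b,
                         "SEN": b, "SPE": b, "AUC": b})
        return EvaluationReport(pd.DataFrame(rows))

    def test_self_pairing_flagged_never_significant(self):
        rep = self.make_report([60, 61, 62], [60, 61, 62])
        out = rep.paired_tests("A")
        row_a = out[out.method == "A"].iloc[0]
        assert row_a.degenerate and not row_a.significant
        row_b = out[out.method == "B"].iloc[0]
        assert row_b.degenerate and not row_b.significant

    def test_constant_offset_sign(self, rng):
        base = 60 + rng.normal(0, 2, size=12)
        rep = self.make_report(base + 3, base)
        t_up = rep.paired_tests("A").set_index("method").loc["B", "t"]
        assert t_up > 0
        rep = self.make_report(base - 3, base)
        t_dn = rep.paired_tests("A").set_index("method").loc["B", "t"]
        assert t_dn < 0

    def test_summary_shapes(self):
        rep = self.make_report([60, 62, 64], [50, 52, 54])
        s = rep.summary()
        assert ("ACC", "mean") in s.columns
        assert s.loc["A", ("ACC", "mean")] == pytest.approx(62.0)


class TestBootstrap:
    def test_single_model_no_resample_equals_plain_cv(self, boot_cohort):
        nets, manifest = boot_cohort
        scheme = SchemeConfig("edge-ttest")
        plain, _ = nested_cv(nets, manifest, scheme, seed=4)
        boot = bootstrap_ensemble(nets, manifest, scheme, n_boot=1, seed=4,
                                  resample=False)
        assert plain == pytest.approx(boot)

    def test_deterministic_under_seed(self, boot_cohort):
        nets, manifest = boot_cohort
        scheme = SchemeConfig("edge-ttest")
        a = bootstrap_ensemble(nets, manifest, scheme, n_boot=3, seed=9)
        b = bootstrap_ensemble(nets, manifest, scheme, n_boot=3, seed=9)
        assert a == pytest.approx(b)

    def test_invalid_n_boot(self, boot_cohort):
        nets, manifest = boot_cohort
        with pytest.raises(ValueError):
            bootstrap_ensemble(nets, manifest, SchemeConfig("edge-ttest"), n_boot=0)
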