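"""Synthetic cohorts of modular signed networks and ROI time series.

Two generators, both fully seed-deterministic:

* ``generate_cohort`` mirrors the real estimator chain: per scan it draws T
  multivariate-normal timepoints from a block-modular covariance (positive
  correlations inside planted modules, weak or negative between), then the
  pipeline estimates Pearson/Fisher-z networks from the series.  The patient
  class has ``effect_size`` added to the correlation of a small planted set
  of edges; scans of one subject share a subject-level random shift on those
  edges, so scans within a subject are correlated and subject-level CV is
  meaningful.

* ``generate_edge_cohort`` skips the time-series stage and draws each scan's
  network directly as a class mean matrix plus symmetric Gaussian edge noise
  — cheap, for experiments that only exercise the selection/evaluation
  stages.

Setting ``effect_size = 0`` makes the two classes exchangeable (a null
cohort: any classifier should sit at chance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .evaluation import CohortManifest
from .fbn import ConnectivityMatrix, ROITimeSeries, fisher_z, pearson_fbn, sic_fbn
from .modules import ModulePartition

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "make_block_covariance",
    "planted_partition",
    "generate_cohort",
    "generate_edge_cohort",
    "sbm_network",
    "worked_example",
    "WORKED_EXAMPLE_SEED",
]

EIG_FLOOR = 1e-6
WORKED_EXAMPLE_SEED = 42
_BASELINE_PATH = Path(__file__).parent / "data" / "worked_example_baseline.json"


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe a small but realistic desk-scale study: 20 regions in
    4 equal modules, within-module correlation +0.4 and between-module
    correlation -0.1 (a clearly modular signed structure), 150 timepoints
    per scan (a typical resting-state acquisition length), 20 subjects per
    class, one scan each, and two planted discriminative edges inside module
    0 whose correlation is reduced by 0.3 in patients (connectivity loss).
    """

    m: int = 20
    K_true: int = 4
    T: int = 150
    n_per_class: int = 20
    scans_per_subject: int = 1
    within_corr: float = 0.4
    between_corr: float = -0.1
    effect_edges: list[tuple[int, int]] | None = None
    effect_size: float = -0.3
    noise_sigma: float = 0.0
    subject_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.within_corr) < 1 and abs(self.between_corr) < 1):
            raise ValueError("correlations must have magnitude < 1")
        if self.effect_edges is None:
            # two edges inside planted module 0
            self.effect_edges = [(0, 1), (2, 3)]
        self.effect_edges = [tuple(sorted(map(int, e))) for e in self.effect_edges]
        pairs = {(i, j) for i in range(self.m) for j in range(i + 1, self.m)}
        if not set(self.effect_edges) <= pairs:
            raise ValueError("effect_edges must be valid unordered node pairs")


def planted_partition(m: int, K: int) -> ModulePartition:
    """Contiguous near-equal planted modules: nodes 0..m-1 split into K blocks."""
    labels = np.concatenate(
        [np.full(len(b), k) for k, b in enumerate(np.array_split(np.arange(m), K))]
    )
    return ModulePartition(labels, K)


def _project_pd(S: np.ndarray, floor: float = EIG_FLOOR):
    """Eigenvalue-floor projection to a positive-definite matrix."""
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= floor:
        return S, False
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, True


def make_block_covariance(spec: SyntheticSpec):
    """Block-modular covariance: unit diagonal, within_corr inside planted
    modules, between_corr elsewhere; eigenvalue-floored to PD if needed.

    Returns (Sigma, repaired_flag).
    """
    part = planted_partition(spec.m, spec.K_true)
    same = part.labels[:, None] == part.labels[None, :]
    S = np.where(same, spec.within_corr, spec.between_corr)
    np.fill_diagonal(S, 1.0)
    S, repaired = _project_pd(S)
    if np.linalg.eigvalsh(S).min() < EIG_FLOOR / 2:
        raise ValueError("infeasible correlation structure (not repairable)")
    return S, repaired


@dataclass
class SyntheticCohort:
    """Generated scans plus the ground truth they were generated from."""

    manifest: CohortManifest
    series: dict[str, ROITimeSeries] | None
    matrices: dict[str, ConnectivityMatrix] | None
    ground_truth: dict
    spec: SyntheticSpec

    def networks(self, estimator: str = "pearson_z", reg: float = 0.1):
        """Estimate a network per scan: pearson, pearson_z or sic."""
        if self.matrices is not None:
            return {s: C.W for s, C in self.matrices.items()}
        nets = {}
        for scan_id, ts in self.series.items():
            if estimator == "sic":
                C = sic_fbn(ts, reg)
            else:
                C = pearson_fbn(ts)
                if estimator == "pearson_z":
                    C = fisher_z(C)
            nets[scan_id] = C.W
        return nets

    @property
    def planted_partition(self) -> ModulePartition:
        return ModulePartition(
            np.array(self.ground_truth["partition"]), self.spec.K_true
        )

    @property
    def effect_edges(self) -> list[tuple[int, int]]:
        return [tuple(e) for e in self.ground_truth["effect_edges"]]

    def save(self, outdir) -> None:
        """Write manifest CSV, per-scan TSVs and ground-truth JSON."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for scan_id, subject, label in self.manifest.scans:
            if self.series is not None:
                path = outdir / f"{scan_id}.tsv"
                ts = self.series[scan_id]
                pd.DataFrame(ts.data, columns=ts.region_ids).to_csv(
                    path, sep="\t", index=False
                )
            else:
                path = outdir / f"{scan_id}.tsv"
                self.matrices[scan_id].write(path)
            rows.append((scan_id, subject, label, path.name))
        pd.DataFrame(rows, columns=["scan_id", "subject_id", "label", "path"]).to_csv(
            outdir / "manifest.csv", index=False
        )
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1)


def _cohort_manifest(spec: SyntheticSpec):
    scans = []
    for cls, label in ((0, "control"), (1, "patient")):
        for s in range(spec.n_per_class):
            subject = f"{label[:3]}{s:03d}"
            for r in range(spec.scans_per_subject):
                scans.append((f"{subject}_scan{r}", subject, label))
    return CohortManifest(scans, positive="patient", negative="control")


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a time-series cohort from the block-modular Gaussian model."""
    rng = np.random.default_rng(spec.seed)
    part = planted_partition(spec.m, spec.K_true)
    sigma0, rep0 = make_block_covariance(spec)
    repaired = rep0
    manifest = _cohort_manifest(spec)
    series: dict[str, ROITimeSeries] = {}
    regions = [f"ROI{i + 1}" for i in range(spec.m)]
    subjects_done: dict[str, np.ndarray] = {}
    for scan_id, subject, label in manifest.scans:
        if subject not in subjects_done:
            shift = np.zeros((spec.m, spec.m))
            delta = rng.normal(0.0, spec.subject_sigma, size=len(spec.effect_edges))
            for (i, j), dlt in zip(spec.effect_edges, delta):
                shift[i, j] = shift[j, i] = dlt
                if label == "patient":
                    shift[i, j] += spec.effect_size
                    shift[j, i] += spec.effect_size
            S, rep = _project_pd(sigma0 + shift)
            repaired = repaired or rep
            subjects_done[subject] = np.linalg.cholesky(S)
        chol = subjects_done[subject]
        X = rng.standard_normal((spec.T, spec.m)) @ chol.T
        if spec.noise_sigma > 0:
            X = X + rng.normal(0.0, spec.noise_sigma, size=X.shape)
        series[scan_id] = ROITimeSeries(X, regions)
    ground_truth = {
        "partition": part.labels.tolist(),
        "effect_edges": [list(e) for e in spec.effect_edges],
        "pd_repaired": bool(repaired),
        "spec": {k: (list(map(list, v)) if k == "effect_edges" else v)
                 for k, v in asdict(spec).items()},
    }
    return SyntheticCohort(manifest, series, None, ground_truth, spec)


def sbm_network(m: int, K: int, within: float, between: float, sigma: float,
                seed: int) -> np.ndarray:
    """One signed planted-partition network: block mean matrix plus symmetric
    Gaussian edge noise (SD ``sigma``), zero diagonal."""
    rng = np.random.default_rng(seed)
    part = planted_partition(m, K)
    same = part.labels[:, None] == part.labels[None, :]
    W = np.where(same, within, between).astype(float)
    noise = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    noise[iu] = rng.normal(0.0, sigma, size=len(iu[0]))
    W = W + noise + noise.T
    np.fill_diagonal(W, 0.0)
    return W


def generate_edge_cohort(spec: SyntheticSpec, edge_sigma: float = 0.1) -> SyntheticCohort:
    """Draw scan networks directly: class mean matrix + Gaussian edge noise.

    Patients have ``effect_size`` added on the planted effect edges of the
    mean matrix; subjects share a random shift on those edges across scans.
    """
    rng = np.random.default_rng(spec.seed)
    part = planted_partition(spec.m, spec.K_true)
    same = part.labels[:, None] == part.labels[None, :]
    base = np.where(same, spec.within_corr, spec.between_corr).astype(float)
    np.fill_diagonal(base, 0.0)
    manifest = _cohort_manifest(spec)
    mats: dict[str, ConnectivityMatrix] = {}
    iu = np.triu_indices(spec.m, k=1)
    subj_shift: dict[str, np.ndarray] = {}
    for scan_id, subject, label in manifest.scans:
        if subject not in subj_shift:
            shift = np.zeros((spec.m, spec.m))
            delta = rng.normal(0.0, spec.subject_sigma, size=len(spec.effect_edges))
            for (i, j), dlt in zip(spec.effect_edges, delta):
                shift[i, j] = shift[j, i] = dlt
                if label == "patient":
                    shift[i, j] += spec.effect_size
                    shift[j, i] += spec.effect_size
            subj_shift[subject] = shift
        noise = np.zeros((spec.m, spec.m))
        noise[iu] = rng.normal(0.0, edge_sigma, size=len(iu[0]))
        W = base + subj_shift[subject] + noise + noise.T
        np.fill_diagonal(W, 0.0)
        mats[scan_id] = ConnectivityMatrix(W, estimator_tag="pearson_z")
    ground_truth = {
        "partition": part.labels.tolist(),
        "effect_edges": [list(e) for e in spec.effect_edges],
        "pd_repaired": False,
        "edge_sigma": edge_sigma,
    }
    return SyntheticCohort(manifest, None, mats, ground_truth, spec)


def compute_worked_example_baseline(cohort: SyntheticCohort) -> dict:
    """Regression reference for the worked example: the consensus module
    partition of the control networks and the edges MLFS selects in every
    fold of one nested-CV run (seed 0)."""
    from .evaluation import SchemeConfig, nested_cv, stable_features
    from .modules import consensus_partition

    nets = cohort.networks()
    controls = [s for s, _, lab in cohort.manifest.scans if lab == "control"]
    part = consensus_partition(
        [nets[s] for s in controls], cohort.spec.K_true, seed=WORKED_EXAMPLE_SEED
    )
    scheme = SchemeConfig("mlfs", k_modules=cohort.spec.K_true)
    (acc, sen, spe, auc), outcomes = nested_cv(nets, cohort.manifest, scheme, seed=0)
    m = cohort.spec.m
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    stable = sorted(pairs[j] for j in stable_features(outcomes))
    return {
        "partition": part.labels.tolist(),
        "stable_edges": [list(e) for e in stable],
        "acc": acc,
        "auc": auc,
    }


def worked_example():
    """The bundled deterministic demonstration cohort.

    m=20 regions in 4 planted modules, 40 subjects (20 per class), two
    discriminative edges planted inside module 0, frozen seed.  Returns
    ``(cohort, baseline)`` where ``baseline`` holds the expected module
    partition and selected edges stored with the package as a regression
    reference (None if the data file is absent).
    """
    spec = SyntheticSpec(seed=WORKED_EXAMPLE_SEED)
    cohort = generate_cohort(spec)
    baseline = None
    if _BASELINE_PATH.exists():
        with open(_BASELINE_PATH) as fh:
            baseline = json.load(fh)
    return cohort, baseline
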