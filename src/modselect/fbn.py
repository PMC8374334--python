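"""Functional brain network (FBN) estimation from ROI time series.

A functional brain network is a signed, weighted, undirected graph: nodes are
brain regions of interest (ROIs) and edge weights measure the statistical
dependence between the regions' BOLD time series.  Positive weights suggest
co-activation, negative weights mutual inhibition.  This module estimates such
networks with Pearson correlation (optionally Fisher r-to-z transformed) or
with sparse inverse covariance (an L1-penalised partial-correlation
estimator), and provides the symmetric edge-noise perturbation used in
robustness experiments.

Conventions fixed here and relied on downstream:

* the diagonal of every connectivity matrix is exactly 0 (self-edges carry no
  information, and arctanh(1) diverges);
* every estimator returns an exactly symmetric matrix;
* perfect correlations are clipped to ``1 - clip_eps`` before the Fisher
  transform so degenerate synthetic data never produces infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.covariance import GraphicalLasso

__all__ = [
    "ROITimeSeries",
    "ConnectivityMatrix",
    "pearson_fbn",
    "fisher_z",
    "sic_fbn",
    "add_edge_noise",
]

_SYM_TOL = 1e-10


def _default_regions(m: int) -> list[str]:
    return [f"ROI{i + 1}" for i in range(m)]


@dataclass
class ROITimeSeries:
    """BOLD mean time series for one scan: T timepoints by m regions."""

    data: np.ndarray
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D array (T x m)")
        T, m = self.data.shape
        if T < 3:
            raise ValueError(f"need at least 3 timepoints, got {T}")
        if m < 2:
            raise ValueError(f"need at least 2 regions, got {m}")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains missing/non-finite values")
        if self.region_ids is None:
            self.region_ids = _default_regions(m)
        self.region_ids = list(self.region_ids)
        if len(self.region_ids) != m:
            raise ValueError("region_ids length does not match data columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def zero_variance_regions(self) -> list[str]:
        """Labels of regions whose series has (numerically) zero variance."""
        sd = self.data.std(axis=0)
        return [r for r, s in zip(self.region_ids, sd) if s <= 1e-15]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ROITimeSeries":
        return cls(df.to_numpy(dtype=float), list(map(str, df.columns)))

    @classmethod
    def read(cls, path, sep=None) -> "ROITimeSeries":
        df = pd.read_csv(path, sep=sep, engine="python")
        return cls.from_dataframe(df)


@dataclass
class ConnectivityMatrix:
    """Symmetric signed connectivity matrix for one scan (one FBN).

    ``estimator_tag`` records the estimator chain: ``pearson`` (raw
    correlations), ``pearson_z`` (Fisher r-to-z transformed) or ``sic``
    (sparse-inverse-covariance partial correlations).
    """

    W: np.ndarray
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]
    estimator_tag: str = "pearson"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if np.abs(self.W - self.W.T).max() > 1e-8:
            raise ValueError("W must be symmetric")
        # enforce exact symmetry and zero diagonal
        self.W = (self.W + self.W.T) / 2.0
        np.fill_diagonal(self.W, 0.0)
        if self.region_ids is None:
            self.region_ids = _default_regions(self.W.shape[0])
        self.region_ids = list(self.region_ids)
        if len(self.region_ids) != self.W.shape[0]:
            raise ValueError("region_ids length does not match W")

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.region_ids, columns=self.region_ids)

    def write(self, path, sep="\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep)

    @classmethod
    def read(cls, path, sep="\t", estimator_tag="pearson_z") -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df.to_numpy(dtype=float), list(map(str, df.columns)), estimator_tag)


def pearson_fbn(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Estimate an FBN as the pairwise Pearson correlation of ROI series.

    Raises if any region has zero variance (its correlation is undefined);
    the error names the offending region(s).
    """
    bad = ts.zero_variance_regions()
    if bad:
        raise ValueError(f"zero-variance region(s): {', '.join(bad)}")
    W = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(W, ts.region_ids, "pearson")


def fisher_z(C: ConnectivityMatrix, clip_eps: float = 1e-7) -> ConnectivityMatrix:
    """Apply Fisher's r-to-z transform (arctanh) to every edge weight.

    Variance-stabilises the correlation weights.  Entries with |r| = 1 are
    clipped to 1 - ``clip_eps`` first so the transform stays finite.
    """
    if C.estimator_tag != "pearson":
        raise ValueError("fisher_z expects raw Pearson correlations")
    W = C.W
    if np.abs(W).max() > 1.0 + 1e-9:
        raise ValueError("correlation magnitude exceeds 1")
    Wc = np.clip(W, -1.0 + clip_eps, 1.0 - clip_eps)
    Z = np.arctanh(Wc)
    np.fill_diagonal(Z, 0.0)
    return ConnectivityMatrix(Z, C.region_ids, "pearson_z")


def sic_fbn(ts: ROITimeSeries, reg: float, max_iter: int = 500) -> ConnectivityMatrix:
    """Estimate an FBN by sparse inverse covariance (graphical lasso).

    Fits an L1-penalised precision matrix Theta (penalty weight ``reg``) and
    converts it to partial correlations, ``W[i, j] = -Theta_ij /
    sqrt(Theta_ii * Theta_jj)``, with zero diagonal.  Larger ``reg`` gives a
    sparser network.
    """
    if reg <= 0:
        raise ValueError("reg must be positive")
    bad = ts.zero_variance_regions()
    if bad:
        raise ValueError(f"zero-variance region(s): {', '.join(bad)}")
    # correlation-scale input so reg is comparable across datasets
    X = (ts.data - ts.data.mean(axis=0)) / ts.data.std(axis=0)
    model = GraphicalLasso(alpha=reg, max_iter=max_iter, assume_centered=True)
    try:
        model.fit(X)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise RuntimeError(f"sparse inverse covariance did not converge: {exc}") from exc
    theta = model.precision_
    d = np.sqrt(np.diag(theta))
    W = -theta / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return ConnectivityMatrix(W, ts.region_ids, "sic")


def add_edge_noise(C: ConnectivityMatrix, sigma: float, seed: int) -> ConnectivityMatrix:
    """Add white Gaussian noise (SD ``sigma``) to every edge weight.

    One draw per unordered pair, mirrored across the diagonal, so the
    perturbed matrix remains a valid symmetric FBN with zero diagonal.
    Deterministic for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    m = C.n_regions
    rng = np.random.default_rng(seed)
    noise = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    noise[iu] = rng.normal(0.0, sigma, size=len(iu[0])) if sigma > 0 else 0.0
    noise = noise + noise.T
    return ConnectivityMatrix(C.W + noise, C.region_ids, C.estimator_tag)
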