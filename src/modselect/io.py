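"""Delimited-text input/output for manifests, time series and matrices."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluation import CohortManifest
from .fbn import ConnectivityMatrix, ROITimeSeries

__all__ = ["read_manifest", "load_series", "load_matrices", "write_matrices"]


def read_manifest(path, positive: str, negative: str):
    """Read a cohort manifest CSV (scan_id, subject_id, label, path).

    Returns ``(manifest, paths)`` with paths resolved relative to the
    manifest file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"scan_id", "subject_id", "label", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    manifest = CohortManifest.from_dataframe(df, positive, negative)
    paths = {str(r.scan_id): path.parent / str(r.path) for r in df.itertuples()}
    return manifest, paths


def load_series(paths: dict) -> dict:
    """Read one ROI time-series table (T x m, region-label header) per scan."""
    return {scan: ROITimeSeries.read(p) for scan, p in paths.items()}


def load_matrices(paths: dict, estimator_tag: str = "pearson_z") -> dict:
    """Read one m x m connectivity matrix per scan."""
    return {
        scan: ConnectivityMatrix.read(p, estimator_tag=estimator_tag)
        for scan, p in paths.items()
    }


def write_matrices(networks: dict, outdir) -> dict:
    """Write each ConnectivityMatrix as a TSV; returns scan -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for scan, C in networks.items():
        p = outdir / f"{scan}.tsv"
        C.write(p)
        written[scan] = p
    return written
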