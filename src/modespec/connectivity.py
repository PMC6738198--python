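"""Frequency-resolved functional-connectivity matrices.

For each frequency cluster, an ROI time series is formed by averaging
the time courses of every mode (across all voxels of the ROI) assigned
to that cluster; connectivity is the matrix of pairwise Pearson
correlations between ROI series.  Band-pass reference matrices apply the
same correlation to Gaussian band-passed ROI-mean raw signals, and
matrix similarity is the Pearson correlation of vectorized strict upper
triangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import DecomposedVolume
from .series import BOLDSeries
from .spectral import Band, gaussian_bandpass

__all__ = [
    "ConnectivityMatrix",
    "load_roi_table",
    "roi_cluster_timeseries",
    "correlation_matrix",
    "bandpass_reference_matrix",
    "matrix_similarity",
]


def load_roi_table() -> pd.DataFrame:
    """The packaged AAL-116 region list (1-based index, unique names)."""
    with resources.files("modespec.data").joinpath("aal116.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return table


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson matrix with provenance tag.

    Rows/columns of ROIs with no valid signal are NaN sentinels (their
    diagonal too); valid diagonal entries are exactly 1.
    """

    values: np.ndarray
    roi_names: list[str]
    tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if len(self.roi_names) != v.shape[0]:
            raise ValueError("roi_names length mismatch")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_names,
                            columns=self.roi_names)

    def save(self, path: str | Path) -> None:
        """Delimited text with ROI-name header (round-trippable)."""
        self.to_frame().to_csv(path, sep="\t", index_label="roi")

    @classmethod
    def load(cls, path: str | Path, tag: str = "") -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), roi_names=list(df.columns), tag=tag)


def roi_cluster_timeseries(dv: DecomposedVolume, labeled_table: pd.DataFrame,
                           cluster: int, roi_ids=None):
    """Average, per ROI, the mode time courses assigned to one cluster.

    Returns ``(roi_ids, series, valid)`` where ``series`` is (R, T) with
    NaN rows for ROIs without any contributing mode (flagged in
    ``valid``).  Requires the decomposition to have retained mode time
    courses.
    """
    if dv.modes is None:
        raise ValueError("decomposition was run without keep_modes")
    t = labeled_table
    if "cluster" not in t.columns:
        raise ValueError("table lacks cluster labels; run assign_imfs first")
    if roi_ids is None:
        roi_ids = np.sort(np.unique(t.loc[t["roi"] > 0, "roi"]))
    roi_ids = np.asarray(roi_ids)
    if roi_ids.size < 2:
        raise ValueError("need at least 2 ROIs")
    n_t = dv.modes.shape[2]
    series = np.full((roi_ids.size, n_t), np.nan)
    valid = np.zeros(roi_ids.size, dtype=bool)
    sel_cluster = t[t["cluster"] == cluster]
    for ri, roi in enumerate(roi_ids):
        grp = sel_cluster[sel_cluster["roi"] == roi]
        if grp.empty:
            warnings.warn(f"ROI {roi} has no mode in cluster {cluster}",
                          RuntimeWarning, stacklevel=2)
            continue
        series[ri] = dv.modes[grp["voxel"].to_numpy(),
                              grp["mode"].to_numpy()].mean(axis=0)
        valid[ri] = True
    return roi_ids, series, valid


def correlation_matrix(series: np.ndarray, roi_names: list[str],
                       tag: str = "") -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI series.

    NaN or zero-variance rows yield NaN sentinel rows/columns.  Group
    results are obtained by element-wise averaging of subject matrices.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 2:
        raise ValueError("series must be (n_rois, n_samples)")
    good = np.isfinite(s).all(axis=1) & (s.std(axis=1) > 0)
    if good.sum() < 2:
        raise ValueError("need at least 2 valid ROI series")
    vals = np.full((s.shape[0], s.shape[0]), np.nan)
    sub = np.corrcoef(s[good])
    idx = np.flatnonzero(good)
    vals[np.ix_(idx, idx)] = sub
    return ConnectivityMatrix(values=vals, roi_names=list(roi_names), tag=tag)


def roi_mean_series(bold: np.ndarray, rois: np.ndarray, roi_ids=None):
    """ROI-mean raw time series from a 4D dataset; returns (roi_ids, (R, T))."""
    rois = np.asarray(rois)
    if roi_ids is None:
        roi_ids = np.sort(np.unique(rois[rois > 0]))
    roi_ids = np.asarray(roi_ids)
    out = np.stack([bold[rois == roi].mean(axis=0) for roi in roi_ids])
    return roi_ids, out


def bandpass_reference_matrix(bold: np.ndarray, rois: np.ndarray, dt: float,
                              band: Band, roi_names: list[str] | None = None,
                              edge_sigma: float = 0.005) -> ConnectivityMatrix:
    """Connectivity of Gaussian band-passed ROI-mean signals.

    The conventional reference uses the 0.01-0.08 Hz band; passing each
    fitted cluster's range instead gives the band-filtered analogues of
    the cluster matrices.
    """
    roi_ids, series = roi_mean_series(bold, rois)
    filtered = np.stack([
        gaussian_bandpass(BOLDSeries(row, dt=dt), band,
                          edge_sigma=edge_sigma).values
        for row in series])
    names = roi_names if roi_names is not None \
        else [f"ROI_{r}" for r in roi_ids]
    return correlation_matrix(filtered, names,
                              tag=f"band_{band.lo:g}-{band.hi:g}Hz")


def matrix_similarity(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Pearson correlation between the strict upper triangles of two
    matrices (same ROI ordering); NaN entries excluded pairwise.

    Returns NaN when fewer than 3 valid pairs remain.
    """
    if a.roi_names != b.roi_names:
        raise ValueError("ROI orderings differ")
    iu = np.triu_indices(a.n_rois, k=1)
    x = a.values[iu]
    y = b.values[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 valid matrix-entry pairs",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def mean_matrix(matrices: list[ConnectivityMatrix], fisher_z: bool = False,
                tag: str = "group") -> ConnectivityMatrix:
    """Element-wise group average of subject matrices.

    Plain averaging of r values by default; ``fisher_z`` averages
    arctanh-transformed values and back-transforms.
    """
    if not matrices:
        raise ValueError("no matrices")
    names = matrices[0].roi_names
    stack = np.stack([m.values for m in matrices])
    if fisher_z:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
            out = np.tanh(np.nanmean(z, axis=0))
        d = np.arange(len(names))
        out[d, d] = np.nanmean(stack, axis=0)[d, d]
    else:
        out = np.nanmean(stack, axis=0)
    return ConnectivityMatrix(values=out, roi_names=names, tag=tag)
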