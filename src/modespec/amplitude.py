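"""Fractional modal amplitude maps and tissue summaries.

The fractional amplitude of a frequency cluster at a voxel is the share
of the voxel's total labeled modal power carried by the modes assigned
to that cluster.  Because it is a ratio, it is comparable across
subjects and acquisitions whose raw signal scales differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FractionalAmplitudeMap", "fractional_amplitude",
           "summarize_amplitude"]


@dataclass
class FractionalAmplitudeMap:
    """Per-voxel, per-cluster fractions of labeled modal power.

    ``fractions`` has shape (V, C) aligned with ``voxel_coords``; rows
    sum to 1 for unmasked voxels.  Voxels whose modes were all unassigned
    are masked out (``valid`` False) and counted.
    """

    fractions: np.ndarray
    valid: np.ndarray
    voxel_coords: np.ndarray
    tissue_of_voxel: np.ndarray
    cluster_labels: list[str]
    unassigned_power_fraction: np.ndarray   # per voxel, share of power not labeled
    n_masked: int

    @property
    def n_clusters(self) -> int:
        return self.fractions.shape[1]

    def to_volumes(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Expand to (C, X, Y, Z) volumes (NaN outside valid voxels)."""
        vols = np.full((self.n_clusters,) + tuple(shape), np.nan)
        idx = self.voxel_coords[self.valid]
        for c in range(self.n_clusters):
            vols[c][idx[:, 0], idx[:, 1], idx[:, 2]] = \
                self.fractions[self.valid, c]
        return vols


def fractional_amplitude(labeled_table: pd.DataFrame,
                         n_clusters: int,
                         cluster_labels: list[str] | None = None
                         ) -> FractionalAmplitudeMap:
    """Per-voxel cluster power fractions from a cluster-labeled mode table.

    ``fraction_c = sum(power of modes labeled c) / sum(power of labeled
    modes)``; multiple modes falling in one cluster are summed.  The
    normalization deliberately excludes unassigned modes, whose power
    share is reported separately.
    """
    if "cluster" not in labeled_table.columns:
        raise ValueError("table lacks cluster labels; run assign_imfs first")
    t = labeled_table
    voxels = np.sort(t["voxel"].unique())
    v = voxels.size
    lookup = {vox: i for i, vox in enumerate(voxels)}
    rows = np.array([lookup[x] for x in t["voxel"]])
    power = t["power"].to_numpy()
    cluster = t["cluster"].to_numpy()

    frac = np.zeros((v, n_clusters))
    for c in range(n_clusters):
        np.add.at(frac[:, c], rows[cluster == c], power[cluster == c])
    total_all = np.zeros(v)
    np.add.at(total_all, rows, power)
    labeled_total = frac.sum(axis=1)
    valid = labeled_total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(valid[:, None], frac / labeled_total[:, None], np.nan)
        unassigned = np.where(total_all > 0,
                              1.0 - labeled_total / total_all, 0.0)
    n_masked = int((~valid).sum())
    if n_masked:
        warnings.warn(f"{n_masked} voxels had no cluster-labeled modes and "
                      "were masked", RuntimeWarning, stacklevel=2)

    first = t.drop_duplicates("voxel").set_index("voxel")
    coords = first.loc[voxels, ["i", "j", "k"]].to_numpy()
    tiss = first.loc[voxels, "tissue"].to_numpy()
    if cluster_labels is None:
        cluster_labels = [f"cluster{c}" for c in range(n_clusters)]
    return FractionalAmplitudeMap(
        fractions=frac, valid=valid, voxel_coords=coords,
        tissue_of_voxel=tiss, cluster_labels=list(cluster_labels),
        unassigned_power_fraction=unassigned, n_masked=n_masked)


def summarize_amplitude(amap: FractionalAmplitudeMap,
                        group: list[FractionalAmplitudeMap] | None = None,
                        tissue_names: dict[int, str] | None = None):
    """Tissue-wise summary of fractional amplitudes.

    Returns ``(summary, tissue_tests, group_mean)``:

    * summary: per-tissue per-cluster mean and sd of the fractions;
    * tissue_tests: Welch two-sample t statistic and p-value per cluster
      for every tissue pair;
    * group_mean: element-wise mean fraction array across subject maps
      (requires co-registered grids), or None when no group is given.
    """
    tissue_names = tissue_names or {1: "CSF", 2: "GM", 3: "WM"}
    fr = amap.fractions[amap.valid]
    tiss = amap.tissue_of_voxel[amap.valid]
    rows = []
    for lbl in np.unique(tiss):
        name = tissue_names.get(int(lbl), str(lbl))
        sel = tiss == lbl
        for c in range(amap.n_clusters):
            rows.append((name, amap.cluster_labels[c],
                         float(np.mean(fr[sel, c])),
                         float(np.std(fr[sel, c], ddof=1)),
                         int(sel.sum())))
    summary = pd.DataFrame(rows, columns=["tissue", "cluster", "mean", "sd",
                                          "n_voxels"])

    test_rows = []
    labels = np.unique(tiss)
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            la, lb = labels[a_i], labels[b_i]
            sa, sb = tiss == la, tiss == lb
            for c in range(amap.n_clusters):
                t_stat, p = stats.ttest_ind(fr[sa, c], fr[sb, c],
                                            equal_var=False)
                test_rows.append((tissue_names.get(int(la), str(la)),
                                  tissue_names.get(int(lb), str(lb)),
                                  amap.cluster_labels[c],
                                  float(t_stat), float(p)))
    tissue_tests = pd.DataFrame(test_rows, columns=["tissue_a", "tissue_b",
                                                    "cluster", "t", "p"])

    group_mean = None
    if group:
        shapes = {m.fractions.shape for m in group} | {amap.fractions.shape}
        if len(shapes) != 1:
            raise ValueError("group maps are not on matching grids")
        group_mean = np.nanmean(np.stack([m.fractions for m in group]),
                                axis=0)
    return summary, tissue_tests, group_mean
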