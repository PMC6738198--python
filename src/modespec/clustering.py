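"""Whole-brain IMF-frequency clustering.

Every in-mask voxel is decomposed into K modes; each mode contributes its
center-of-mass frequency to a pooled histogram, weighted by its power
normalized to the voxel's total modal power.  Peaks of that histogram are
modeled as Gaussians; each fitted peak defines a *frequency cluster*
whose range is the central 95%-area interval (center +/- 1.96 sd).
Cluster labels follow the convention that IMF1 is the highest-frequency
cluster and the index increases as frequency decreases.

The number of detected clusters is a property of the histogram, not of
the K requested at the decomposition stage; :func:`order_selection`
quantifies which K yields the most precise and reproducible clusters
across subjects and repeated runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from . import spectral
from .decompose import VMDConfig, vmd_decompose_batch
from .series import BOLDSeries
from .spectral import Band, _periodogram

__all__ = [
    "DecomposedVolume",
    "decompose_volume",
    "WeightedHistogram",
    "build_histogram",
    "FrequencyClusterSet",
    "fit_clusters",
    "assign_imfs",
    "OrderSelectionReport",
    "order_selection",
    "icc",
]


@dataclass
class DecomposedVolume:
    """Per-voxel modal decomposition of a 4D dataset.

    ``table`` has one row per (voxel, mode) with columns
    voxel, i, j, k, tissue, roi, mode, freq, power, weight; per-voxel
    weights sum to 1.  ``modes`` retains the mode time courses,
    shape (V, K, T), aligned with ``voxel_coords``.
    """

    table: pd.DataFrame
    modes: np.ndarray | None
    voxel_coords: np.ndarray
    dt: float
    n_skipped: int
    config: VMDConfig

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt


def _mode_spectral_stats(modes: np.ndarray, dt: float):
    """Vectorized per-mode PSD total power and center-of-mass frequency.

    Matches :func:`modespec.spectral.psd` + :func:`com_frequency` exactly
    (same demeaned one-sided periodogram)."""
    freqs, dens, df = _periodogram(modes, dt, axis=-1)
    power = dens.sum(axis=-1) * df                 # total power = variance
    num = (dens * freqs).sum(axis=-1)
    den = dens.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        com = np.where(den > 0, num / den, np.nan)
    return com, power


def decompose_volume(bold: np.ndarray, tissue: np.ndarray, dt: float,
                     vmd_config: VMDConfig,
                     rois: np.ndarray | None = None,
                     keep_modes: bool = True) -> DecomposedVolume:
    """Decompose every in-mask voxel of a band-limited 4D dataset.

    The caller is expected to have band-limited the data (0.01-0.25 Hz
    for long-TR data; short-TR data low-pass filtered at 0.25 Hz first).
    Zero-variance voxels are skipped and counted; a warning is issued if
    they exceed 10% of the mask.
    """
    bold = np.asarray(bold, dtype=float)
    tissue = np.asarray(tissue)
    if bold.ndim != 4:
        raise ValueError("bold must be 4-D")
    if bold.shape[:3] != tissue.shape:
        raise ValueError("tissue labels do not match BOLD grid")
    mask = tissue > 0
    coords = np.argwhere(mask)
    series = bold[mask]                            # (V, T)
    variances = series.var(axis=1)
    good = variances > 0
    n_skipped = int((~good).sum())
    if n_skipped > 0.1 * coords.shape[0]:
        warnings.warn(f"{n_skipped} of {coords.shape[0]} voxels are "
                      "degenerate (zero variance)", RuntimeWarning,
                      stacklevel=2)
    coords = coords[good]
    series = series[good]

    imfsets = vmd_decompose_batch(series, dt, vmd_config)
    k = vmd_config.n_modes
    v = series.shape[0]
    modes = np.stack([s.modes for s in imfsets]) if v else \
        np.zeros((0, k, series.shape[1]))
    com, power = _mode_spectral_stats(modes, dt)
    tot = power.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        weight = np.where(tot > 0, power / tot, 0.0)

    tiss = tissue[mask][good]
    roi = (np.asarray(rois)[mask][good] if rois is not None
           else np.zeros(v, dtype=int))
    rows = {
        "voxel": np.repeat(np.arange(v), k),
        "i": np.repeat(coords[:, 0], k),
        "j": np.repeat(coords[:, 1], k),
        "k": np.repeat(coords[:, 2], k),
        "tissue": np.repeat(tiss, k),
        "roi": np.repeat(roi, k),
        "mode": np.tile(np.arange(k), v),
        "freq": com.ravel(),
        "power": power.ravel(),
        "weight": weight.ravel(),
    }
    return DecomposedVolume(table=pd.DataFrame(rows),
                            modes=modes if keep_modes else None,
                            voxel_coords=coords, dt=dt,
                            n_skipped=n_skipped, config=vmd_config)


@dataclass
class WeightedHistogram:
    """Power-weighted histogram of modal frequencies."""

    edges: np.ndarray
    mass: np.ndarray
    n_voxels: int
    bin_width: float

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def build_histogram(dv: DecomposedVolume, tissue: int | None = None,
                    bin_width: float = 0.005) -> WeightedHistogram:
    """Pool modal frequencies into a weighted histogram over [0, Nyquist].

    Each mode contributes its normalized power weight, so the total mass
    equals the number of contributing voxels.
    """
    table = dv.table
    if tissue is not None:
        table = table[table["tissue"] == tissue]
    table = table.dropna(subset=["freq"])
    if table.empty:
        raise ValueError("no voxels after tissue filtering")
    nyq = dv.nyquist
    n_bins = int(np.ceil(nyq / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    mass, _ = np.histogram(table["freq"], bins=edges,
                           weights=table["weight"])
    n_voxels = int(table["voxel"].nunique())
    return WeightedHistogram(edges=edges, mass=mass, n_voxels=n_voxels,
                             bin_width=bin_width)


@dataclass
class FrequencyClusterSet:
    """Gaussian frequency clusters fitted to a pooled modal histogram.

    Centers are sorted ascending; ``labels[i]`` carries the conventional
    name (IMF1 = highest frequency).  ``ranges`` are central 95%-area
    intervals, center +/- 1.96 sd, clipped to [0, f_max].
    """

    centers: np.ndarray
    sds: np.ndarray
    amplitudes: np.ndarray
    ranges: list[Band]
    labels: list[str]
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.centers.size


def _gauss_sum(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        a, mu, sd = params[i:i + 3]
        out = out + a * np.exp(-((f - mu) ** 2) / (2 * sd**2))
    return out


def fit_clusters(hist: WeightedHistogram, max_peaks: int = 6,
                 prominence_frac: float = 0.05,
                 min_mass_frac: float = 0.02,
                 f_max: float | None = None) -> FrequencyClusterSet:
    """Fit a sum of Gaussians to the histogram peaks.

    Peaks are seeded at local maxima exceeding ``prominence_frac`` of the
    tallest bin (up to ``max_peaks``, tallest first) and refined by
    least squares; fitted components carrying less than ``min_mass_frac``
    of the total mass are dropped.  On fit failure the seeded moments
    (local mass mean/sd) are used and flagged.
    """
    if hist.total_mass <= 0:
        raise ValueError("histogram has no mass")
    f = hist.centers
    y = hist.mass
    f_max = f_max if f_max is not None else float(hist.edges[-1])
    peaks, props = find_peaks(y, prominence=prominence_frac * y.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(y))])
        props = {"prominences": np.array([y.max()])}
    order = np.argsort(props["prominences"])[::-1][:max_peaks]
    peaks = np.sort(peaks[order])

    # moment-based seeds on the midpoint partition around the peaks
    seed_params = []
    boundaries = np.concatenate([[0], (f[peaks][:-1] + f[peaks][1:]) / 2,
                                 [f_max]]) if peaks.size > 1 else \
        np.array([0.0, f_max])
    for p_i, pk in enumerate(peaks):
        sel = (f >= boundaries[p_i]) & (f < boundaries[p_i + 1])
        w = y[sel]
        if w.sum() > 0:
            mu = float(np.sum(f[sel] * w) / w.sum())
            sd = float(np.sqrt(np.sum(w * (f[sel] - mu) ** 2) / w.sum()))
        else:
            mu, sd = float(f[pk]), hist.bin_width
        sd = max(sd, hist.bin_width / 2)
        seed_params.extend([float(y[pk]), mu, sd])
    seeds = np.asarray(seed_params)

    flagged = False
    try:
        lo = np.tile([0.0, 0.0, hist.bin_width / 4], peaks.size)
        hi = np.tile([np.inf, f_max, f_max], peaks.size)
        params, _ = curve_fit(_gauss_sum, f, y, p0=seeds, bounds=(lo, hi),
                              maxfev=20000)
    except Exception:
        params = seeds
        flagged = True
    params = np.asarray(params).reshape(-1, 3)
    # component mass relative to total histogram mass
    comp_mass = params[:, 0] * params[:, 2] * np.sqrt(2 * np.pi) \
        / hist.bin_width
    keep = comp_mass >= min_mass_frac * hist.total_mass
    if not np.any(keep):
        keep[:] = True
    params = params[keep]
    resid = float(np.sum((y - _gauss_sum(f, *params.ravel())) ** 2))

    order = np.argsort(params[:, 1])
    amps, centers, sds = params[order, 0], params[order, 1], params[order, 2]
    n = centers.size
    ranges = [Band(max(0.0, c - 1.96 * s), min(f_max, c + 1.96 * s))
              for c, s in zip(centers, sds)]
    labels = [f"IMF{n - i}" for i in range(n)]
    return FrequencyClusterSet(
        centers=centers, sds=sds, amplitudes=amps, ranges=ranges,
        labels=labels,
        diagnostics={"fit_failed": flagged, "n_peaks_seeded": peaks.size,
                     "residual": resid,
                     "dropped_components": int((~keep).sum())})


def assign_imfs(table: pd.DataFrame,
                clusters: FrequencyClusterSet) -> pd.DataFrame:
    """Label each modal row with its frequency cluster.

    A mode belongs to the cluster whose 95% range contains its frequency;
    where ranges overlap the nearest center wins.  Modes outside every
    range get cluster index -1 (retained but excluded from cluster
    statistics).  Returns a copy with ``cluster`` (ascending index) and
    ``cluster_label`` columns.
    """
    if clusters.n_clusters == 0:
        raise ValueError("cluster set is empty")
    freq = table["freq"].to_numpy()
    n = clusters.n_clusters
    in_range = np.zeros((freq.size, n), dtype=bool)
    for ci, band in enumerate(clusters.ranges):
        in_range[:, ci] = (freq >= band.lo) & (freq <= band.hi)
    dist = np.abs(freq[:, None] - clusters.centers[None, :])
    dist_masked = np.where(in_range, dist, np.inf)
    best = np.argmin(dist_masked, axis=1)
    assigned = np.where(in_range.any(axis=1), best, -1)
    assigned = np.where(np.isnan(freq), -1, assigned)
    out = table.copy()
    out["cluster"] = assigned
    label_map = {i: clusters.labels[i] for i in range(n)}
    label_map[-1] = "unassigned"
    out["cluster_label"] = out["cluster"].map(label_map)
    return out


# ---------------------------------------------------------------------------
# Model-order selection and reproducibility
# ---------------------------------------------------------------------------

@dataclass
class OrderSelectionReport:
    """Precision and reproducibility of cluster estimates per candidate K."""

    metrics: pd.DataFrame     # K, center_sd, width_sd, manifestation_pct, run_correlation
    per_run: pd.DataFrame     # subject, run, K, cluster centers/widths
    recommended_K: int


def _match_clusters(reference: np.ndarray, centers: np.ndarray,
                    gate: float = 0.02) -> np.ndarray:
    """Greedy nearest-center matching of ``centers`` onto ``reference``.

    Returns, for each reference cluster, the index into ``centers`` or -1
    when nothing lies within the gate.
    """
    out = np.full(reference.size, -1)
    used = set()
    for ri in np.argsort(reference):
        d = np.abs(centers - reference[ri])
        for ci in np.argsort(d):
            if ci in used or d[ci] > gate:
                continue
            out[ri] = ci
            used.add(ci)
            break
    return out


def order_selection(subject_runs, candidate_K=(2, 4, 5, 8),
                    vmd_config: VMDConfig | None = None,
                    bin_width: float = 0.005, tissue: int | None = None,
                    max_peaks: int = 8,
                    match_gate: float = 0.02) -> OrderSelectionReport:
    """Compare cluster precision and reproducibility across candidate K.

    ``subject_runs`` is a list (subjects) of lists (runs) of
    ``(bold4d, tissue_labels, dt)`` tuples, each already band-limited.
    For each K the full decompose -> histogram -> Gaussian-fit chain is
    run per subject and run.  Metrics per K: group sd of matched cluster
    centers and widths, percentage of runs manifesting each cluster, and
    the between-run correlation of cluster centers.  The recommended K
    minimizes the rank sum over the four metrics.
    """
    if len(subject_runs) < 2 or any(len(r) < 2 for r in subject_runs):
        raise ValueError("need >= 2 subjects with >= 2 runs each")
    base = vmd_config or VMDConfig()
    per_run_rows = []
    for s, runs in enumerate(subject_runs):
        for r, (bold, tiss, dt) in enumerate(runs):
            for k in candidate_K:
                cfg = VMDConfig(n_modes=k, alpha=base.alpha, tau=base.tau,
                                tol=base.tol, max_iter=base.max_iter,
                                init_scheme=base.init_scheme,
                                dc_mode=base.dc_mode, seed=base.seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    dv = decompose_volume(bold, tiss, dt, cfg,
                                          keep_modes=False)
                    hist = build_histogram(dv, tissue=tissue,
                                           bin_width=bin_width)
                    cl = fit_clusters(hist, max_peaks=max_peaks)
                for ci in range(cl.n_clusters):
                    per_run_rows.append(
                        (s, r, k, ci, float(cl.centers[ci]),
                         float(2 * 1.96 * cl.sds[ci])))
    per_run = pd.DataFrame(per_run_rows,
                           columns=["subject", "run", "K", "cluster",
                                    "center", "width"])

    metric_rows = []
    for k in candidate_K:
        sub = per_run[per_run["K"] == k]
        # group template: pooled centers of the modal cluster count
        counts = sub.groupby(["subject", "run"]).size()
        n_runs = len(counts)
        modal = int(counts.mode().iloc[0])
        template_runs = counts[counts == modal].index
        templ_centers = []
        for (s, r) in template_runs:
            c = sub[(sub["subject"] == s) & (sub["run"] == r)]["center"]
            templ_centers.append(np.sort(c.to_numpy()))
        template = np.mean(templ_centers, axis=0)

        matched_centers = np.full((n_runs, template.size), np.nan)
        matched_widths = np.full((n_runs, template.size), np.nan)
        run_keys = list(counts.index)
        for qi, (s, r) in enumerate(run_keys):
            grp = sub[(sub["subject"] == s) & (sub["run"] == r)]
            cent = grp["center"].to_numpy()
            wid = grp["width"].to_numpy()
            m = _match_clusters(template, cent, gate=match_gate)
            for ti, ci in enumerate(m):
                if ci >= 0:
                    matched_centers[qi, ti] = cent[ci]
                    matched_widths[qi, ti] = wid[ci]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            center_sd = float(np.nanmean(np.nanstd(matched_centers, axis=0,
                                                   ddof=0)))
            width_sd = float(np.nanmean(np.nanstd(matched_widths, axis=0,
                                                  ddof=0)))
        manifestation = float(100.0 *
                              np.mean(~np.isnan(matched_centers)))
        # between-run correlation of matched centers (run 0 vs 1 per subject)
        c1, c2 = [], []
        for s in sub["subject"].unique():
            i1 = run_keys.index((s, 0)) if (s, 0) in run_keys else None
            i2 = run_keys.index((s, 1)) if (s, 1) in run_keys else None
            if i1 is None or i2 is None:
                continue
            both = (~np.isnan(matched_centers[i1])
                    & ~np.isnan(matched_centers[i2]))
            c1.extend(matched_centers[i1][both])
            c2.extend(matched_centers[i2][both])
        if len(c1) >= 3 and np.std(c1) > 0 and np.std(c2) > 0:
            run_corr = float(np.corrcoef(c1, c2)[0, 1])
        else:
            run_corr = float("nan")
        metric_rows.append((k, center_sd, width_sd, manifestation, run_corr))
    metrics = pd.DataFrame(metric_rows,
                           columns=["K", "center_sd", "width_sd",
                                    "manifestation_pct", "run_correlation"])
    ranks = (metrics["center_sd"].rank() + metrics["width_sd"].rank()
             + metrics["manifestation_pct"].rank(ascending=False)
             + metrics["run_correlation"].rank(ascending=False))
    recommended = int(metrics.loc[ranks.idxmin(), "K"])
    return OrderSelectionReport(metrics=metrics, per_run=per_run,
                                recommended_K=recommended)


def icc(run1: np.ndarray, run2: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``run1``/``run2`` are paired measurements (e.g. per-subject cluster
    center frequencies from two scan sessions).  Returns NaN when the
    data carry no variance at all.
    """
    x = np.column_stack([np.asarray(run1, dtype=float),
                         np.asarray(run2, dtype=float)])
    if x.shape[0] < 2:
        raise ValueError("need at least 2 paired subjects")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        warnings.warn("zero total variance: ICC undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)
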