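"""Synthetic rs-fMRI data with known ground truth.

Two generators are provided:

* :func:`make_tone_mixtures` — the Monte Carlo benchmark input: a clean
  signal built from equal-power cosines at four canonical rs-fMRI
  frequencies, plus white-noise realizations calibrated to a target
  signal-to-noise power ratio.
* :func:`make_brain_phantom` — a small 4D brain-like volume whose voxel
  signals are mixtures of oscillations drawn from a configurable set of
  frequency clusters, with tissue-dependent power fractions, ROI blocks
  that share band-limited components (planting frequency-dependent
  functional connectivity), and additive white noise.  The returned
  :class:`PhantomTruth` records everything that was drawn, so any
  downstream statistic can be checked against its generating value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .series import BOLDSeries

__all__ = [
    "ToneMixtureConfig",
    "ToneMixtures",
    "make_tone_mixtures",
    "BrainPhantomConfig",
    "PhantomTruth",
    "BrainPhantom",
    "make_brain_phantom",
    "write_phantom_nifti",
    "read_phantom_nifti",
    "TISSUE_LABELS",
]

# FAST-convention tissue encoding
TISSUE_LABELS = {"CSF": 1, "GM": 2, "WM": 3}


@dataclass(frozen=True)
class ToneMixtureConfig:
    """Four-tone Monte Carlo benchmark conditions.

    Defaults follow the study conditions: tones at 0.03/0.08/0.15/0.23 Hz
    sampled at TR = 2 s for 230 retained frames, 200 white-noise
    realizations at a signal-power-to-noise-power ratio of 1.2.
    """

    tone_freqs: tuple[float, ...] = (0.03, 0.08, 0.15, 0.23)
    dt: float = 2.0
    n_samples: int = 230
    snr_target: float = 1.2
    n_realizations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = 0.5 / self.dt
        if any(f >= nyq for f in self.tone_freqs):
            raise ValueError("all tone frequencies must be below Nyquist")
        if self.snr_target <= 0:
            raise ValueError("snr_target must be positive")


@dataclass
class ToneMixtures:
    """Clean four-tone signal plus its noisy realizations."""

    clean: BOLDSeries
    realizations: list[BOLDSeries]
    noises: list[np.ndarray]
    realized_snrs: np.ndarray
    config: ToneMixtureConfig


def make_tone_mixtures(config: ToneMixtureConfig | None = None) -> ToneMixtures:
    """Generate the benchmark signal and noise realizations.

    The clean signal is a sum of equal-amplitude cosines with random
    phases drawn once from the seed (the same clean signal underlies
    every realization).  Each realization adds fresh white noise scaled
    so that the expected signal-power/noise-power ratio equals
    ``snr_target``; the per-realization realized ratios are reported.
    """
    config = config or ToneMixtureConfig()
    rng = np.random.default_rng(config.seed)
    t = config.dt * np.arange(config.n_samples)
    phases = rng.uniform(0, 2 * np.pi, size=len(config.tone_freqs))
    clean_vals = np.sum(
        [np.cos(2 * np.pi * f * t + p)
         for f, p in zip(config.tone_freqs, phases)], axis=0)
    clean = BOLDSeries(clean_vals, dt=config.dt)
    p_sig = float(np.var(clean_vals))
    noise_sd = np.sqrt(p_sig / config.snr_target)
    realizations, noises, snrs = [], [], []
    for _ in range(config.n_realizations):
        w = rng.standard_normal(config.n_samples) * noise_sd
        noises.append(w)
        realizations.append(BOLDSeries(clean_vals + w, dt=config.dt))
        pn = float(np.var(w))
        snrs.append(p_sig / pn if pn > 0 else float("inf"))
    return ToneMixtures(clean=clean, realizations=realizations, noises=noises,
                        realized_snrs=np.asarray(snrs), config=config)


# ---------------------------------------------------------------------------
# Brain phantom
# ---------------------------------------------------------------------------

def _default_power_fractions() -> dict[str, tuple[float, ...]]:
    # mean fractional power per cluster (ascending center frequency);
    # the lowest-frequency cluster dominates, slightly more so in WM,
    # echoing the typical rs-fMRI power distribution
    return {
        "GM": (0.35, 0.30, 0.15, 0.20),
        "WM": (0.40, 0.30, 0.15, 0.15),
        "CSF": (0.30, 0.25, 0.25, 0.20),
    }


@dataclass(frozen=True)
class BrainPhantomConfig:
    """Configuration of the 4D brain phantom.

    Cluster centers/sds (ascending frequency) default to the four
    canonical rs-fMRI frequency clusters, with widths chosen so that
    center +/- 1.96 sd reproduces their typical reported ranges.
    ``sharing`` gives, per cluster, the mixing coefficient s between a
    block-shared component and each voxel's private oscillation
    (pairwise voxel correlation within a block is s^2 before noise); the
    default plants connectivity only in the two lowest-frequency
    clusters.  ``n_frames`` counts acquired frames; analyses customarily
    discard the first ``n_discard``.
    """

    shape: tuple[int, int, int] = (16, 16, 8)
    cluster_centers: tuple[float, ...] = (0.028, 0.080, 0.15, 0.22)
    cluster_sds: tuple[float, ...] = (0.004, 0.009, 0.010, 0.010)
    power_fractions: dict = field(default_factory=_default_power_fractions)
    fraction_concentration: float = 100.0
    n_rois: int = 12
    network_blocks: tuple[tuple[int, ...], ...] = ((1, 2, 3, 4), (5, 6, 7, 8),
                                                   (9, 10, 11, 12))
    sharing: tuple[float, ...] = (0.8, 0.6, 0.0, 0.0)
    tr: float = 2.0
    n_frames: int = 240
    n_discard: int = 10
    noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        c = len(self.cluster_centers)
        if len(self.cluster_sds) != c or len(self.sharing) != c:
            raise ValueError("cluster_centers, cluster_sds, sharing lengths differ")
        if any(s <= 0 for s in self.cluster_sds):
            raise ValueError("cluster_sds must be positive")
        if any(not (0 <= s <= 1) for s in self.sharing):
            raise ValueError("sharing coefficients must lie in [0, 1]")
        for tis, fr in self.power_fractions.items():
            if len(fr) != c:
                raise ValueError(f"power_fractions[{tis}] length != n clusters")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"power_fractions[{tis}] must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_centers)


@dataclass
class PhantomTruth:
    """Everything the phantom generator drew, for ground-truth checks."""

    voxel_coords: np.ndarray        # (V, 3) in-brain voxel indices
    tissue_of_voxel: np.ndarray     # (V,) FAST labels
    roi_of_voxel: np.ndarray        # (V,) 1-based ROI ids (0 = none)
    frequencies: np.ndarray         # (V, C) drawn per-voxel frequencies, Hz
    fractions: np.ndarray           # (V, C) per-voxel cluster power fractions
    shared_frequencies: dict        # (block index, cluster) -> Hz
    shared_series: dict             # (block index, cluster) -> (T,) array
    tissue_volume: np.ndarray       # (X, Y, Z) labels
    roi_volume: np.ndarray          # (X, Y, Z) 1-based ROI ids
    n_redrawn: int                  # frequencies redrawn for exceeding Nyquist
    config: BrainPhantomConfig


@dataclass
class BrainPhantom:
    """Generated 4D dataset plus its ground truth."""

    bold: np.ndarray                # (X, Y, Z, T)
    tissue: np.ndarray              # (X, Y, Z)
    rois: np.ndarray                # (X, Y, Z)
    tr: float
    truth: PhantomTruth

    def analyzed(self) -> np.ndarray:
        """BOLD with the initial discarded frames removed."""
        return self.bold[..., self.truth.config.n_discard:]


def _narrowband_noise(rng: np.random.Generator, n: int, dt: float,
                      center: float, sd: float) -> np.ndarray:
    """Unit-variance noise whose power spectrum is a Gaussian of the given
    center and width — the band-limited component shared within a network
    block."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=dt)
    spec *= np.exp(-((f - center) ** 2) / (4.0 * sd**2))  # amplitude envelope
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _phantom_geometry(config: BrainPhantomConfig):
    """Concentric-shell tissue labels (CSF core, WM shell, GM rind) and
    azimuthal-sector ROI labels within gray matter.  The geometry only
    provides labels; the statistics do not depend on it."""
    nx, ny, nz = config.shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = np.sqrt(((ix - cx) / (nx / 2)) ** 2 + ((iy - cy) / (ny / 2)) ** 2
                + ((iz - cz) / (nz / 2)) ** 2)
    tissue = np.zeros(config.shape, dtype=np.int16)
    tissue[r <= 0.35] = TISSUE_LABELS["CSF"]
    tissue[(r > 0.35) & (r <= 0.65)] = TISSUE_LABELS["WM"]
    tissue[(r > 0.65) & (r <= 1.0)] = TISSUE_LABELS["GM"]
    rois = np.zeros(config.shape, dtype=np.int16)
    gm = tissue == TISSUE_LABELS["GM"]
    theta = np.arctan2(iy - cy, ix - cx)  # (-pi, pi]
    sector = np.floor((theta + np.pi) / (2 * np.pi) * config.n_rois)
    sector = np.clip(sector, 0, config.n_rois - 1).astype(np.int16)
    rois[gm] = sector[gm] + 1
    return tissue, rois


def make_brain_phantom(config: BrainPhantomConfig | None = None) -> BrainPhantom:
    """Generate a seeded 4D brain phantom with known frequency clusters.

    Each in-brain voxel's series is sum_c sqrt(frac_c) * x_c + noise,
    where x_c is a unit-variance cosine at a frequency drawn from cluster
    c's Gaussian (redrawn if at/above Nyquist or non-positive).  Inside a
    network block, x_c is mixed with the block's shared component — unit
    variance band-limited noise with cluster c's Gaussian power spectrum —
    as sqrt(1-s^2) * private + s * shared, preserving unit variance.
    """
    config = config or BrainPhantomConfig()
    rng = np.random.default_rng(config.seed)
    tissue, rois = _phantom_geometry(config)
    mask = tissue > 0
    coords = np.argwhere(mask)
    v = coords.shape[0]
    c = config.n_clusters
    t_axis = config.tr * np.arange(config.n_frames)
    centers = np.asarray(config.cluster_centers)
    sds = np.asarray(config.cluster_sds)

    # per-voxel frequencies, truncated to (0, Nyquist)
    freqs = rng.normal(centers, sds, size=(v, c))
    n_redrawn = 0
    bad = (freqs >= config.nyquist) | (freqs <= 0)
    while np.any(bad):
        n_redrawn += int(bad.sum())
        freqs[bad] = rng.normal(np.broadcast_to(centers, (v, c))[bad],
                                np.broadcast_to(sds, (v, c))[bad])
        bad = (freqs >= config.nyquist) | (freqs <= 0)

    # per-voxel power fractions around the tissue means
    tiss_of_voxel = tissue[mask]
    label_to_name = {val: name for name, val in TISSUE_LABELS.items()}
    fractions = np.empty((v, c))
    for lbl in np.unique(tiss_of_voxel):
        name = label_to_name[int(lbl)]
        mean = np.asarray(config.power_fractions[name])
        sel = tiss_of_voxel == lbl
        fractions[sel] = rng.dirichlet(mean * config.fraction_concentration,
                                       size=int(sel.sum()))

    # block-shared components (unit-variance cosines in the cluster band)
    roi_of_voxel = rois[mask]
    block_of_roi: dict[int, int] = {}
    for b, block in enumerate(config.network_blocks):
        for roi in block:
            block_of_roi[int(roi)] = b
    shared_freqs: dict[tuple[int, int], float] = {}
    shared_series: dict[tuple[int, int], np.ndarray] = {}
    for b in range(len(config.network_blocks)):
        for cc in range(c):
            if config.sharing[cc] <= 0:
                continue
            shared_freqs[(b, cc)] = float(centers[cc])
            shared_series[(b, cc)] = _narrowband_noise(
                rng, config.n_frames, config.tr, centers[cc], sds[cc])

    phases = rng.uniform(0, 2 * np.pi, size=(v, c))
    private = np.sqrt(2.0) * np.cos(
        2 * np.pi * freqs[:, :, None] * t_axis[None, None, :]
        + phases[:, :, None])                       # (V, C, T)
    comps = private
    sharing = np.asarray(config.sharing)
    if shared_series:
        comps = private.copy()
        for (b, cc), sh in shared_series.items():
            s = sharing[cc]
            in_block = np.isin(roi_of_voxel,
                               list(config.network_blocks[b]))
            comps[in_block, cc, :] = (np.sqrt(1 - s**2)
                                      * private[in_block, cc, :]
                                      + s * sh[None, :])
    amps = np.sqrt(fractions)                        # (V, C)
    signals = np.einsum("vc,vct->vt", amps, comps)
    noise = rng.standard_normal((v, config.n_frames)) * config.noise_sd
    series = signals + noise

    bold = np.zeros(config.shape + (config.n_frames,))
    bold[mask] = series
    truth = PhantomTruth(voxel_coords=coords, tissue_of_voxel=tiss_of_voxel,
                         roi_of_voxel=roi_of_voxel, frequencies=freqs,
                         fractions=fractions, shared_frequencies=shared_freqs,
                         shared_series=shared_series, tissue_volume=tissue,
                         roi_volume=rois, n_redrawn=n_redrawn, config=config)
    return BrainPhantom(bold=bold, tissue=tissue, rois=rois, tr=config.tr,
                        truth=truth)


# ---------------------------------------------------------------------------
# NIfTI persistence
# ---------------------------------------------------------------------------

def _nifti_image(data: np.ndarray, tr: float | None = None):
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    if tr is not None:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    return img


def write_phantom_nifti(phantom: BrainPhantom, directory: str | Path) -> dict:
    """Write BOLD, tissue and ROI volumes as NIfTI-1 plus the truth record.

    The TR is stored in the time-axis header field.  Returns the mapping
    of artifact names to paths; a read-back reproduces the arrays exactly.
    """
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": directory / "phantom_bold.nii.gz",
        "tissue": directory / "phantom_tissue.nii.gz",
        "rois": directory / "phantom_rois.nii.gz",
        "truth": directory / "phantom_truth.json",
    }
    nib.save(_nifti_image(phantom.bold, tr=phantom.tr), paths["bold"])
    nib.save(_nifti_image(phantom.tissue.astype(np.int16)), paths["tissue"])
    nib.save(_nifti_image(phantom.rois.astype(np.int16)), paths["rois"])
    tr = phantom.truth
    payload = {
        "voxel_coords": tr.voxel_coords.tolist(),
        "tissue_of_voxel": tr.tissue_of_voxel.tolist(),
        "roi_of_voxel": tr.roi_of_voxel.tolist(),
        "frequencies": tr.frequencies.tolist(),
        "fractions": tr.fractions.tolist(),
        "shared_frequencies": {f"{b},{c}": f
                               for (b, c), f in tr.shared_frequencies.items()},
        "n_redrawn": tr.n_redrawn,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(tr.config).items()},
    }
    paths["truth"].write_text(json.dumps(payload))
    return paths


def read_phantom_nifti(directory: str | Path):
    """Read back the volumes written by :func:`write_phantom_nifti`.

    Returns (bold, tissue, rois, tr_seconds, truth_payload).
    """
    import nibabel as nib

    directory = Path(directory)
    bold_img = nib.load(directory / "phantom_bold.nii.gz")
    bold = np.asarray(bold_img.dataobj)
    tr = float(bold_img.header.get_zooms()[3])
    tissue = np.asarray(nib.load(directory / "phantom_tissue.nii.gz").dataobj)
    rois = np.asarray(nib.load(directory / "phantom_rois.nii.gz").dataobj)
    truth = json.loads((directory / "phantom_truth.json").read_text())
    return bold, tissue, rois, tr, truth
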