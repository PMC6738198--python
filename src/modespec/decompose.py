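"""Modal decomposition of BOLD time series.

Three decompositions are provided:

* ``vmd_decompose`` — variational mode decomposition (VMD).  All K modes
  are extracted concurrently by minimizing the summed modal bandwidth
  (H1 smoothness of each demodulated mode) subject to reconstruction,
  solved in the frequency domain by alternating Wiener-filter mode
  updates, center-frequency updates (power-spectral center of mass of
  each mode) and an optional dual ascent on the reconstruction
  constraint.
* ``emd_decompose`` — classic empirical mode decomposition by recursive
  sifting with cubic-spline envelopes.
* ``ceemd_decompose`` — complementary ensemble EMD: EMD averaged over
  pairs of positively and negatively noise-perturbed copies of the
  signal.

The bandwidth penalty ``alpha`` of VMD trades spectral compactness of
the modes against reconstruction fidelity; ``select_alpha`` picks the
smallest candidate that minimizes inter-modal spectral overlap while
keeping the relative reconstruction error under a cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .series import BOLDSeries
from . import spectral
from .spectral import Band, Spectrum

__all__ = [
    "VMDConfig",
    "EMDConfig",
    "IMFSet",
    "vmd_decompose",
    "vmd_decompose_batch",
    "select_alpha",
    "AlphaSelection",
    "emd_decompose",
    "ceemd_decompose",
    "save_imfset",
    "load_imfset",
]

DEFAULT_ALPHA_GRID = tuple(np.logspace(1.0, 4.0, 13))


@dataclass(frozen=True)
class VMDConfig:
    """Settings for variational mode decomposition.

    Parameters
    ----------
    n_modes
        Number K of modes to extract.
    alpha
        Bandwidth penalty; larger values give narrower modes.
    tau
        Dual-ascent step on the reconstruction constraint.  The default 0
        disables exact-reconstruction enforcement, appropriate for noisy
        data where the noise floor should not be forced into the modes.
    tol
        Convergence threshold on the summed relative change of all modes.
    max_iter
        Iteration cap.
    init_scheme
        Center-frequency initialization: 'peaks' (default) seeds each
        series' centers at its strongest periodogram peaks, 'uniform'
        spaces them over (0, Nyquist), 'zero' starts all at 0, 'random'
        draws uniformly.
    dc_mode
        If True, pins the first mode's center frequency at 0.
    seed
        Seed for 'random' initialization.
    """

    n_modes: int = 4
    alpha: float = 1000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init_scheme: str = "peaks"
    dc_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0 < self.tol < 1):
            raise ValueError("tol must lie in (0, 1)")
        if self.init_scheme not in ("peaks", "uniform", "zero", "random"):
            raise ValueError(f"unknown init_scheme {self.init_scheme!r}")


@dataclass(frozen=True)
class EMDConfig:
    """Settings for EMD and CEEMD.

    ``sift_tol`` is the Cauchy stopping threshold on successive sift
    iterates; ``ensemble_size`` counts complementary noise *pairs*;
    ``noise_scale`` is the added-noise standard deviation as a fraction
    of the signal standard deviation.
    """

    sift_tol: float = 0.2
    max_sifts: int = 100
    max_imfs: int = 12
    ensemble_size: int = 100
    noise_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sift_tol <= 0 or self.max_sifts <= 0 or self.max_imfs <= 0:
            raise ValueError("sift_tol, max_sifts, max_imfs must be positive")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class IMFSet:
    """Modes extracted from one series.

    ``modes`` has shape (K, N) and is sorted by ascending center
    frequency; ``center_freqs`` are the spectral center-of-mass
    frequencies (Hz) of each mode.  ``residual`` is defined as
    ``input - sum(modes)``, so the reconstruction identity holds to
    floating-point roundoff.
    """

    modes: np.ndarray
    center_freqs: np.ndarray
    residual: np.ndarray
    dt: float
    n_iter: int
    converged: bool
    method: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def mode_series(self, k: int) -> BOLDSeries:
        return BOLDSeries(self.modes[k], dt=self.dt)

    def mode_spectra(self) -> list[Spectrum]:
        return [spectral.psd(self.mode_series(k)) for k in range(self.n_modes)]

    def reconstruction(self) -> np.ndarray:
        return self.modes.sum(axis=0) + self.residual

    def relative_residual_power(self) -> float:
        """Relative squared reconstruction residual of the mode sum
        against the demeaned input."""
        x = self.reconstruction()
        xd = x - x.mean()
        r = xd - (self.modes.sum(axis=0) - self.modes.sum(axis=0).mean())
        denom = float(np.sum(xd**2))
        if denom == 0:
            return 0.0
        return float(np.sum(r**2)) / denom


def _sort_modes(modes: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Sort modes ascending by center-of-mass frequency (zero-power modes
    sort last with NaN frequency)."""
    freqs = np.empty(modes.shape[0])
    for k in range(modes.shape[0]):
        if np.allclose(modes[k], modes[k].mean()):
            freqs[k] = np.nan
        else:
            freqs[k] = spectral.com_frequency(
                spectral.psd(BOLDSeries(modes[k], dt=dt)))
    order = np.argsort(np.where(np.isnan(freqs), np.inf, freqs))
    return modes[order], freqs[order]


# ---------------------------------------------------------------------------
# VMD
# ---------------------------------------------------------------------------

def _mirror_extend(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Mirror-extend each row by half its length on both sides."""
    n = x.shape[-1]
    h = n // 2
    left = x[..., h - 1::-1] if h > 0 else x[..., :0]
    right = x[..., :n - h - 1:-1] if n - h > 0 else x[..., :0]
    return np.concatenate([left, x, right], axis=-1), h


def _init_omegas(x: np.ndarray, k: int, scheme: str, seed: int) -> np.ndarray:
    """Initial center frequencies in cycles/sample, shape (v, k).

    'peaks' seeds each series' centers at its k most prominent
    periodogram peaks (padded with uniformly spaced values when fewer
    exist), which keeps modes from being captured by a stronger neighbor
    basin; 'uniform' spaces them evenly over (0, Nyquist).
    """
    from scipy.signal import find_peaks

    v = x.shape[0]
    uniform = 0.5 * (np.arange(1, k + 1) / (k + 1))
    if scheme == "uniform":
        return np.tile(uniform, (v, 1))
    if scheme == "zero":
        return np.zeros((v, k))
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return np.sort(rng.uniform(0.0, 0.5, size=(v, k)), axis=1)
    # peaks
    freqs = np.fft.rfftfreq(x.shape[-1])
    dens = np.abs(np.fft.rfft(x - x.mean(axis=-1, keepdims=True),
                              axis=-1)) ** 2
    out = np.empty((v, k))
    for i in range(v):
        pk, props = find_peaks(dens[i], prominence=0.0)
        if pk.size:
            top = pk[np.argsort(props["prominences"])[::-1][:k]]
            om = np.sort(freqs[top])
        else:
            om = np.empty(0)
        if om.size < k:
            om = np.sort(np.concatenate([om, uniform[:k - om.size]]))
        out[i] = om
    return out


def _vmd_kernel(x: np.ndarray, config: VMDConfig):
    """Batched VMD core.

    Parameters
    ----------
    x
        (V, N) demeaned input rows.

    Returns
    -------
    modes : (V, K, N) time-domain modes (unsorted, in solver order)
    omegas : (V, K) converged center frequencies, cycles/sample
    n_iter : (V,) iterations used per row
    converged : (V,) bool
    history : list of per-iteration convergence functionals (only when V == 1)
    """
    v, n = x.shape
    k = config.n_modes
    xm, crop = _mirror_extend(x)
    t = xm.shape[-1]
    f_hat = np.fft.rfft(xm, axis=-1)            # (V, F) one-sided
    freqs = np.fft.rfftfreq(t)                  # cycles/sample
    nf = freqs.size

    u_hat = np.zeros((v, k, nf), dtype=complex)
    lam = np.zeros((v, nf), dtype=complex)
    omega = _init_omegas(x, k, config.init_scheme, config.seed)
    if config.dc_mode:
        omega[:, 0] = 0.0
    sum_u = np.zeros((v, nf), dtype=complex)

    active = np.ones(v, dtype=bool)
    n_iter = np.full(v, config.max_iter, dtype=int)
    eps = np.finfo(float).eps
    history: list[float] = []

    for it in range(config.max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        fa = f_hat[idx]
        la = lam[idx]
        sa = sum_u[idx]
        ua = u_hat[idx]
        oa = omega[idx]
        diff = np.zeros(idx.size)
        for kk in range(k):
            sa = sa - ua[:, kk]
            denom = 1.0 + 2.0 * config.alpha * (freqs[None, :]
                                                - oa[:, kk, None]) ** 2
            u_new = (fa - sa + la / 2.0) / denom
            old = ua[:, kk]
            diff += (np.sum(np.abs(u_new - old) ** 2, axis=-1)
                     / (np.sum(np.abs(old) ** 2, axis=-1) + eps))
            ua[:, kk] = u_new
            sa = sa + u_new
            if not (config.dc_mode and kk == 0):
                p = np.abs(u_new) ** 2
                oa[:, kk] = (p @ freqs) / (p.sum(axis=-1) + eps)
        if config.tau > 0:
            la = la + config.tau * (sa - fa)
        u_hat[idx] = ua
        omega[idx] = oa
        sum_u[idx] = sa
        lam[idx] = la
        if v == 1:
            history.append(float(diff[0]))
        done = diff < config.tol
        if np.any(done):
            n_iter[idx[done]] = it + 1
            active[idx[done]] = False

    converged = n_iter < config.max_iter
    modes_full = np.fft.irfft(u_hat, n=t, axis=-1)
    modes = modes_full[..., crop:crop + n]
    return modes, omega, n_iter, converged, history


def vmd_decompose_batch(values: np.ndarray, dt: float,
                        config: VMDConfig) -> list[IMFSet]:
    """Run VMD on many equal-length series at once (vectorized solver).

    Per-row iteration counts equal those of single-series
    :func:`vmd_decompose` calls and the modes agree to floating-point
    roundoff (summation order differs across batch shapes).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be (n_series, n_samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input")
    n = x.shape[1]
    if n < 32:
        raise ValueError("series too short for decomposition (need >= 32)")
    if config.n_modes > n // 4:
        raise ValueError("n_modes exceeds length/4")
    means = x.mean(axis=1, keepdims=True)
    modes, omega, n_iter, converged, history = _vmd_kernel(x - means, config)
    n_unconverged = int(np.sum(~converged))
    if n_unconverged:
        warnings.warn(
            f"VMD did not converge within {config.max_iter} iterations for "
            f"{n_unconverged} of {x.shape[0]} series",
            RuntimeWarning, stacklevel=2)
    out: list[IMFSet] = []
    for i in range(x.shape[0]):
        m_sorted, freqs = _sort_modes(modes[i], dt)
        residual = x[i] - m_sorted.sum(axis=0)
        diag = {"omega_hz": np.sort(omega[i]) / dt, "alpha": config.alpha}
        # duplicate-center diagnostic: keep both modes, only flag
        fin = freqs[np.isfinite(freqs)]
        if fin.size > 1 and np.any(np.diff(np.sort(fin)) < 1e-6):
            diag["duplicate_centers"] = True
        if history:
            diag["convergence_history"] = np.asarray(history)
        out.append(IMFSet(modes=m_sorted, center_freqs=freqs,
                          residual=residual, dt=dt,
                          n_iter=int(n_iter[i]), converged=bool(converged[i]),
                          method="VMD", diagnostics=diag))
    return out


def vmd_decompose(series: BOLDSeries, config: VMDConfig) -> IMFSet:
    """Variational mode decomposition of one series into K modes."""
    return vmd_decompose_batch(series.values[None, :], series.dt, config)[0]


@dataclass(frozen=True)
class AlphaSelection:
    """Outcome of the bandwidth-penalty grid search."""

    alpha: float
    table: "object"     # pandas.DataFrame: alpha, overlap, recon_error, feasible
    flagged: bool       # True when no candidate met the reconstruction cap


def select_alpha(series: BOLDSeries, K: int,
                 grid: Sequence[float] | None = None,
                 recon_cap: float = 0.25,
                 config: VMDConfig | None = None) -> AlphaSelection:
    """Pick the VMD bandwidth penalty from a candidate grid.

    For each candidate the series is decomposed and two diagnostics are
    computed: the mean fractional spectral overlap between modes (each
    mode scored against a midpoint partition of the band built from the
    K mode center frequencies) and the relative squared reconstruction
    error.  The selected alpha is the smallest candidate among those
    minimizing the overlap subject to ``recon_error <= recon_cap``; if no
    candidate satisfies the cap, the one with the smallest error is
    returned and flagged.
    """
    import pandas as pd

    grid = DEFAULT_ALPHA_GRID if grid is None else tuple(grid)
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if list(grid) != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    base = config or VMDConfig(n_modes=K)
    if base.n_modes != K:
        base = replace(base, n_modes=K)

    xd = series.values - series.values.mean()
    denom = float(np.sum(xd**2))
    rows = []
    for a in grid:
        imfs = vmd_decompose(series, replace(base, alpha=float(a)))
        specs = imfs.mode_spectra()
        fin = imfs.center_freqs[np.isfinite(imfs.center_freqs)]
        if fin.size <= 1:
            overlap = 0.0
        else:
            bands = spectral.midpoint_bands(fin, 0.0, series.nyquist + 1e-12)
            overlap = spectral.fractional_overlap(specs, bands).mean
        recon = imfs.modes.sum(axis=0)
        err = float(np.sum((xd - (recon - recon.mean()))**2)) / max(denom, 1e-300)
        rows.append((float(a), overlap, err))
    table = pd.DataFrame(rows, columns=["alpha", "overlap", "recon_error"])
    table["feasible"] = table["recon_error"] <= recon_cap
    feas = table[table["feasible"]]
    if feas.empty:
        best = table.loc[table["recon_error"].idxmin()]
        return AlphaSelection(alpha=float(best["alpha"]), table=table,
                              flagged=True)
    min_ov = feas["overlap"].min()
    winners = feas[feas["overlap"] <= min_ov + 1e-12]
    return AlphaSelection(alpha=float(winners["alpha"].iloc[0]), table=table,
                          flagged=False)


# ---------------------------------------------------------------------------
# EMD / CEEMD
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima."""
    d = np.diff(x)
    # collapse flat segments by treating ties with the previous slope sign
    s = np.sign(d)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    ds = np.diff(s)
    maxima = np.flatnonzero(ds < 0) + 1
    minima = np.flatnonzero(ds > 0) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Natural cubic-spline envelope through extrema, end extrema mirrored
    across the signal boundaries."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    n_ref = min(2, idx.size)
    tl = -t[:n_ref][::-1]
    vl = v[:n_ref][::-1]
    tr = 2.0 * (n - 1) - t[-n_ref:][::-1]
    vr = v[-n_ref:][::-1]
    tt = np.concatenate([tl, t, tr])
    vv = np.concatenate([vl, v, vr])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    cs = CubicSpline(tt[keep], vv[keep], bc_type="natural")
    return cs(np.arange(n, dtype=float))


def _emd_core(x: np.ndarray, config: EMDConfig) -> list[np.ndarray]:
    """Sifting loop; returns IMFs in extraction order (high frequency
    first).  Monotone input yields an empty list."""
    imfs: list[np.ndarray] = []
    r = x.astype(float).copy()
    eps = np.finfo(float).eps
    total_energy = float(np.sum(x.astype(float) ** 2)) + eps
    while len(imfs) < config.max_imfs:
        if float(np.sum(r**2)) < 1e-10 * total_energy:
            break  # remainder is numerical residue
        maxima, minima = _local_extrema(r)
        if maxima.size < 2 or minima.size < 2:
            break
        h = r.copy()
        for _ in range(config.max_sifts):
            upper = _envelope(h, maxima)
            lower = _envelope(h, minima)
            mean_env = (upper + lower) / 2.0
            h_new = h - mean_env
            sd = float(np.sum((h - h_new) ** 2) / (np.sum(h**2) + eps))
            h = h_new
            if sd < config.sift_tol:
                break
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
        if float(np.sum(h**2)) < 1e-12 * total_energy:
            break  # sift yielded numerical residue, remainder is a trend
        imfs.append(h)
        r = r - h
        maxima, minima = _local_extrema(r)
        if maxima.size < 2 or minima.size < 2:
            break
    return imfs


def _imfset_from_modes(x: np.ndarray, modes: list[np.ndarray], dt: float,
                       method: str, diagnostics: dict | None = None) -> IMFSet:
    if modes:
        m = np.asarray(modes)
        m_sorted, freqs = _sort_modes(m, dt)
    else:
        m_sorted = np.zeros((0, x.size))
        freqs = np.zeros(0)
    residual = x - m_sorted.sum(axis=0)
    return IMFSet(modes=m_sorted, center_freqs=freqs, residual=residual,
                  dt=dt, n_iter=len(modes), converged=True, method=method,
                  diagnostics=diagnostics or {})


def emd_decompose(series: BOLDSeries, config: EMDConfig | None = None) -> IMFSet:
    """Classic EMD by recursive sifting.

    At each sift the mean of the cubic-spline envelopes of the local
    maxima and minima is subtracted until the Cauchy criterion drops
    below ``sift_tol``; the extracted IMF is removed and sifting repeats
    on the remainder until it is monotone or ``max_imfs`` is reached.
    """
    config = config or EMDConfig()
    x = np.asarray(series.values, dtype=float)
    modes = _emd_core(x, config)
    return _imfset_from_modes(x, modes, series.dt, "EMD",
                              {"extraction_order_count": len(modes)})


def ceemd_decompose(series: BOLDSeries, config: EMDConfig | None = None) -> IMFSet:
    """Complementary ensemble EMD.

    EMD is run on ``ensemble_size`` pairs (signal + w_i, signal - w_i) of
    white-noise-perturbed copies and the IMFs are averaged across the
    ensemble, aligned by extraction index (shorter decompositions padded
    with zero modes).  Deterministic under a fixed seed.
    """
    config = config or EMDConfig()
    x = np.asarray(series.values, dtype=float)
    rng = np.random.default_rng(config.seed)
    sd = config.noise_scale * float(np.std(x))
    all_runs: list[list[np.ndarray]] = []
    for _ in range(config.ensemble_size):
        w = rng.standard_normal(x.size) * sd
        all_runs.append(_emd_core(x + w, config))
        all_runs.append(_emd_core(x - w, config))
    n_modes = max((len(r) for r in all_runs), default=0)
    if n_modes == 0:
        return _imfset_from_modes(x, [], series.dt, "CEEMD")
    acc = np.zeros((n_modes, x.size))
    for run in all_runs:
        for j, m in enumerate(run):
            acc[j] += m
    acc /= len(all_runs)
    return _imfset_from_modes(
        x, list(acc), series.dt, "CEEMD",
        {"ensemble_runs": len(all_runs),
         "mode_count_range": (min(len(r) for r in all_runs), n_modes)})


# ---------------------------------------------------------------------------
# Text persistence
# ---------------------------------------------------------------------------

def save_imfset(imfs: IMFSet, path: str | Path) -> None:
    """Write an IMF set as delimited text: one column per mode plus the
    residual, with center frequencies (Hz) in the header."""
    path = Path(path)
    cols = np.column_stack([imfs.modes.T, imfs.residual]) \
        if imfs.n_modes else imfs.residual[:, None]
    names = [f"mode_{f:.6g}Hz" for f in imfs.center_freqs] + ["residual"]
    meta = (f"# dt={imfs.dt!r} method={imfs.method} n_iter={imfs.n_iter} "
            f"converged={imfs.converged}")
    header = meta + "\n" + "\t".join(names)
    np.savetxt(path, cols, delimiter="\t", header=header, comments="")


def load_imfset(path: str | Path) -> IMFSet:
    """Round-trip reader for :func:`save_imfset` output."""
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline().strip().lstrip("# ").split()
        names = fh.readline().strip().split("\t")
    kv = dict(item.split("=", 1) for item in meta)
    data = np.loadtxt(path, delimiter="\t", skiprows=2)
    if data.ndim == 1:
        data = data[:, None]
    modes = data[:, :-1].T
    freqs = np.array([float(n[len("mode_"):-2]) for n in names[:-1]])
    return IMFSet(modes=modes, center_freqs=freqs, residual=data[:, -1],
                  dt=float(kv["dt"]), n_iter=int(kv["n_iter"]),
                  converged=kv["converged"] == "True", method=kv["method"])
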