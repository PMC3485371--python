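"""Segmented Fourier analysis of virtual-electrode time series.

Computes magnitude-squared coherence for every node-pair and spectral power
for every node, per experimental block and subject, and assembles the
labelled 4-D tensors that feed the mean-centered PLS stage:

* coherence: ``(block, subject, freq, pair)``
* power:     ``(block, subject, freq, node)``

The estimator is the classic overlapping-segment (Welch) scheme: each block
is cut into ``n_fft``-sample segments advanced by ``hop`` samples, each
segment is de-meaned, Hanning-tapered and Fourier transformed, and cross- and
auto-spectra are accumulated over segments.  With the default grid
(fs = 300 Hz, 256-point transform, 4–64 Hz band of interest) there are 51
analysis bins.

No normalisation is applied to the power spectra: coherence is scale-free by
construction, and power enters the downstream analysis mean-centered, so only
relative (within-run) scale matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.signal import get_window

from .dataset import VirtualElectrodeDataset

__all__ = [
    "SpectralConfig",
    "enumerate_pairs",
    "analysis_bins",
    "segment_starts",
    "segment_spectra",
    "coherence",
    "power_spectrum",
    "build_tensors",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the segmented spectral analysis.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    n_fft : int
        Samples per segment (transform length).  256 samples at 300 Hz is
        0.853 s; this is the length consistent with a 256-bin transform whose
        4–64 Hz restriction holds exactly 51 bins.
    hop : int
        Samples between consecutive segment starts (150 = 0.5 s at 300 Hz).
    window : str
        Taper name understood by :func:`scipy.signal.get_window`.
    f_min, f_max : float
        Analysis range in Hz, inclusive on both ends.
    analysis_duration : float
        Seconds of each block entering the analysis (the first
        ``analysis_duration`` seconds; blocks are length-matched this way).
    truncate_incomplete : bool
        If True, blocks shorter than ``analysis_duration`` are used in full;
        if False (default) they raise.
    """

    fs: float = 300.0
    n_fft: int = 256
    hop: int = 150
    window: str = "hann"
    f_min: float = 4.0
    f_max: float = 64.0
    analysis_duration: float = 360.0
    truncate_incomplete: bool = False

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_fft < 2:
            raise ValueError("n_fft must be at least 2")
        if self.hop < 1:
            raise ValueError("hop must be at least 1")
        if not (0 <= self.f_min < self.f_max <= self.fs / 2):
            raise ValueError(
                f"need 0 <= f_min < f_max <= fs/2, got [{self.f_min}, {self.f_max}] at fs={self.fs}"
            )
        if self.n_fft > self.fs * self.analysis_duration:
            raise ValueError("analysis_duration too short for one segment")

    @property
    def n_analysis_samples(self) -> int:
        return int(round(self.fs * self.analysis_duration))

    def taper(self) -> np.ndarray:
        return get_window(self.window, self.n_fft)


def enumerate_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """All unordered node-pairs (i, j), i < j, in lexicographic order.

    80 nodes give the study's 3160 pair-wise combinations.
    """
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    return [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]


def analysis_bins(config: SpectralConfig) -> list[tuple[int, float]]:
    """Indices and center frequencies of the analysis bins.

    Bin k sits at ``k * fs / n_fft``; bins with ``f_min <= f <= f_max``
    (inclusive on both ends) are retained, in ascending order.
    """
    df = config.fs / config.n_fft
    k_lo = int(np.ceil(config.f_min / df - 1e-9))
    k_hi = int(np.floor(config.f_max / df + 1e-9))
    k_hi = min(k_hi, config.n_fft // 2)
    bins = [(k, k * df) for k in range(max(k_lo, 0), k_hi + 1)]
    if not bins:
        raise ValueError(
            f"no analysis bins in [{config.f_min}, {config.f_max}] Hz at "
            f"fs={config.fs}, n_fft={config.n_fft}"
        )
    return bins


def segment_starts(n_samples: int, n_fft: int, hop: int) -> np.ndarray:
    """Start indices 0, hop, 2*hop, ... of full segments within the record."""
    if n_samples < n_fft:
        raise ValueError(
            f"record of {n_samples} samples shorter than one {n_fft}-sample segment"
        )
    n_seg = (n_samples - n_fft) // hop + 1
    return np.arange(n_seg) * hop


def segment_spectra(x: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """Complex spectra of all segments of ``x`` at the analysis bins.

    Each segment is de-meaned, tapered with the configured window and
    transformed with an ``n_fft``-point FFT; only the analysis bins are
    returned.  Output shape ``(n_segments, n_bins)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D time series")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains non-finite values")
    segs = _windowed_segments(x[np.newaxis, :], config)[0]
    idx = np.array([k for k, _ in analysis_bins(config)])
    return np.fft.rfft(segs, n=config.n_fft, axis=-1)[:, idx]


def _windowed_segments(x: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """De-meaned, tapered segments of each row of ``x``: (n_sig, n_seg, n_fft)."""
    starts = segment_starts(x.shape[-1], config.n_fft, config.hop)
    segs = x[:, starts[:, None] + np.arange(config.n_fft)]
    segs = segs - segs.mean(axis=-1, keepdims=True)
    return segs * config.taper()


def _auto_cross(x: np.ndarray, y: np.ndarray, config: SpectralConfig):
    """Auto- and cross-spectra summed over segments.

    The cross term is accumulated in explicitly symmetric real arithmetic so
    that swapping x and y changes only the sign of the imaginary part,
    making magnitude-squared coherence exactly symmetric in floating point.
    """
    X = segment_spectra(x, config)
    Y = X if y is x else segment_spectra(np.asarray(y, dtype=float), config)
    sxx = np.sum(X.real**2 + X.imag**2, axis=0)
    syy = np.sum(Y.real**2 + Y.imag**2, axis=0)
    re = np.sum(X.real * Y.real + X.imag * Y.imag, axis=0)
    im = np.sum(X.imag * Y.real - X.real * Y.imag, axis=0)
    return sxx, syy, re**2 + im**2, X.shape[0]


def coherence(x: np.ndarray, y: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """Magnitude-squared coherence of two equal-length series at the analysis bins.

    ``C(f) = |sum_seg X conj(Y)|^2 / (sum_seg |X|^2 * sum_seg |Y|^2)``,
    bounded in [0, 1].  Bins at which either signal has zero total power are
    returned as NaN (flagged missing) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    sxx, syy, sxy_sq, _ = _auto_cross(x, y, config)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        c = sxy_sq / denom
    c = np.where(denom > 0, c, np.nan)
    return np.clip(c, 0.0, 1.0, out=c)


def power_spectrum(x: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """Segment-averaged power ``P(f) = sum_seg |X(f)|^2 / n_segments``."""
    sxx, _, _, n_seg = _auto_cross(np.asarray(x, dtype=float), x, config)
    return sxx / n_seg


def _block_spectra(block: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """Analysis-bin spectra for every node of one block: (n_nodes, n_seg, n_bins)."""
    if not np.all(np.isfinite(block)):
        raise ValueError("block contains non-finite samples")
    segs = _windowed_segments(np.asarray(block, dtype=float), config)
    idx = np.array([k for k, _ in analysis_bins(config)])
    return np.fft.rfft(segs, n=config.n_fft, axis=-1)[:, :, idx]


def build_tensors(
    dataset: VirtualElectrodeDataset, config: SpectralConfig
) -> tuple[xr.DataArray, xr.DataArray]:
    """Coherence and power tensors for a full multi-subject, multi-block dataset.

    Only the first ``analysis_duration`` seconds of each block are used, so
    rest and task blocks of unequal raw duration contribute equal data.

    Returns
    -------
    coherence : xr.DataArray
        dims ``(block, subject, freq, pair)`` with auxiliary coords
        ``node_i``/``node_j`` on the pair axis (lexicographic i<j order).
    power : xr.DataArray
        dims ``(block, subject, freq, node)``.
    """
    if abs(dataset.fs - config.fs) > 1e-9:
        raise ValueError(
            f"dataset sampled at {dataset.fs} Hz but config expects {config.fs} Hz"
        )
    n_use = config.n_analysis_samples
    if dataset.n_samples < n_use:
        if not config.truncate_incomplete:
            raise ValueError(
                f"blocks hold {dataset.n_samples} samples but analysis_duration "
                f"requires {n_use}; shorten analysis_duration or set "
                "truncate_incomplete=True"
            )
        n_use = dataset.n_samples

    bins = analysis_bins(config)
    freqs = np.array([f for _, f in bins])
    pairs = enumerate_pairs(dataset.n_nodes)
    iu = np.array([p[0] for p in pairs])
    ju = np.array([p[1] for p in pairs])

    n_blocks, n_subj = dataset.n_blocks, dataset.n_subjects
    coh = np.empty((n_blocks, n_subj, len(bins), len(pairs)))
    pow_ = np.empty((n_blocks, n_subj, len(bins), dataset.n_nodes))

    for b in range(n_blocks):
        for s in range(n_subj):
            X = _block_spectra(dataset.data[s, b, :, :n_use], config)
            n_seg = X.shape[1]
            # cross-spectral matrix per bin, summed over segments
            S = np.einsum("isf,jsf->ijf", X, np.conj(X))
            auto = np.real(np.einsum("iif->if", S))
            pow_[b, s] = (auto / n_seg).T
            denom = auto[iu] * auto[ju]
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.abs(S[iu, ju]) ** 2 / denom
            c = np.where(denom > 0, c, np.nan)
            coh[b, s] = np.clip(c, 0.0, 1.0).T

    common = {"block": list(dataset.block_labels), "subject": list(dataset.subject_ids)}
    coh_da = xr.DataArray(
        coh,
        dims=("block", "subject", "freq", "pair"),
        coords={
            **common,
            "freq": freqs,
            "pair": np.arange(len(pairs)),
            "node_i": ("pair", [dataset.node_ids[i] for i in iu]),
            "node_j": ("pair", [dataset.node_ids[j] for j in ju]),
        },
        name="coherence",
        attrs={"fs": config.fs, "n_fft": config.n_fft, "hop": config.hop},
    )
    pow_da = xr.DataArray(
        pow_,
        dims=("block", "subject", "freq", "node"),
        coords={**common, "freq": freqs, "node": list(dataset.node_ids)},
        name="power",
        attrs={"fs": config.fs, "n_fft": config.n_fft, "hop": config.hop},
    )
    return coh_da, pow_da
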