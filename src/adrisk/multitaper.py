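"""Multitaper time-frequency estimation with Slepian (DPSS) tapers.

The power spectrum of each sliding window is estimated by tapering the
data with K discrete prolate spheroidal sequences — the eigenfunctions
of the spectral-concentration operator, whose eigenvalues lambda_k give
the in-band energy fraction of each taper — and averaging the K
per-taper periodograms with equal weight.  Defaults (NW=4, K=7,
64-sample windows, 32-sample overlap, 512-point FFT at 250 Hz) turn a
320-sample epoch into 9 overlapping analysis windows.

Spectra are one-sided power densities (power per Hz): power at non-DC,
non-Nyquist bins is doubled, so band-integrated power matches the
two-sided convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows
from sklearn.base import BaseEstimator, TransformerMixin

from .epochs import EpochSet


@dataclass(frozen=True)
class MultitaperConfig:
    """Windowing parameters of the sliding multitaper estimate."""

    NW: float = 4.0
    K: int = 7
    nperseg: int = 64
    noverlap: int = 32
    nfft: int = 512
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.K > 2 * self.NW - 1:
            raise ValueError(
                f"K={self.K} exceeds the 2NW-1={2 * self.NW - 1:g} "
                "well-concentrated tapers"
            )
        if not self.noverlap < self.nperseg:
            raise ValueError("noverlap must be < nperseg")
        if self.nfft < self.nperseg:
            raise ValueError("nfft must be >= nperseg")
        if self.nfft & (self.nfft - 1):
            raise ValueError("nfft must be a power of 2")

    @property
    def step(self) -> int:
        return self.nperseg - self.noverlap

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.nperseg:
            raise ValueError(
                f"epoch of {n_samples} samples shorter than nperseg={self.nperseg}"
            )
        return (n_samples - self.nperseg) // self.step + 1


@dataclass(frozen=True)
class TaperBank:
    """K Slepian tapers with their concentration eigenvalues.

    Tapers are unit-energy, pairwise orthogonal, ordered by descending
    eigenvalue; each taper's first non-zero element is positive.
    """

    tapers: np.ndarray  # K x nperseg
    eigenvalues: np.ndarray  # K, descending in (0, 1)

    @property
    def K(self) -> int:
        return self.tapers.shape[0]


@dataclass(frozen=True)
class TimeFrequencyRepresentation:
    """Per-trial sliding-window PSD.

    ``psd`` is trials x channels x freq_bins x windows (power per Hz,
    one-sided); ``freqs`` the Hz grid with spacing fs/nfft;
    ``window_times`` the window centres in seconds relative to stimulus
    onset.
    """

    psd: np.ndarray
    freqs: np.ndarray
    window_times: np.ndarray
    config: MultitaperConfig = field(compare=False)

    @property
    def n_windows(self) -> int:
        return self.psd.shape[-1]


def compute_tapers(nperseg: int, NW: float, K: int) -> TaperBank:
    """Slepian taper bank for a window of ``nperseg`` samples.

    Raises if ``K`` exceeds the 2NW-1 well-concentrated sequences.
    """
    if K > 2 * NW - 1:
        raise ValueError(f"K={K} exceeds 2NW-1={2 * NW - 1:g}")
    tapers, ratios = windows.dpss(
        nperseg, NW, Kmax=K, return_ratios=True, norm=2
    )
    tapers = np.atleast_2d(tapers)
    # sign convention: first non-zero element of each taper positive
    for k in range(tapers.shape[0]):
        nz = np.flatnonzero(np.abs(tapers[k]) > 0)
        if nz.size and tapers[k, nz[0]] < 0:
            tapers[k] = -tapers[k]
    return TaperBank(tapers=tapers, eigenvalues=np.atleast_1d(ratios))


def _onesided_scale(nfft: int) -> np.ndarray:
    scale = np.full(nfft // 2 + 1, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    return scale


def per_taper_spectrum(
    x: np.ndarray, taper: np.ndarray, nfft: int, fs: float
) -> np.ndarray:
    """One-sided power density |DFT(x * taper)|^2 of a single window.

    With a unit-energy taper the spectrum integrates (sum x fs/nfft) to
    the mean power of ``x``.
    """
    x = np.asarray(x, dtype=float)
    taper = np.asarray(taper, dtype=float)
    if x.shape[-1] != taper.shape[-1]:
        raise ValueError(
            f"window length {x.shape[-1]} != taper length {taper.shape[-1]}"
        )
    spec = np.fft.rfft(x * taper, n=nfft, axis=-1)
    psd = (spec.real**2 + spec.imag**2) / fs
    return psd * _onesided_scale(nfft)


def multitaper_psd(
    x: np.ndarray, bank: TaperBank, nfft: int, fs: float
) -> np.ndarray:
    """Unweighted average of the K per-taper spectra of one window."""
    if bank.K == 0:
        raise ValueError("empty taper bank")
    acc = np.zeros(np.shape(x)[:-1] + (nfft // 2 + 1,))
    for k in range(bank.K):
        acc += per_taper_spectrum(x, bank.tapers[k], nfft, fs)
    return acc / bank.K


class MultitaperSpectrogram(TransformerMixin, BaseEstimator):
    """Sliding-window multitaper PSD as an sklearn-style transformer.

    ``transform`` maps a trials x channels x samples array to a
    trials x channels x freq_bins x windows PSD array; ``fit`` only
    builds the taper bank.  :func:`spectrogram` wraps this for
    :class:`~adrisk.epochs.EpochSet` inputs.
    """

    def __init__(self, NW: float = 4.0, K: int = 7, nperseg: int = 64,
                 noverlap: int = 32, nfft: int = 512, fs: float = 250.0,
                 batch_size: int = 64):
        self.NW = NW
        self.K = K
        self.nperseg = nperseg
        self.noverlap = noverlap
        self.nfft = nfft
        self.fs = fs
        self.batch_size = batch_size

    def _config(self) -> MultitaperConfig:
        return MultitaperConfig(
            NW=self.NW, K=self.K, nperseg=self.nperseg,
            noverlap=self.noverlap, nfft=self.nfft, fs=self.fs,
        )

    def fit(self, X=None, y=None) -> "MultitaperSpectrogram":
        cfg = self._config()
        self.config_ = cfg
        self.bank_ = compute_tapers(cfg.nperseg, cfg.NW, cfg.K)
        self.freqs_ = np.arange(cfg.nfft // 2 + 1) * cfg.fs / cfg.nfft
        # fold each taper into a real DFT matrix: a window's zero-padded
        # rFFT equals x @ (diag(taper) W), evaluated as one real GEMM per
        # taper with [Re | Im] stacked column-wise
        n_bins = cfg.nfft // 2 + 1
        W = np.exp(
            -2j
            * np.pi
            * np.outer(np.arange(cfg.nperseg), np.arange(n_bins))
            / cfg.nfft
        )
        self._dft_mats_ = [
            np.ascontiguousarray(
                np.concatenate(
                    [(t[:, None] * W).real, (t[:, None] * W).imag], axis=1
                )
            )
            for t in self.bank_.tapers
        ]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "bank_"):
            self.fit()
        cfg = self.config_
        X = np.asarray(X)
        squeeze = X.ndim == 2
        if squeeze:
            X = X[None]
        n_trials, n_ch, n_samp = X.shape
        n_win = cfg.n_windows(n_samp)
        starts = np.arange(n_win) * cfg.step
        scale = _onesided_scale(cfg.nfft)
        out = np.empty(
            (n_trials, n_ch, cfg.nfft // 2 + 1, n_win), dtype=np.float64
        )
        n_bins = cfg.nfft // 2 + 1
        for lo in range(0, n_trials, self.batch_size):
            hi = min(lo + self.batch_size, n_trials)
            # batch x channels x windows x nperseg view of the epochs
            seg = np.stack(
                [X[lo:hi, :, s:s + cfg.nperseg] for s in starts], axis=2
            ).astype(np.float64)
            rows = seg.reshape(-1, cfg.nperseg)
            acc = np.zeros((rows.shape[0], n_bins))
            for mat in self._dft_mats_:
                spec = rows @ mat  # [Re | Im] halves
                np.square(spec, out=spec)
                acc += spec[:, :n_bins]
                acc += spec[:, n_bins:]
            acc *= scale / (cfg.K * cfg.fs)
            out[lo:hi] = np.moveaxis(
                acc.reshape(seg.shape[:-1] + (n_bins,)), 2, 3
            )  # -> freq_bins x windows
        return out[0] if squeeze else out

    def window_times(self, n_samples: int, t0_offset_ms: float) -> np.ndarray:
        cfg = self._config()
        n_win = cfg.n_windows(n_samples)
        centers = np.arange(n_win) * cfg.step + cfg.nperseg / 2.0
        return t0_offset_ms / 1000.0 + centers / cfg.fs


def spectrogram(
    epochs: EpochSet, config: MultitaperConfig | None = None
) -> TimeFrequencyRepresentation:
    """Per-trial multitaper spectrogram of an epoch set."""
    config = config or MultitaperConfig(fs=epochs.fs)
    est = MultitaperSpectrogram(
        NW=config.NW, K=config.K, nperseg=config.nperseg,
        noverlap=config.noverlap, nfft=config.nfft, fs=config.fs,
    ).fit()
    psd = est.transform(epochs.data)
    return TimeFrequencyRepresentation(
        psd=psd,
        freqs=est.freqs_,
        window_times=est.window_times(epochs.n_samples, epochs.t0_offset),
        config=config,
    )
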