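"""Per-epoch EEG feature families and per-subject aggregation.

Four families are computed from each 8-s epoch over the 9-channel montage
(7 electrodes + 2 virtual bipolars), 286 features in total under the default
schemes:

* relative spectral power, 9 bands x 9 channels = 81 (``pow-<band>-<ch>``);
* band-averaged magnitude squared coherence, 5 bands x 5 electrode pairs = 25
  (``msc-<band>-<a>-<b>``);
* amplitude-modulation rate-of-change: normalized energy of each carrier
  band's Hilbert envelope within a modulation band, 14 combinations x 9
  channels = 126 (``am-<band>-<mband>-<ch>``);
* modulation-spectral patches: energy in rectangular regions of the
  (modulation frequency x carrier frequency) plane plus their ratios,
  (3 + 3) x 9 = 54 (``patch-<R|RoR>-<ch>``).

Per-epoch trajectories are collapsed to per-subject features with six
functionals (mean, std, cv, median, skew, kurt), 1716 per subject by default.

All families are self-normalized, so every feature is invariant to a positive
rescaling of the raw signal.  Values are returned alongside a boolean
validity mask; degenerate epochs (flat channel, zero total power) yield
``valid == False`` with a value of 0 rather than NaN.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from ._filters import bandpass
from .preprocess import EpochSet
from .schemes import BandScheme, PatchScheme

FUNCTIONALS = ("mean", "std", "cv", "median", "skew", "kurt")

#: Short-time analysis parameters for the modulation spectrogram
#: (256 ms Hamming frames, 32 ms hop at 125 Hz).
_STFT_NPERSEG = 32
_STFT_HOP = 4

_RATIO_FLOOR = 1e-12


def _as_frames(values: np.ndarray, valid: np.ndarray,
               names: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    return (pd.DataFrame(values, columns=names),
            pd.DataFrame(valid, columns=names))


def _subband(epochs: np.ndarray, fs: float, lo: float, hi: float,
             cache: dict | None) -> np.ndarray:
    """Band-filtered epochs, shared between families via ``cache``."""
    if cache is None:
        return bandpass(epochs, lo, hi, fs)
    key = (lo, hi)
    if key not in cache:
        cache[key] = bandpass(epochs, lo, hi, fs)
    return cache[key]


def spectral_power_features(epochs: np.ndarray, fs: float,
                            labels: tuple[str, ...], scheme: BandScheme,
                            _cache: dict | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative band power: subband power / full-band power, clipped to [0, 1].

    ``epochs`` is epoch x channel x sample, already band-limited to the
    analysis broadband (0.5-45 Hz), so the denominator is the plain epoch
    power.  A zero-power (flat) channel invalidates its features.
    """
    total = np.mean(epochs ** 2, axis=-1)  # (n_ep, n_ch)
    ok = total > 0
    denom = np.where(ok, total, 1.0)
    blocks, valid_blocks, names = [], [], []
    for band, (lo, hi) in scheme.power_bands.items():
        sub = np.mean(_subband(epochs, fs, lo, hi, _cache) ** 2, axis=-1)
        rel = np.clip(sub / denom, 0.0, 1.0)
        blocks.append(np.where(ok, rel, 0.0))
        valid_blocks.append(ok)
        names.extend(f"pow-{band}-{ch}" for ch in labels)
    values = np.concatenate([b.reshape(b.shape[0], -1) for b in blocks], axis=1)
    valid = np.concatenate([v.reshape(v.shape[0], -1) for v in valid_blocks], axis=1)
    return _as_frames(values, valid, names)


def coherence_features(epochs: np.ndarray, fs: float, labels: tuple[str, ...],
                       scheme: BandScheme) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band-averaged magnitude squared coherence for the configured pairs.

    Welch estimator with 1-s Hamming segments and 50% overlap inside each
    epoch; the MSC spectrum is averaged over the frequency bins falling in
    each band.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    nperseg = int(round(fs))
    blocks, names = [], []
    for a, b in scheme.coherence_pairs:
        for lab in (a, b):
            if lab not in index:
                raise KeyError(f"coherence pair {a}-{b}: channel {lab!r} missing")
        f, cxy = signal.coherence(epochs[:, index[a]], epochs[:, index[b]],
                                  fs=fs, window="hamming", nperseg=nperseg,
                                  noverlap=nperseg // 2, axis=-1)
        for band, (lo, hi) in scheme.coherence_bands.items():
            sel = (f >= lo) & (f <= hi)
            blocks.append(np.mean(cxy[..., sel], axis=-1))
            names.append(f"msc-{band}-{a}-{b}")
    values = np.clip(np.stack(blocks, axis=1), 0.0, 1.0)
    valid = np.isfinite(values)
    return _as_frames(np.where(valid, values, 0.0), valid, names)


def _envelope_spectra(epochs: np.ndarray, fs: float, lo: float, hi: float,
                      cache: dict | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram of the demeaned Hilbert envelope of a carrier band.

    Returns (frequencies, power) with power of shape epoch x channel x freq.
    The envelope DC (mean level) is removed before the FFT: the features
    quantify the *rate of change* of subband energy, not its mean.
    """
    sub = _subband(epochs, fs, lo, hi, cache)
    env = np.abs(signal.hilbert(sub, axis=-1))
    env = env - env.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(env, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(epochs.shape[-1], d=1.0 / fs)
    return freqs, spec


def amplitude_modulation_features(epochs: np.ndarray, fs: float,
                                  labels: tuple[str, ...], scheme: BandScheme,
                                  _cache: dict | None = None
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplitude-modulation rate-of-change features.

    Per carrier band: zero-phase band-pass, Hilbert envelope, envelope
    periodogram (DC removed), then energy integrated over each allowed
    modulation band and normalized by the carrier's total modulation-spectrum
    energy.  Values lie in [0, 1] and the values of one carrier over its
    allowed modulation bands sum to at most 1.
    """
    by_carrier: dict[str, list[str]] = {}
    for carrier, mband in scheme.am_pairs:
        by_carrier.setdefault(carrier, []).append(mband)
    cols: dict[str, np.ndarray] = {}
    valid_cols: dict[str, np.ndarray] = {}
    for carrier in by_carrier:
        lo, hi = scheme.power_bands[carrier]
        freqs, spec = _envelope_spectra(epochs, fs, lo, hi, _cache)
        total = spec[..., 1:].sum(axis=-1)  # exclude the (zeroed) DC bin
        ok = total > 0
        denom = np.where(ok, total, 1.0)
        for mband in by_carrier[carrier]:
            mlo, mhi = scheme.mod_bands[mband]
            # half-open [lo, hi): a boundary FFT bin belongs to one band only,
            # keeping fractions over a carrier's modulation bands sub-additive
            sel = (freqs >= mlo) & (freqs < mhi)
            frac = spec[..., sel].sum(axis=-1) / denom
            for c, ch in enumerate(labels):
                cols[f"am-{carrier}-{mband}-{ch}"] = np.where(
                    ok[:, c], np.clip(frac[:, c], 0.0, 1.0), 0.0)
                valid_cols[f"am-{carrier}-{mband}-{ch}"] = ok[:, c]
    # emit in am_pairs order, channel-minor
    names = [f"am-{carrier}-{mband}-{ch}"
             for carrier, mband in scheme.am_pairs for ch in labels]
    values = np.stack([cols[n] for n in names], axis=1)
    valid = np.stack([valid_cols[n] for n in names], axis=1)
    return _as_frames(values, valid, names)


def modulation_spectrogram(epochs: np.ndarray, fs: float
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense modulation spectrogram on a (carrier freq x modulation freq) grid.

    A short-time Fourier magnitude spectrogram is computed per channel, the
    temporal mean of each carrier bin is removed, and a second FFT along the
    frame axis yields modulation-domain power.

    Returns (carrier_freqs, mod_freqs, power) with power shaped
    epoch x channel x carrier x modulation.
    """
    f, _, Z = signal.stft(epochs, fs=fs, window="hamming",
                          nperseg=_STFT_NPERSEG,
                          noverlap=_STFT_NPERSEG - _STFT_HOP,
                          boundary=None, padded=False, axis=-1)
    mag = np.abs(Z)
    mag = mag - mag.mean(axis=-1, keepdims=True)
    power = np.abs(np.fft.rfft(mag, axis=-1)) ** 2
    frame_rate = fs / _STFT_HOP
    mod_freqs = np.fft.rfftfreq(mag.shape[-1], d=1.0 / frame_rate)
    return f, mod_freqs, power


def modulation_patch_features(epochs: np.ndarray, fs: float,
                              labels: tuple[str, ...], scheme: PatchScheme
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized modulation energy in rectangular patches, plus their ratios.

    Patch energy is the modulation-spectrogram power integrated over the
    rectangle, divided by total (DC-removed) modulation power.  Ratios divide
    two patch energies with the denominator floored at 1e-12 of the total.
    A rectangle that clips to zero grid cells is a configuration error.
    """
    cf, mf, power = modulation_spectrogram(epochs, fs)
    total = power[..., 1:].sum(axis=(-2, -1))  # (n_ep, n_ch); skip mod-DC
    ok = total > 0
    denom = np.where(ok, total, 1.0)
    patch_vals: dict[str, np.ndarray] = {}
    for name, (mlo, mhi, clo, chi) in scheme.patches.items():
        csel = (cf >= clo) & (cf <= chi)
        msel = (mf >= mlo) & (mf <= mhi) & (mf > 0)
        if not csel.any() or not msel.any():
            raise ValueError(
                f"patch {name!r} ({mlo}-{mhi} Hz mod x {clo}-{chi} Hz carrier) "
                f"contains no grid cells at fs={fs}")
        patch_vals[name] = power[:, :, csel][..., msel].sum(axis=(-2, -1)) / denom
    cols, valid_cols, names = [], [], []
    for name in scheme.patches:
        cols.append(patch_vals[name])
        valid_cols.append(ok)
        names.append(name)
    for num, den in scheme.ratios:
        ratio = patch_vals[num] / np.maximum(patch_vals[den], _RATIO_FLOOR)
        cols.append(ratio)
        valid_cols.append(ok)
        names.append(f"{num}o{den}")
    full_names = [f"patch-{n}-{ch}" for n in names for ch in labels]
    values = np.concatenate([np.where(ok, c, 0.0) for c in cols], axis=1)
    valid = np.concatenate(valid_cols, axis=1)
    return _as_frames(values, valid, full_names)


def epoch_features(epoch_set: EpochSet,
                   band_scheme: BandScheme | None = None,
                   patch_scheme: PatchScheme | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All four families for every epoch: epochs x 286 under default schemes.

    Column order is family order (power, coherence, AM, patches); within a
    family, band/pair/patch-major and channel-minor.
    """
    band_scheme = band_scheme or BandScheme()
    patch_scheme = patch_scheme or PatchScheme()
    ep, fs, labels = epoch_set.epochs, epoch_set.fs, epoch_set.labels
    cache: dict = {}
    parts = [
        spectral_power_features(ep, fs, labels, band_scheme, _cache=cache),
        coherence_features(ep, fs, labels, band_scheme),
        amplitude_modulation_features(ep, fs, labels, band_scheme, _cache=cache),
        modulation_patch_features(ep, fs, labels, patch_scheme),
    ]
    values = pd.concat([p[0] for p in parts], axis=1)
    valid = pd.concat([p[1] for p in parts], axis=1)
    return values, valid


def epoch_feature_vector(epoch: np.ndarray, fs: float, labels: tuple[str, ...],
                         band_scheme: BandScheme | None = None,
                         patch_scheme: PatchScheme | None = None) -> pd.Series:
    """Feature vector of a single channel x sample epoch (NaN where invalid)."""
    eset = EpochSet(epoch[None, ...], fs, labels,
                    window_s=epoch.shape[-1] / fs, shift_s=1.0)
    values, valid = epoch_features(eset, band_scheme, patch_scheme)
    out = values.iloc[0].copy()
    out[~valid.iloc[0]] = np.nan
    return out


def aggregate_functionals(values: pd.DataFrame, valid: pd.DataFrame | None = None,
                          min_epochs: int = 3) -> pd.Series:
    """Collapse per-epoch feature trajectories with six summary statistics.

    Conventions (fixed): std is the n-1 sample standard deviation; cv is
    std/mean, defined as 0 when |mean| < 1e-12; skewness and kurtosis are
    moment-based (Fisher/excess kurtosis, no bias correction) and defined as 0
    for a zero-variance series.  Epochs flagged invalid for a feature are
    excluded from that feature's statistics; a feature with fewer than
    ``min_epochs`` valid epochs is reported missing (NaN for all six
    functionals).
    """
    x = values.to_numpy(dtype=float)
    mask = valid.to_numpy(dtype=bool) if valid is not None else np.isfinite(x)
    x = np.where(mask, x, np.nan)
    n = mask.sum(axis=0).astype(float)
    enough = n >= min_epochs
    x[:, n == 0] = 0.0  # placeholder; masked out via `enough` below

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=0)
        std = np.nanstd(x, axis=0, ddof=1)
        median = np.nanmedian(x, axis=0)
        cv = np.where(np.abs(mean) < 1e-12, 0.0, std / mean)
        centered = x - mean
        m2 = np.nanmean(centered ** 2, axis=0)
        m3 = np.nanmean(centered ** 3, axis=0)
        m4 = np.nanmean(centered ** 4, axis=0)
        nonzero = m2 > 0
        skew = np.where(nonzero, m3 / np.where(nonzero, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(nonzero, m4 / np.where(nonzero, m2, 1.0) ** 2 - 3.0, 0.0)

    stats = {"mean": mean, "std": std, "cv": cv,
             "median": median, "skew": skew, "kurt": kurt}
    out: dict[str, float] = {}
    for func in FUNCTIONALS:
        vals = np.where(enough, stats[func], np.nan)
        for j, name in enumerate(values.columns):
            out[f"{func}-{name}"] = vals[j]
    return pd.Series(out)
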