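"""Spectral feature extraction for EEG affect recognition.

Turns multichannel EEG epochs into band-power feature vectors: the power
spectral density of every channel is estimated with Welch's method, averaged
within five canonical frequency bands (theta, slow alpha, alpha, beta,
gamma), and complemented with hemispheric asymmetry features -- the
right-minus-left difference of band power for every symmetric electrode
pair of the montage.

The resulting feature vector has ``n_channels * 5 + n_pairs * 5`` entries:
230 for a 32-channel cap with 14 symmetric pairs, 105 for a 14-channel cap
with 7 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "BandSet",
    "Montage",
    "RecordingEpoch",
    "FeatureTable",
    "DEFAULT_BANDS",
    "get_montage",
    "welch_psd",
    "band_power",
    "asymmetry_features",
    "extract_features",
    "feature_names_for",
]


@dataclass(frozen=True)
class BandSet:
    """Named frequency intervals in Hz, half-open ``[low, high)``.

    The slow-alpha and alpha bands deliberately overlap on 8-10 Hz; the
    gamma band is open-ended in the literature (">30 Hz") and its upper
    edge is configurable (default 45 Hz, below mains interference and
    below the Nyquist frequency of a 128 Hz recording).
    """

    bands: tuple[tuple[str, float, float], ...] = (
        ("theta", 4.0, 8.0),
        ("slow_alpha", 8.0, 10.0),
        ("alpha", 8.0, 12.0),
        ("beta", 12.0, 30.0),
        ("gamma", 30.0, 45.0),
    )

    def __post_init__(self) -> None:
        for name, low, high in self.bands:
            if not low < high:
                raise ValueError(f"band {name!r}: lower edge {low} must be < upper edge {high}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def max_edge(self) -> float:
        return max(high for _, _, high in self.bands)

    def with_gamma_upper(self, upper: float) -> "BandSet":
        """Return a copy with the gamma upper edge replaced."""
        new = tuple(
            (n, lo, upper if n == "gamma" else hi) for n, lo, hi in self.bands
        )
        return BandSet(new)


DEFAULT_BANDS = BandSet()


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout plus its left/right symmetric pairs.

    ``pairs`` are (right, left) channel-name tuples; midline electrodes
    (Fz, Cz, Pz, Oz) belong to no pair.
    """

    name: str
    channels: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        chan_set = set(self.channels)
        if len(chan_set) != len(self.channels):
            raise ValueError("duplicate channel names in montage")
        seen: set[str] = set()
        for right, left in self.pairs:
            for ch in (right, left):
                if ch not in chan_set:
                    raise ValueError(f"pair channel {ch!r} not in montage channels")
                if ch in seen:
                    raise ValueError(f"channel {ch!r} appears in more than one pair")
                seen.add(ch)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage {self.name!r}") from None


# Channel order of the Biosemi ActiveTwo 32-electrode cap as distributed
# with the public affect databases; 14 lateral pairs, midline excluded.
_BIOSEMI32 = Montage(
    name="biosemi32",
    channels=(
        "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
        "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
        "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
        "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
    ),
    pairs=(
        ("Fp2", "Fp1"), ("AF4", "AF3"), ("F8", "F7"), ("F4", "F3"),
        ("FC6", "FC5"), ("FC2", "FC1"), ("T8", "T7"), ("C4", "C3"),
        ("CP6", "CP5"), ("CP2", "CP1"), ("P8", "P7"), ("P4", "P3"),
        ("PO4", "PO3"), ("O2", "O1"),
    ),
)

# Emotiv EPOC 14-electrode headset; 7 lateral pairs.
_EPOC14 = Montage(
    name="epoc14",
    channels=(
        "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
        "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
    ),
    pairs=(
        ("AF4", "AF3"), ("F8", "F7"), ("F4", "F3"), ("FC6", "FC5"),
        ("T8", "T7"), ("P8", "P7"), ("O2", "O1"),
    ),
)

_BUILTIN_MONTAGES = {"biosemi32": _BIOSEMI32, "epoc14": _EPOC14}


def get_montage(name: str) -> Montage:
    """Return a built-in montage by name (``"biosemi32"`` or ``"epoc14"``)."""
    try:
        return _BUILTIN_MONTAGES[name]
    except KeyError:
        raise KeyError(
            f"unknown montage {name!r}; built-ins: {sorted(_BUILTIN_MONTAGES)}"
        ) from None


@dataclass
class RecordingEpoch:
    """One trial's multichannel signal (channels x samples, microvolts)."""

    signal: np.ndarray
    fs: float
    subject_id: str
    trial_id: str
    valence: Optional[int] = None
    arousal: Optional[int] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class FeatureTable:
    """Trials x features matrix with per-row subject IDs and binary labels.

    ``valence`` / ``arousal`` are float arrays with NaN where the label is
    absent; :meth:`labels` returns the requested dimension as ints and
    raises when any row lacks it.
    """

    values: np.ndarray
    feature_names: list[str]
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    valence: np.ndarray
    arousal: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        n = self.values.shape[0]
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=object)
        self.valence = np.asarray(self.valence, dtype=float)
        self.arousal = np.asarray(self.arousal, dtype=float)
        for arr_name in ("subject_ids", "trial_ids", "valence", "arousal"):
            if getattr(self, arr_name).shape != (n,):
                raise ValueError(f"{arr_name} must have one entry per trial row")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match the feature axis")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def subjects(self) -> list:
        """Unique subject IDs in first-appearance order."""
        seen: dict = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def labels(self, dim: str) -> np.ndarray:
        if dim not in ("valence", "arousal"):
            raise ValueError(f"label dimension must be 'valence' or 'arousal', got {dim!r}")
        lab = getattr(self, dim)
        if np.isnan(lab).any():
            raise ValueError(f"{dim} labels missing for some rows")
        return lab.astype(int)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return FeatureTable(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            subject_ids=self.subject_ids[idx],
            trial_ids=self.trial_ids[idx],
            valence=self.valence[idx],
            arousal=self.arousal[idx],
        )


def welch_psd(
    epoch: RecordingEpoch,
    window_len: int = 128,
    overlap_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel Welch power spectral density.

    Averaged modified periodograms with a Hamming taper of ``window_len``
    samples, ``overlap_frac`` overlap and per-segment mean removal;
    one-sided density normalisation, so that ``sum(psd) * df`` recovers the
    variance of a zero-mean stationary signal (Parseval).

    Returns
    -------
    freqs : ndarray, shape (n_freqs,)
        Frequency grid from 0 to ``fs / 2``.
    psd : ndarray, shape (n_channels, n_freqs)
        Nonnegative density, in signal-units^2 per Hz.
    """
    if epoch.n_samples < window_len:
        raise ValueError(
            f"epoch has {epoch.n_samples} samples but Welch's method needs at "
            f"least window_len={window_len}"
        )
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    freqs, psd = _signal.welch(
        epoch.signal,
        fs=epoch.fs,
        window="hamming",
        nperseg=window_len,
        noverlap=int(round(window_len * overlap_frac)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: BandSet = DEFAULT_BANDS,
) -> np.ndarray:
    """Mean PSD within each band, per channel.

    Entry ``(c, b)`` is the mean of channel ``c``'s PSD bins whose frequency
    falls in the half-open interval ``[low_b, high_b)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.atleast_2d(np.asarray(psd, dtype=float))
    out = np.empty((psd.shape[0], bands.n_bands))
    df = freqs[1] - freqs[0] if len(freqs) > 1 else np.nan
    for b, (name, low, high) in enumerate(bands.bands):
        mask = (freqs >= low) & (freqs < high)
        if not mask.any():
            raise ValueError(
                f"band {name!r} [{low}, {high}) Hz contains no frequency bins "
                f"(grid resolution {df:g} Hz, max frequency {freqs[-1]:g} Hz)"
            )
        out[:, b] = psd[:, mask].mean(axis=1)
    return out


def asymmetry_features(bp: np.ndarray, montage: Montage) -> np.ndarray:
    """Right-minus-left band-power difference for every symmetric pair.

    ``bp`` rows must align with ``montage.channels``; returns a
    (n_pairs x n_bands) matrix.
    """
    bp = np.asarray(bp, dtype=float)
    if bp.shape[0] != montage.n_channels:
        raise ValueError(
            f"band-power matrix has {bp.shape[0]} rows but montage "
            f"{montage.name!r} has {montage.n_channels} channels"
        )
    out = np.empty((montage.n_pairs, bp.shape[1]))
    for p, (right, left) in enumerate(montage.pairs):
        out[p] = bp[montage.channel_index(right)] - bp[montage.channel_index(left)]
    return out


def feature_names_for(montage: Montage, bands: BandSet = DEFAULT_BANDS) -> list[str]:
    """Deterministic column naming: channel-band entries, then pair-band."""
    names = [f"{ch}_{band}" for ch in montage.channels for band in bands.names]
    names += [
        f"{right}-{left}_{band}"
        for right, left in montage.pairs
        for band in bands.names
    ]
    return names


def extract_features(
    epochs: Sequence[RecordingEpoch],
    montage: Montage,
    bands: BandSet = DEFAULT_BANDS,
    window_len: int = 128,
    overlap_frac: float = 0.5,
    log_power: bool = False,
) -> FeatureTable:
    """Extract band-power + asymmetry features, one row per epoch.

    Column count is ``n_channels * n_bands + n_pairs * n_bands`` (230 for
    the 32-channel montage, 105 for the 14-channel one). With
    ``log_power=True`` channel powers are log10-transformed and asymmetry
    becomes a log-power ratio; default is the linear scale.
    """
    names = feature_names_for(montage, bands)
    if len(epochs) == 0:
        empty = np.empty((0,))
        return FeatureTable(
            values=np.empty((0, len(names))),
            feature_names=names,
            subject_ids=empty.astype(object),
            trial_ids=empty.astype(object),
            valence=empty,
            arousal=empty,
        )

    fs0 = epochs[0].fs
    rows = []
    for ep in epochs:
        if ep.n_channels != montage.n_channels:
            raise ValueError(
                f"epoch {ep.trial_id!r} has {ep.n_channels} channels; montage "
                f"{montage.name!r} expects {montage.n_channels}"
            )
        if ep.fs != fs0:
            raise ValueError("all epochs must share the same sampling rate")
        if ep.fs <= 2 * bands.max_edge:
            raise ValueError(
                f"sampling rate {ep.fs} Hz must exceed twice the highest band "
                f"edge ({bands.max_edge} Hz)"
            )
        freqs, psd = welch_psd(ep, window_len=window_len, overlap_frac=overlap_frac)
        bp = band_power(freqs, psd, bands)
        if log_power:
            bp = np.log10(np.maximum(bp, np.finfo(float).tiny))
        asym = asymmetry_features(bp, montage)
        rows.append(np.concatenate([bp.ravel(), asym.ravel()]))

    to_nan = lambda v: np.nan if v is None else float(v)
    return FeatureTable(
        values=np.vstack(rows),
        feature_names=names,
        subject_ids=np.array([ep.subject_id for ep in epochs], dtype=object),
        trial_ids=np.array([ep.trial_id for ep in epochs], dtype=object),
        valence=np.array([to_nan(ep.valence) for ep in epochs]),
        arousal=np.array([to_nan(ep.arousal) for ep in epochs]),
    )
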