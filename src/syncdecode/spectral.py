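"""Time-frequency decomposition and power estimation.

Epoched sub-ROI source time series are decomposed with complex Morlet
wavelets (7 cycles each) into an epoch x frequency x time tensor of complex
coefficients, the raw material for both the imaginary-coherence connectivity
features and the temporally resolved power analyses.  Temporally unresolved
power spectra use the multitaper estimator (mne-python's
``psd_array_multitaper``).

Frequency handling is band-oriented: theta 3-7, alpha 8-12, beta 13-30,
low gamma 31-60 and high gamma 61-120 Hz, with a log-spaced set of analysis
frequencies inside each band (5/5/18/20/21 bins by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from ._seeds import child_rng, derive_seed

__all__ = [
    "DEFAULT_BANDS",
    "DEFAULT_BINS_PER_BAND",
    "FrequencyGrid",
    "SpectralTensor",
    "morlet_wavelet",
    "morlet_tfr",
    "multitaper_power",
    "power_subsamples",
    "PowerFeatures",
    "power_features",
    "band_power_timecourse",
    "relative_power_change",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "low_gamma": (31.0, 60.0),
    "high_gamma": (61.0, 120.0),
}

# log-spaced analysis bins inside each band
DEFAULT_BINS_PER_BAND: dict[str, int] = {
    "theta": 5,
    "alpha": 5,
    "beta": 18,
    "low_gamma": 20,
    "high_gamma": 21,
}


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered analysis frequencies plus named, non-overlapping bands."""

    frequencies: np.ndarray
    bands: dict[str, tuple[float, float]]

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        ivs = sorted(self.bands.values())
        for (_lo1, hi1), (lo2, _hi2) in zip(ivs, ivs[1:]):
            if lo2 <= hi1:
                raise ValueError("bands must not overlap")
        if f.ndim != 1 or f.size == 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be a strictly increasing 1-D array")
        for name in self.bands:
            if self.band_indices(name).size == 0:
                raise ValueError(f"band {name!r} contains no grid frequency")

    @classmethod
    def from_bands(
        cls,
        bands: dict[str, tuple[float, float]] | None = None,
        bins_per_band: dict[str, int] | int | None = None,
    ) -> "FrequencyGrid":
        """Build a grid with log-spaced bins inside each band."""
        bands = dict(bands or DEFAULT_BANDS)
        if bins_per_band is None:
            counts = {k: DEFAULT_BINS_PER_BAND.get(k, 5) for k in bands}
        elif isinstance(bins_per_band, int):
            counts = {k: bins_per_band for k in bands}
        else:
            counts = {k: bins_per_band[k] for k in bands}
        freqs = []
        for name, (lo, hi) in sorted(bands.items(), key=lambda kv: kv[1][0]):
            m = counts[name]
            if m == 1:
                freqs.append([np.sqrt(lo * hi)])
            else:
                freqs.append(np.geomspace(lo, hi, m))
        return cls(frequencies=np.concatenate(freqs), bands=bands)

    @classmethod
    def default(cls) -> "FrequencyGrid":
        return cls.from_bands()

    def band_indices(self, band: str) -> np.ndarray:
        lo, hi = self.bands[band]
        return np.flatnonzero((self.frequencies >= lo) & (self.frequencies <= hi))

    def band_center(self, band: str) -> float:
        lo, hi = self.bands[band]
        return 0.5 * (lo + hi)

    @property
    def band_names(self) -> list[str]:
        return sorted(self.bands, key=lambda k: self.bands[k][0])


@dataclass
class SpectralTensor:
    """Complex Morlet coefficients, epoch x frequency x time.

    ``valid`` marks samples outside the edge region contaminated by the
    wavelet's support; masked samples must never enter window averages.
    """

    data: np.ndarray  # (K, F, T) complex
    grid: FrequencyGrid
    times: np.ndarray  # (T,) seconds
    valid: np.ndarray  # (F, T) bool

    def window_mask(self, tmin: float, tmax: float) -> np.ndarray:
        """Boolean time mask for the half-open window [tmin, tmax)."""
        return (self.times >= tmin) & (self.times < tmax)


def morlet_wavelet(freq: float, sfreq: float, n_cycles: float = 7.0) -> np.ndarray:
    """Unit-L2-norm complex Morlet wavelet spanning ``n_cycles`` cycles."""
    if freq <= 0:
        raise ValueError("wavelet frequency must be positive")
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(round(0.5 * n_cycles / freq * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2.0j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return w / np.linalg.norm(w)


def morlet_tfr(
    epochs: np.ndarray,
    sfreq: float,
    grid: FrequencyGrid,
    n_cycles: float = 7.0,
    tmin: float = 0.0,
) -> SpectralTensor:
    """Morlet time-frequency transform of a (K, T) epoch array.

    The transform is linear in the input.  Zero-padding handles the epoch
    edges; samples within half the wavelet support of either edge are marked
    invalid in the mask (a frequency whose wavelet outgrows the epoch is
    masked entirely).
    """
    epochs = np.asarray(epochs)
    if epochs.ndim == 1:
        epochs = epochs[None, :]
    if not np.all(np.isfinite(epochs)):
        raise ValueError("epochs contain non-finite samples")
    K, T = epochs.shape
    F = grid.frequencies.size
    out = np.empty((K, F, T), dtype=np.complex128)
    valid = np.zeros((F, T), dtype=bool)
    for fi, f in enumerate(grid.frequencies):
        w = morlet_wavelet(f, sfreq, n_cycles)
        half = w.size // 2
        out[:, fi, :] = fftconvolve(epochs, np.conj(w[::-1])[None, :], mode="same", axes=1)
        if 2 * half < T:
            valid[fi, half : T - half] = True
    times = tmin + np.arange(T) / sfreq
    return SpectralTensor(data=out, grid=grid, times=times, valid=valid)


def multitaper_power(
    epochs: np.ndarray,
    sfreq: float,
    fmin: float = 3.0,
    fmax: float = 120.0,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch multitaper power spectra (no temporal resolution).

    Thin wrapper over :func:`mne.time_frequency.psd_array_multitaper`;
    returns ``(psd, freqs)`` with ``psd`` of shape ``epochs.shape[:-1] +
    (n_freqs,)``.
    """
    from mne.time_frequency import psd_array_multitaper

    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if fmax > sfreq / 2.0:
        raise ValueError(f"fmax {fmax} Hz exceeds Nyquist ({sfreq / 2.0} Hz)")
    psd, freqs = psd_array_multitaper(
        epochs, sfreq, fmin=fmin, fmax=fmax, bandwidth=bandwidth,
        normalization="full", verbose="error",
    )
    return psd, freqs


def power_subsamples(
    spectra: np.ndarray, n_groups: int = 4, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-epoch spectra within ``n_groups`` seeded disjoint groups.

    Epochs are randomly partitioned into equal-sized groups (remainder epochs
    dropped); returns ``(group_means, assignment)`` where ``group_means`` has
    shape ``(n_groups,) + spectra.shape[1:]`` and ``assignment[k]`` is the
    group of epoch ``k`` (-1 for dropped epochs).
    """
    spectra = np.asarray(spectra)
    K = spectra.shape[0]
    if K < n_groups:
        raise ValueError(f"need at least {n_groups} epochs, got {K}")
    per = K // n_groups
    rng = child_rng(seed, "power-subsamples")
    order = rng.permutation(K)
    assignment = np.full(K, -1, dtype=int)
    means = np.empty((n_groups,) + spectra.shape[1:], dtype=float)
    for g in range(n_groups):
        members = order[g * per : (g + 1) * per]
        assignment[members] = g
        means[g] = spectra[members].mean(axis=0)
    return means, assignment


@dataclass
class PowerFeatures:
    """Per subject/condition/subsample power-pattern vectors for one ROI.

    ``values`` has shape (n_subjects, n_conditions, n_subsamples, N, F):
    sub-ROI x frequency-bin power averaged within each of the seeded epoch
    subsamples.  ``band_matrix`` restricts to one band and flattens to the
    (rows, N*M) design used by the RBF-SVM decoder.
    """

    values: np.ndarray
    freqs: np.ndarray
    roi: str
    grid: FrequencyGrid
    subjects: list = field(default_factory=list)

    def band_matrix(self, band: str) -> np.ndarray:
        lo, hi = self.grid.bands[band]
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        ns, nc, nq, N, _ = self.values.shape
        return self.values[..., sel].reshape(ns, nc, nq, -1)


def power_features(
    cohort,
    roi: str,
    grid: FrequencyGrid | None = None,
    n_groups: int = 4,
    seed: int = 0,
    time_window: tuple[float, float] | None = None,
    impulse: bool | None = None,
    fmin: float = 3.0,
    fmax: float = 120.0,
    bandwidth: float | None = None,
) -> PowerFeatures:
    """Multitaper power-pattern features for one ROI of a cohort.

    Per subject and condition, epochs are filtered by the ``impulse`` flag
    (None keeps all), equalized to the subject's minimum count across
    conditions, optionally cropped to ``time_window`` (half-open, seconds),
    and their single-epoch multitaper spectra averaged within ``n_groups``
    seeded subsamples.  Values are nonnegative.
    """
    grid = grid or FrequencyGrid.default()
    sub_idx = cohort.layout.subroi_indices(roi)
    times = cohort.times
    if time_window is not None:
        tsel = (times >= time_window[0]) & (times < time_window[1])
        if not tsel.any():
            raise ValueError("time_window outside the epoch")
    else:
        tsel = slice(None)

    subjects = cohort.subjects
    per_subject = {}
    for s in subjects:
        picks = {}
        for c in cohort.conditions:
            arr = cohort.epochs[(s, c)]
            keep = np.arange(arr.shape[0])
            if impulse is not None:
                flags = cohort.impulse.get((s, c))
                if flags is None:
                    raise ValueError("cohort has no impulse flags")
                keep = np.flatnonzero(flags == impulse)
            picks[c] = keep
        kmin = min(v.size for v in picks.values())
        if kmin < n_groups:
            raise ValueError(
                f"subject {s}: only {kmin} epochs after filtering, need >= {n_groups}"
            )
        for c in cohort.conditions:
            keep = picks[c]
            if keep.size > kmin:
                rng = child_rng(seed, "power-equalize", s, c)
                keep = np.sort(rng.choice(keep, size=kmin, replace=False))
            per_subject[(s, c)] = keep

    first = True
    out = None
    freqs = None
    for si, s in enumerate(subjects):
        for c in cohort.conditions:
            keep = per_subject[(s, c)]
            arr = cohort.epochs[(s, c)][keep][:, sub_idx, :][..., tsel]
            K, N, T = arr.shape
            psd, freqs = multitaper_power(
                arr.reshape(K * N, T), cohort.sample_rate, fmin=fmin, fmax=fmax,
                bandwidth=bandwidth,
            )
            psd = psd.reshape(K, N, -1)
            groups, _ = power_subsamples(psd, n_groups=n_groups,
                                         seed=derive_seed(seed, "power-groups", s, c))
            if first:
                out = np.empty(
                    (len(subjects), len(cohort.conditions), n_groups, N, freqs.size)
                )
                first = False
            out[si, c] = groups
    return PowerFeatures(values=out, freqs=freqs, roi=roi, grid=grid, subjects=subjects)


def band_power_timecourse(tensor: SpectralTensor) -> np.ndarray:
    """Band-averaged power |S|^2 over time, NaN where the mask is invalid.

    Returns an array (K, n_bands, T); invalid time samples are NaN so that
    any window average that accidentally includes them is poisoned.
    """
    power = np.abs(tensor.data) ** 2
    bands = tensor.grid.band_names
    K, _, T = power.shape
    out = np.full((K, len(bands), T), np.nan)
    for bi, band in enumerate(bands):
        idx = tensor.grid.band_indices(band)
        p = power[:, idx, :]
        v = tensor.valid[idx, :]
        # a time sample is valid for the band if every member bin is valid
        col_ok = v.all(axis=0)
        out[:, bi, col_ok] = p[:, :, col_ok].mean(axis=1)
    return out


def relative_power_change(
    timecourse: np.ndarray,
    times: np.ndarray,
    baseline: tuple[float, float] = (-0.4, -0.2),
    analysis: tuple[float, float] = (0.0, 2.0),
) -> np.ndarray:
    """Relative power change (analysis - baseline) / baseline.

    ``timecourse`` has time on the last axis; both windows are half-open
    [tmin, tmax) on ``times``.  NaN samples (masked edges) are excluded from
    the window means; a window with no valid sample or a non-positive
    baseline raises.
    """
    times = np.asarray(times)
    bmask = (times >= baseline[0]) & (times < baseline[1])
    amask = (times >= analysis[0]) & (times < analysis[1])
    if not bmask.any() or not amask.any():
        raise ValueError("baseline/analysis window falls outside the epoch")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        base = np.nanmean(np.asarray(timecourse)[..., bmask], axis=-1)
        post = np.nanmean(np.asarray(timecourse)[..., amask], axis=-1)
    if np.any(~np.isfinite(base)) or np.any(base <= 0):
        raise ValueError("baseline power must be positive and finite")
    return (post - base) / base
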