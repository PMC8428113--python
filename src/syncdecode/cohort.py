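"""Synthetic multi-subject cohorts of cortical sub-ROI source time series.

The generator emulates the data layout of a source-localized MEG
working-memory experiment: ~17-19 subjects, 6 stimulus classes ("ripple
velocities"), per subject and class tens of epochs of sub-ROI time series at
500 Hz, with regions of interest split into sub-ROIs.

Each sub-ROI signal is a sum of

* 1/f-like background noise (power slope -1), independent per sub-ROI,
* stationary band-limited oscillatory components with power equal across
  conditions, and
* optional *planted couplings*: a seed and a target sub-ROI share a common
  band-limited driver, with the target copy phase-lagged by a
  condition-specific angle whose per-epoch jitter is von Mises distributed
  with concentration kappa.  These couplings carry the condition information
  in the phase-synchronization (imaginary coherence) patterns while leaving
  power spectra condition-blind.

Impulse trials (50 % of maintenance epochs) multiply selected band
components by a condition-specific power gain after the impulse latency,
emulating "activity-silent" content read-out by a task-irrelevant probe.
Per-subject sign flips emulate the surface-normal sign ambiguity of source
orientations; behavior (proportion correct) is linked to each subject's
coupling fidelity.  All randomness derives from one master seed via the
documented stream-splitting scheme in :mod:`syncdecode._seeds`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd

from ._seeds import child_rng
from .spectral import DEFAULT_BANDS

__all__ = [
    "RoiLayout",
    "CouplingSpec",
    "GroundTruth",
    "CohortDataset",
    "simulate_cohort",
    "simulate_behavior",
    "make_impulse_gains",
    "align_signs",
    "save_cohort",
    "load_cohort",
]

N_CONDITIONS = 6


@dataclass(frozen=True)
class RoiLayout:
    """Abstract ROI layout: (name, hemisphere, n sub-ROIs) triples.

    Global sub-ROI indices are assigned contiguously in listing order; the
    index map is a bijection onto 0..N_total-1 by construction.
    """

    rois: tuple  # of (name, hemisphere, n_subrois)
    seed_rois: tuple = ("STC-rh",)

    def __post_init__(self):
        names = [name for name, _h, _n in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")
        for name, _h, n in self.rois:
            if n < 1:
                raise ValueError(f"ROI {name!r} must have >= 1 sub-ROIs")
        for s in self.seed_rois:
            if s not in names:
                raise ValueError(f"seed ROI {s!r} not in layout")

    @property
    def roi_names(self) -> list[str]:
        return [name for name, _h, _n in self.rois]

    @property
    def n_subrois(self) -> int:
        return sum(n for _name, _h, n in self.rois)

    def roi_slice(self, roi: str) -> slice:
        start = 0
        for name, _h, n in self.rois:
            if name == roi:
                return slice(start, start + n)
            start += n
        raise KeyError(roi)

    def subroi_indices(self, roi: str) -> np.ndarray:
        s = self.roi_slice(roi)
        return np.arange(s.start, s.stop)

    def target_rois(self, seed_roi: str | None = None) -> list[str]:
        seeds = set(self.seed_rois)
        return [name for name in self.roi_names if name not in seeds]

    @classmethod
    def reduced(cls, n_sub_seed: int = 2, n_sub_target: int = 2, n_targets: int = 2) -> "RoiLayout":
        """Small layout for calibration studies: one seed ROI + a few targets."""
        rois = [("STC-rh", "rh", n_sub_seed)]
        target_names = ["IFG-rh", "SM-rh", "CMF-rh", "PC-rh", "LOF-rh", "RMF-rh"]
        for name in target_names[:n_targets]:
            rois.append((name, "rh", n_sub_target))
        return cls(rois=tuple(rois), seed_rois=("STC-rh",))

    @classmethod
    def fullscale(cls) -> "RoiLayout":
        """Full-scale layout: two STC seeds (12 left / 13 right sub-ROIs) plus 6 targets per
        hemisphere with 9 sub-ROIs each (the 13 x 9 pairing of the worked
        examples)."""
        rois = [("STC-lh", "lh", 12), ("STC-rh", "rh", 13)]
        for hemi in ("lh", "rh"):
            for name in ("IFG", "CMF", "LOF", "RMF", "PC", "SM"):
                rois.append((f"{name}-{hemi}", hemi, 9))
        return cls(rois=tuple(rois), seed_rois=("STC-lh", "STC-rh"))


@dataclass(frozen=True)
class CouplingSpec:
    """A planted seed->target phase coupling in one frequency band.

    ``phase_lags[c]`` is the mean lag (radians, in (-pi, pi]) imposed on the
    target copy of the shared driver under condition ``c``; per-epoch jitter
    is von Mises with concentration ``kappa`` (kappa -> inf = rigid lag).
    """

    seed_subroi: int
    target_subroi: int
    band: str
    phase_lags: tuple  # length N_CONDITIONS, radians
    kappa: float = 20.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if len(self.phase_lags) != N_CONDITIONS:
            raise ValueError(f"need {N_CONDITIONS} per-condition phase lags")
        for lag in self.phase_lags:
            if not (-np.pi < lag <= np.pi + 1e-12):
                raise ValueError("phase lags must lie in (-pi, pi]")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (the recovery-test oracle)."""

    couplings: list = field(default_factory=list)
    # condition -> (n_subrois, n_bands) power gains applied after the impulse
    impulse_gains: dict = field(default_factory=dict)
    behavior_intercept: float = 0.70
    behavior_slope: float = 0.14
    behavior_noise_sd: float = 0.08
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    oscillation_amplitude: float = 1.0
    noise_amplitude: float = 1.0
    global_amplitude: float = 0.7
    fidelity_sd: float = 0.15
    master_seed: int | None = None

    def validate(self, layout: RoiLayout) -> None:
        n = layout.n_subrois
        for cs in self.couplings:
            if not (0 <= cs.seed_subroi < n and 0 <= cs.target_subroi < n):
                raise ValueError("coupling references a sub-ROI outside the layout")
            if cs.band not in self.bands:
                raise ValueError(f"coupling band {cs.band!r} not in configured bands")
        for c, gains in self.impulse_gains.items():
            g = np.asarray(gains)
            if g.shape != (n, len(self.bands)):
                raise ValueError(
                    f"impulse gains for condition {c} must be (n_subrois, n_bands)"
                )
            if np.any(g <= 0):
                raise ValueError("impulse power gains must be positive")

    @property
    def band_names(self) -> list[str]:
        return sorted(self.bands, key=lambda k: self.bands[k][0])


@dataclass
class CohortDataset:
    """Epoched sub-ROI time series for every subject and condition.

    ``epochs[(s, c)]`` is a (K, N_subROI, T) float32 array; time runs from
    ``tmin`` at ``sample_rate``; ``impulse[(s, c)]`` flags impulse epochs
    (maintenance phase only).  ``behavior`` holds per-subject proportion
    correct.
    """

    epochs: dict
    sample_rate: float
    tmin: float
    phase: str  # "maintenance" | "encoding"
    layout: RoiLayout
    impulse: dict = field(default_factory=dict)
    behavior: pd.DataFrame | None = None
    fidelity: np.ndarray | None = None
    truth: GroundTruth | None = None

    @property
    def subjects(self) -> list[int]:
        return sorted({s for s, _c in self.epochs})

    @property
    def conditions(self) -> list[int]:
        return sorted({c for _s, c in self.epochs})

    def n_epochs(self, subject: int, condition: int) -> int:
        return self.epochs[(subject, condition)].shape[0]

    @property
    def times(self) -> np.ndarray:
        T = next(iter(self.epochs.values())).shape[2]
        return self.tmin + np.arange(T) / self.sample_rate

    def validate(self) -> None:
        if sorted(self.conditions) != list(range(N_CONDITIONS)):
            raise ValueError(f"expected conditions 0..{N_CONDITIONS - 1}")
        n = self.layout.n_subrois
        for key, arr in self.epochs.items():
            if arr.ndim != 3 or arr.shape[1] != n:
                raise ValueError(f"epoch array {key} has inconsistent sub-ROI dimension")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"epoch array {key} contains non-finite samples")
        if self.phase != "maintenance" and self.impulse:
            raise ValueError("impulse flags are defined only for maintenance epochs")


def _band_limited_noise(
    rng: np.random.Generator, n_epochs: int, T: int, sfreq: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance analytic (complex) band-limited Gaussian noise (K, T)."""
    freqs = np.fft.fftfreq(T, 1.0 / sfreq)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        # band above Nyquist for this epoch length: nearest positive bin
        sel = np.zeros(T, bool)
        sel[np.argmin(np.abs(freqs - np.clip(lo, 0, sfreq / 2)))] = True
    spec = np.zeros((n_epochs, T), dtype=np.complex128)
    m = int(sel.sum())
    spec[:, sel] = rng.standard_normal((n_epochs, m)) + 1j * rng.standard_normal((n_epochs, m))
    z = np.fft.ifft(spec, axis=1)
    # normalize the real part to unit variance per epoch
    sd = z.real.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return z / sd


def _pink_noise(rng: np.random.Generator, n_epochs: int, T: int) -> np.ndarray:
    """1/f-power background noise (spectral slope -1), unit variance, (K, T)."""
    freqs = np.fft.rfftfreq(T)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    spec = (
        rng.standard_normal((n_epochs, freqs.size))
        + 1j * rng.standard_normal((n_epochs, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=T, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_cohort(
    layout: RoiLayout,
    truth: GroundTruth,
    n_subjects: int = 17,
    epochs_per_condition: int = 58,
    epoch_length: float = 2.5,
    sample_rate: float = 500.0,
    phase: str = "maintenance",
    seed: int = 0,
    tmin: float = 0.0,
    impulse_fraction: float = 0.5,
    impulse_latency: float = 2.5,
) -> CohortDataset:
    """Synthesize a cohort with the planted structure in ``truth``.

    Maintenance cohorts flag ``impulse_fraction`` of the epochs per condition
    as impulse trials; for those, the condition's power-gain pattern scales
    the band oscillations for t >= ``impulse_latency`` (seconds on the epoch
    time axis).  Encoding cohorts carry no impulse flags.  Per-subject,
    per-sub-ROI random sign flips emulate the surface-normal sign ambiguity.
    Fully reproducible from ``seed``.
    """
    truth.validate(layout)
    if phase not in ("maintenance", "encoding"):
        raise ValueError("phase must be 'maintenance' or 'encoding'")
    T = int(round(epoch_length * sample_rate))
    N = layout.n_subrois
    bands = truth.band_names
    band_edges = [truth.bands[b] for b in bands]
    times = tmin + np.arange(T) / sample_rate

    fid_rng = child_rng(seed, "fidelity")
    fidelity = np.clip(fid_rng.normal(1.0, truth.fidelity_sd, size=n_subjects), 0.1, None)

    epochs: dict = {}
    impulse: dict = {}
    for s in range(n_subjects):
        sign_rng = child_rng(seed, "signs", s)
        signs = sign_rng.choice([-1.0, 1.0], size=N)
        for c in range(N_CONDITIONS):
            rng = child_rng(seed, "epochs", s, c, phase)
            K = epochs_per_condition
            data = np.zeros((K, N, T))
            if impulse_fraction > 0 and phase == "maintenance":
                n_imp = int(round(impulse_fraction * K))
                flags = np.zeros(K, dtype=bool)
                flags[rng.choice(K, size=n_imp, replace=False)] = True
            else:
                flags = np.zeros(K, dtype=bool)

            # background 1/f noise, plus a zero-lag common component shared by
            # all sub-ROIs: it emulates the instantaneous shared activity that
            # lets sign alignment work, and cancels exactly in ImCoh
            common = truth.global_amplitude * _pink_noise(rng, K, T)
            for r in range(N):
                data[:, r, :] += truth.noise_amplitude * _pink_noise(rng, K, T) + common

            # stationary band oscillations, power equal across conditions
            # except for the impulse gain pattern
            post = times >= impulse_latency
            gains = truth.impulse_gains.get(c)
            for bi, (lo, hi) in enumerate(band_edges):
                for r in range(N):
                    comp = truth.oscillation_amplitude * _band_limited_noise(
                        rng, K, T, sample_rate, lo, hi
                    ).real
                    if gains is not None and post.any() and flags.any():
                        factor = np.sqrt(float(gains[r, bi]))
                        sub = comp[flags]
                        sub[:, post] *= factor
                        comp[flags] = sub
                    data[:, r, :] += comp

            # planted couplings: shared analytic driver per coupling
            for cs in truth.couplings:
                lo, hi = truth.bands[cs.band]
                z = _band_limited_noise(rng, K, T, sample_rate, lo, hi)
                if np.isinf(cs.kappa):
                    theta = np.full(K, cs.phase_lags[c])
                else:
                    theta = rng.vonmises(cs.phase_lags[c], max(cs.kappa, 1e-12), size=K)
                amp = cs.amplitude * fidelity[s]
                data[:, cs.seed_subroi, :] += amp * z.real
                data[:, cs.target_subroi, :] += amp * (z * np.exp(-1j * theta)[:, None]).real

            data *= signs[None, :, None]
            epochs[(s, c)] = data.astype(np.float32)
            if phase == "maintenance":
                impulse[(s, c)] = flags

    behavior = simulate_behavior(truth, fidelity, seed=seed)
    ds = CohortDataset(
        epochs=epochs,
        sample_rate=sample_rate,
        tmin=tmin,
        phase=phase,
        layout=layout,
        impulse=impulse if phase == "maintenance" else {},
        behavior=behavior,
        fidelity=fidelity,
        truth=truth,
    )
    ds.validate()
    return ds


def simulate_behavior(
    truth: GroundTruth, fidelity: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Per-subject proportion correct from the linear behavior link.

    proportion correct = clip(intercept + slope * fidelity + noise, 0, 1)
    with noise ~ N(0, behavior_noise_sd).
    """
    fidelity = np.asarray(fidelity, dtype=float)
    if not np.all(np.isfinite(fidelity)):
        raise ValueError("fidelity values must be finite")
    rng = child_rng(seed, "behavior")
    noise = (
        rng.normal(0.0, truth.behavior_noise_sd, size=fidelity.size)
        if truth.behavior_noise_sd > 0
        else np.zeros(fidelity.size)
    )
    pc = np.clip(truth.behavior_intercept + truth.behavior_slope * fidelity + noise, 0.0, 1.0)
    return pd.DataFrame({"subject": np.arange(fidelity.size), "proportion_correct": pc})


def align_signs(cohort: CohortDataset, max_iter: int = 20) -> CohortDataset:
    """Flip sub-ROIs to correlate positively with the subject-mean reference.

    Mirrors the sign alignment applied to surface-normal source estimates.
    For each subject, every sub-ROI is compared against the leave-one-out
    sum of the other sub-ROIs (concatenated across epochs and conditions)
    and flipped when the correlation is negative; the pass repeats until no
    sub-ROI flips (the shared zero-lag activity anchors a consistent sign
    assignment).  Returns a new dataset.
    """
    new_epochs = {}
    for s in cohort.subjects:
        stacked = np.concatenate(
            [cohort.epochs[(s, c)] for c in cohort.conditions], axis=0
        )  # (K_all, N, T)
        flat = stacked.transpose(1, 0, 2).reshape(stacked.shape[1], -1).astype(np.float64)
        flat -= flat.mean(axis=1, keepdims=True)
        signs = np.ones(flat.shape[0])
        gram = flat @ flat.T  # (N, N)
        for _ in range(max_iter):
            changed = False
            for r in range(signs.size):
                # leave-one-out correlation with the signed sum of the others
                corr = signs[r] * (gram[r] @ signs - signs[r] * gram[r, r])
                if corr < 0:
                    signs[r] *= -1.0
                    changed = True
            if not changed:
                break
        signs = signs.astype(np.float32)
        for c in cohort.conditions:
            new_epochs[(s, c)] = cohort.epochs[(s, c)] * signs[None, :, None]
    return CohortDataset(
        epochs=new_epochs,
        sample_rate=cohort.sample_rate,
        tmin=cohort.tmin,
        phase=cohort.phase,
        layout=cohort.layout,
        impulse=dict(cohort.impulse),
        behavior=cohort.behavior,
        fidelity=cohort.fidelity,
        truth=cohort.truth,
    )


def make_impulse_gains(
    layout: RoiLayout,
    bands: dict,
    roi: str | None = None,
    strength: float = 0.5,
    seed: int = 0,
    n_conditions: int = N_CONDITIONS,
) -> dict:
    """Condition-specific impulse power-gain patterns.

    Draws an independent log-normal gain exp(strength * z) per (condition,
    sub-ROI, band) so that each condition imprints a distinct power pattern
    after the impulse.  If ``roi`` is given, only that ROI's sub-ROIs carry
    gains (elsewhere gain = 1); ``strength = 0`` yields all-ones (no
    impulse effect).
    """
    rng = child_rng(seed, "impulse-gains")
    n = layout.n_subrois
    nb = len(bands)
    sel = np.ones(n, dtype=bool) if roi is None else np.zeros(n, dtype=bool)
    if roi is not None:
        sel[layout.subroi_indices(roi)] = True
    gains = {}
    for c in range(n_conditions):
        g = np.ones((n, nb))
        g[sel] = np.exp(strength * rng.standard_normal((int(sel.sum()), nb)))
        gains[c] = g
    return gains


def _truth_to_json(truth: GroundTruth) -> str:
    d = asdict(truth)
    d["couplings"] = [asdict(c) for c in truth.couplings]
    d["impulse_gains"] = {str(k): np.asarray(v).tolist() for k, v in truth.impulse_gains.items()}
    return json.dumps(d)


def _truth_from_json(s: str) -> GroundTruth:
    d = json.loads(s)
    d["couplings"] = [
        CouplingSpec(**{**c, "phase_lags": tuple(c["phase_lags"])}) for c in d["couplings"]
    ]
    d["impulse_gains"] = {int(k): np.asarray(v) for k, v in d["impulse_gains"].items()}
    return GroundTruth(**d)


def save_cohort(path, cohort: CohortDataset) -> None:
    """Persist a cohort as HDF5: /subjects/<s>/<c>/epochs, /layout, /behavior,
    /meta."""
    with h5py.File(path, "w") as f:
        g = f.create_group("subjects")
        for (s, c), arr in cohort.epochs.items():
            grp = g.require_group(f"{s}").require_group(f"{c}")
            grp.create_dataset("epochs", data=arr, compression="gzip", compression_opts=1)
            if (s, c) in cohort.impulse:
                grp.create_dataset("impulse", data=cohort.impulse[(s, c)])
        lay = f.create_group("layout")
        lay.attrs["rois"] = json.dumps([list(r) for r in cohort.layout.rois])
        lay.attrs["seed_rois"] = json.dumps(list(cohort.layout.seed_rois))
        if cohort.behavior is not None:
            f.create_dataset("behavior", data=cohort.behavior["proportion_correct"].to_numpy())
        if cohort.fidelity is not None:
            f.create_dataset("fidelity", data=cohort.fidelity)
        meta = f.create_group("meta")
        meta.attrs["sample_rate"] = cohort.sample_rate
        meta.attrs["tmin"] = cohort.tmin
        meta.attrs["phase"] = cohort.phase
        if cohort.truth is not None:
            meta.attrs["truth"] = _truth_to_json(cohort.truth)


def load_cohort(path) -> CohortDataset:
    with h5py.File(path, "r") as f:
        epochs: dict = {}
        impulse: dict = {}
        for s in f["subjects"]:
            for c in f["subjects"][s]:
                grp = f["subjects"][s][c]
                epochs[(int(s), int(c))] = grp["epochs"][()]
                if "impulse" in grp:
                    impulse[(int(s), int(c))] = grp["impulse"][()].astype(bool)
        rois = tuple(tuple(r) for r in json.loads(f["layout"].attrs["rois"]))
        layout = RoiLayout(
            rois=rois, seed_rois=tuple(json.loads(f["layout"].attrs["seed_rois"]))
        )
        behavior = None
        if "behavior" in f:
            pc = f["behavior"][()]
            behavior = pd.DataFrame(
                {"subject": np.arange(pc.size), "proportion_correct": pc}
            )
        fidelity = f["fidelity"][()] if "fidelity" in f else None
        meta = f["meta"].attrs
        truth = _truth_from_json(meta["truth"]) if "truth" in meta else None
        return CohortDataset(
            epochs=epochs,
            sample_rate=float(meta["sample_rate"]),
            tmin=float(meta["tmin"]),
            phase=str(meta["phase"]),
            layout=layout,
            impulse=impulse,
            behavior=behavior,
            fidelity=fidelity,
            truth=truth,
        )
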