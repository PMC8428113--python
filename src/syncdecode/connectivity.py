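"""Imaginary-coherence connectivity features between sub-ROI pairs.

The imaginary part of coherency,

    ImCoh(f, t) = Im[ <Sx Sy*>_k / sqrt(<|Sx|^2>_k <|Sy|^2>_k) ],

is insensitive to instantaneous (zero-lag) mixing and therefore robust to
MEG field spread, which makes it the connectivity measure of choice for
source-space phase-synchronization analyses.  The sign convention follows
the formula above: a positive ImCoh at (f, t) means the first signal's phase
leads the second's (Sy = Sx * e^{i pi/2} yields ImCoh = -1).

Features for decoding are built per (seed ROI, target ROI, band, window):
epochs are split into four disjoint seeded quarters, ImCoh is estimated per
quarter for every seed-sub-ROI x target-sub-ROI pair, and the signed values
are averaged over the band's frequency bins and the window's valid time
samples, yielding a vector of N_seed x N_target features per quarter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import child_rng
from .cohort import CohortDataset
from .spectral import FrequencyGrid, morlet_tfr

__all__ = [
    "DEFAULT_WINDOWS",
    "ConnectivityFeatures",
    "imcoh",
    "equalize_epochs",
    "connectivity_features",
    "save_features",
    "load_features",
]

DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "early": (0.5, 1.25),
    "late": (1.25, 2.0),
}
ENCODING_WINDOW: dict[str, tuple[float, float]] = {"encoding": (0.0, 1.0)}

N_SUBSAMPLES = 4


def imcoh(Sx: np.ndarray, Sy: np.ndarray) -> np.ndarray:
    """Imaginary coherence between two (K, F, T) coefficient stacks.

    Averages cross- and auto-spectra over the epoch axis at every (f, t) bin.
    Bounded in [-1, 1]; exactly antisymmetric under argument swap.  Raises if
    fewer than two epochs are available or either signal has zero power at
    some bin (coherence undefined).
    """
    Sx = np.asarray(Sx)
    Sy = np.asarray(Sy)
    if Sx.shape != Sy.shape:
        raise ValueError("coefficient stacks must share shape")
    if Sx.shape[0] < 2:
        raise ValueError("imaginary coherence requires at least 2 epochs")
    # Im[Sx conj(Sy)] in real arithmetic so that swapping the arguments
    # negates every elementary product pair and antisymmetry is exact
    icross = np.mean(Sx.imag * Sy.real - Sx.real * Sy.imag, axis=0)
    px = np.mean(Sx.real**2 + Sx.imag**2, axis=0)
    py = np.mean(Sy.real**2 + Sy.imag**2, axis=0)
    denom = px * py
    if np.any(denom <= 0):
        raise ValueError("zero power: coherence undefined")
    return icross / np.sqrt(denom)


def equalize_epochs(cohort: CohortDataset, seed: int = 0) -> CohortDataset:
    """Fix each subject's epoch count at their minimum condition count.

    Down-samples (seeded, without replacement) every condition of a subject
    to that subject's minimum accepted-epoch count, keeping the
    signal-to-noise ratio of the coherence estimates constant across
    conditions.
    """
    new_epochs = {}
    new_impulse = {}
    for s in cohort.subjects:
        kmin = min(cohort.n_epochs(s, c) for c in cohort.conditions)
        for c in cohort.conditions:
            arr = cohort.epochs[(s, c)]
            if arr.shape[0] == kmin:
                sel = np.arange(kmin)
            else:
                rng = child_rng(seed, "equalize", s, c)
                sel = np.sort(rng.choice(arr.shape[0], size=kmin, replace=False))
            new_epochs[(s, c)] = arr[sel]
            if (s, c) in cohort.impulse:
                new_impulse[(s, c)] = cohort.impulse[(s, c)][sel]
    return CohortDataset(
        epochs=new_epochs,
        sample_rate=cohort.sample_rate,
        tmin=cohort.tmin,
        phase=cohort.phase,
        layout=cohort.layout,
        impulse=new_impulse,
        behavior=cohort.behavior,
        fidelity=cohort.fidelity,
        truth=cohort.truth,
    )


@dataclass
class ConnectivityFeatures:
    """ImCoh feature tensors per (seed ROI, target ROI, band, window).

    ``features[(seed, target, band, window)]`` is an array of shape
    (n_subjects, n_conditions, n_subsamples, N_seed * N_target), ordered
    seed-major then target.  Values lie in [-1, 1].
    """

    features: dict
    subjects: list
    conditions: list
    n_subsamples: int = N_SUBSAMPLES
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    grid: FrequencyGrid | None = None

    def matrix(self, seed_roi: str, target_roi: str, band: str, window: str):
        """(X, y, subjects) design for a decoder: one row per subject x
        condition x subsample."""
        arr = self.features[(seed_roi, target_roi, band, window)]
        ns, nc, nq, nf = arr.shape
        X = arr.reshape(ns * nc * nq, nf)
        y = np.tile(np.repeat(np.arange(nc), nq), ns)
        subj = np.repeat(self.subjects, nc * nq)
        return X, y, subj

    @property
    def tests(self) -> list[tuple]:
        return sorted(self.features)

    def to_frame(self):
        """Long-format export (one row per subject x condition x subsample)."""
        import pandas as pd

        rows = []
        for (seed, target, band, window), arr in sorted(self.features.items()):
            ns, nc, nq, nf = arr.shape
            for si, s in enumerate(self.subjects):
                for c in range(nc):
                    for q in range(nq):
                        rows.append(
                            {
                                "seed_roi": seed,
                                "target_roi": target,
                                "band": band,
                                "window": window,
                                "subject": s,
                                "condition": c,
                                "subsample": q,
                                **{
                                    f"f{i}": arr[si, c, q, i] for i in range(nf)
                                },
                            }
                        )
        return pd.DataFrame(rows)


def save_features(path, feats: ConnectivityFeatures) -> None:
    """Persist features to HDF5 under /features/connectivity/<pair>/<band>/<window>."""
    import h5py

    with h5py.File(path, "w") as f:
        root = f.create_group("features/connectivity")
        for (sr, tr, band, window), arr in feats.features.items():
            g = root.require_group(f"{sr}__{tr}").require_group(band)
            g.create_dataset(window, data=arr)
        f.attrs["subjects"] = feats.subjects
        f.attrs["conditions"] = feats.conditions
        f.attrs["n_subsamples"] = feats.n_subsamples
        import json

        f.attrs["windows"] = json.dumps({k: list(v) for k, v in feats.windows.items()})


def load_features(path) -> ConnectivityFeatures:
    import h5py
    import json

    with h5py.File(path, "r") as f:
        features = {}
        root = f["features/connectivity"]
        for pair in root:
            sr, tr = pair.split("__")
            for band in root[pair]:
                for window in root[pair][band]:
                    features[(sr, tr, band, window)] = root[pair][band][window][()]
        return ConnectivityFeatures(
            features=features,
            subjects=list(f.attrs["subjects"]),
            conditions=list(f.attrs["conditions"]),
            n_subsamples=int(f.attrs["n_subsamples"]),
            windows={k: tuple(v) for k, v in json.loads(f.attrs["windows"]).items()},
        )


def _quarter_assignment(K: int, n_subsamples: int, rng: np.random.Generator) -> list[np.ndarray]:
    per = K // n_subsamples
    if per < 2:
        raise ValueError(
            f"{K} epochs yield quarters of {per} epochs; coherence needs >= 2 per quarter"
        )
    order = rng.permutation(K)
    return [order[q * per : (q + 1) * per] for q in range(n_subsamples)]


def connectivity_features(
    cohort: CohortDataset,
    grid: FrequencyGrid,
    windows: dict | None = None,
    seed_rois: list | None = None,
    target_rois: list | None = None,
    n_subsamples: int = N_SUBSAMPLES,
    seed: int = 0,
    n_cycles: float = 7.0,
    same_hemisphere_only: bool = True,
) -> ConnectivityFeatures:
    """Assemble ImCoh decoding features for every seed-target ROI pair.

    For each subject and condition the (equalized) epochs are split into
    ``n_subsamples`` disjoint seeded quarters (remainder epochs dropped);
    within each quarter, ImCoh between every seed sub-ROI and target sub-ROI
    is band/window averaged over valid (unmasked) samples only.  Connections
    are restricted to intra-hemispheric seed-target pairs by default.
    """
    windows = dict(windows) if windows is not None else (
        dict(DEFAULT_WINDOWS) if cohort.phase == "maintenance" else dict(ENCODING_WINDOW)
    )
    layout = cohort.layout
    seed_rois = list(seed_rois) if seed_rois is not None else list(layout.seed_rois)
    target_rois = (
        list(target_rois) if target_rois is not None else layout.target_rois()
    )

    def hemi(roi: str) -> str:
        for name, h, _n in layout.rois:
            if name == roi:
                return h
        raise KeyError(roi)

    pairs = [
        (sr, tr)
        for sr in seed_rois
        for tr in target_rois
        if (not same_hemisphere_only) or hemi(sr) == hemi(tr)
    ]
    if not pairs:
        raise ValueError("no seed-target ROI pairs to analyze")
    bands = grid.band_names

    subjects = cohort.subjects
    conditions = cohort.conditions
    feats = {
        (sr, tr, b, w): np.zeros(
            (
                len(subjects),
                len(conditions),
                n_subsamples,
                layout.subroi_indices(sr).size * layout.subroi_indices(tr).size,
            )
        )
        for sr, tr in pairs
        for b in bands
        for w in windows
    }

    needed = sorted(
        {i for sr, tr in pairs for i in layout.subroi_indices(sr)}
        | {i for sr, tr in pairs for i in layout.subroi_indices(tr)}
    )
    pos = {g: i for i, g in enumerate(needed)}

    for si, s in enumerate(subjects):
        for c in conditions:
            arr = cohort.epochs[(s, c)]
            rng = child_rng(seed, "quarters", s, c)
            quarters = _quarter_assignment(arr.shape[0], n_subsamples, rng)
            for q, idx in enumerate(quarters):
                sub = arr[idx][:, needed, :].astype(np.float64)
                Kq, Nn, T = sub.shape
                tens = morlet_tfr(
                    sub.reshape(Kq * Nn, T), cohort.sample_rate, grid,
                    n_cycles=n_cycles, tmin=cohort.tmin,
                )
                S = tens.data.reshape(Kq, Nn, grid.frequencies.size, T)
                for sr, tr in pairs:
                    s_idx = [pos[g] for g in layout.subroi_indices(sr)]
                    t_idx = [pos[g] for g in layout.subroi_indices(tr)]
                    Ss = S[:, s_idx]  # (Kq, Ns, F, T)
                    St = S[:, t_idx]
                    cross = np.einsum("kaft,kbft->abft", Ss, np.conj(St)) / Kq
                    ps = np.mean(np.abs(Ss) ** 2, axis=0)  # (Ns, F, T)
                    pt = np.mean(np.abs(St) ** 2, axis=0)
                    denom = np.sqrt(ps[:, None] * pt[None, :])
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ic = np.imag(cross) / denom  # (Ns, Nt, F, T)
                    for w, (t0, t1) in windows.items():
                        tmask = tens.window_mask(t0, t1)
                        for b in bands:
                            fidx = grid.band_indices(b)
                            ok = tens.valid[np.ix_(fidx, tmask)]
                            block = ic[:, :, fidx][:, :, :, tmask]
                            if not ok.any():
                                raise ValueError(
                                    f"window {w!r} has no valid samples in band {b!r}"
                                )
                            vals = block[:, :, ok].mean(axis=2)
                            feats[(sr, tr, b, w)][si, c, q, :] = vals.reshape(-1)

    return ConnectivityFeatures(
        features=feats,
        subjects=subjects,
        conditions=conditions,
        n_subsamples=n_subsamples,
        windows=windows,
        grid=grid,
    )
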