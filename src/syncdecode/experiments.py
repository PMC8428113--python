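"""Calibration and recovery experiments on synthetic cohorts.

These are the package's validation studies: because the generative truth is
known, the whole analysis chain can be checked for chance-level calibration
(null cohorts decode at 1/6), family-wise error control (the max-statistic
and min-RMSE permutation procedures), planted-coupling recovery, and the
impulse-probe contrast.  Problem sizes are reduced relative to a full MEG
study so each experiment runs in minutes on a single core; the methods note
documents the choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .cohort import (
    CouplingSpec,
    GroundTruth,
    RoiLayout,
    align_signs,
    make_impulse_gains,
    simulate_cohort,
)
from .connectivity import connectivity_features
from .decoding import DecoderSpec, SvrFoldCache, power_pattern_decode
from .inference import svr_permutation_null
from .pipeline import connectivity_inference, decode_all_connections, impulse_contrast
from .spectral import FrequencyGrid

__all__ = [
    "ReducedDesign",
    "fwer_calibration",
    "chance_calibration",
    "recovery_experiment",
    "svr_rule_calibration",
    "impulse_detection_experiment",
]

TWO_BANDS = {"alpha": (8.0, 12.0), "high_gamma": (61.0, 120.0)}
# lags chosen so the six conditions map to equally spaced ImCoh targets
CONDITION_LAGS = tuple(np.arcsin(np.linspace(-0.9, 0.9, 6)))


@dataclass(frozen=True)
class ReducedDesign:
    """Shared knobs of the desk-scale synthetic designs."""

    sample_rate: float = 250.0
    epoch_length: float = 2.5
    bands: dict = field(default_factory=lambda: dict(TWO_BANDS))
    bins_per_band: int = 3

    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.from_bands(self.bands, self.bins_per_band)


def fwer_calibration(
    n_replicates: int = 200,
    n_perm: int = 100,
    seed: int = 1,
    n_subjects: int = 4,
    epochs_per_condition: int = 16,
) -> dict:
    """Family-wise false-positive rate of the max-stat procedure.

    Each replicate simulates a fully null cohort on a reduced design whose
    test family has 4 members (one connection x two bands x two windows),
    runs the full feature -> decode -> permutation chain with ``n_perm``
    label permutations, and records whether any test is flagged after
    max-statistic correction.  Short (1.2 s) epochs keep both windows inside
    the valid wavelet region for the beta and gamma bands used here.
    """
    bands = {"beta": (13.0, 30.0), "high_gamma": (61.0, 120.0)}
    windows = {"early": (0.3, 0.7), "late": (0.7, 1.1)}
    layout = RoiLayout.reduced(1, 1, 1)
    grid = FrequencyGrid.from_bands(bands, 3)
    flags = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        truth = GroundTruth(bands=bands)
        cohort = simulate_cohort(
            layout, truth, n_subjects=n_subjects,
            epochs_per_condition=epochs_per_condition, epoch_length=1.2,
            sample_rate=250.0, seed=rep_seed,
        )
        cohort = align_signs(cohort)
        feats = connectivity_features(cohort, grid, windows=windows, seed=rep_seed)
        spec = DecoderSpec(n_repeats=10, seed=rep_seed)
        _, report = connectivity_inference(
            feats, spec, n_perm=n_perm, splits_per_perm=1, seed=rep_seed
        )
        flags.append(bool(report.table["significant"].any()))
    flags = np.asarray(flags)
    return {
        "fwer": float(flags.mean()),
        "n_replicates": n_replicates,
        "n_tests": 4,
        "n_perm": n_perm,
        "flags": flags,
    }


def chance_calibration(
    n_cohorts: int = 20,
    seed: int = 1,
    n_subjects: int = 8,
    epochs_per_condition: int = 40,
    design: ReducedDesign | None = None,
) -> dict:
    """Mean decoding accuracy across null cohorts (should be ~1/6).

    Null cohorts (no couplings, no impulse gains) run through sign
    alignment, ImCoh features and cross-subject decoding for every
    connection x band x window test; accuracies are pooled over all tests
    and cohorts.
    """
    design = design or ReducedDesign()
    layout = RoiLayout.reduced(2, 2, 2)
    grid = design.grid()
    accs = []
    for rep in range(n_cohorts):
        rep_seed = seed + rep
        truth = GroundTruth(bands=dict(design.bands))
        cohort = align_signs(
            simulate_cohort(
                layout, truth, n_subjects=n_subjects,
                epochs_per_condition=epochs_per_condition,
                epoch_length=design.epoch_length,
                sample_rate=design.sample_rate, seed=rep_seed,
            )
        )
        feats = connectivity_features(cohort, grid, seed=rep_seed)
        results = decode_all_connections(feats, DecoderSpec(n_repeats=20, seed=rep_seed))
        accs.extend(r.accuracy for r in results.values())
    accs = np.asarray(accs)
    return {
        "mean_accuracy": float(accs.mean()),
        "chance": 1.0 / 6.0,
        "n_cohorts": n_cohorts,
        "n_tests_per_cohort": accs.size // n_cohorts,
        "accuracies": accs,
    }


def planted_truth(kappa: float = 50.0, amplitude: float = 3.0) -> GroundTruth:
    """One strong condition-specific coupling: STC sub-ROI 0 -> IFG sub-ROI 0
    at high gamma (the documented strong-recovery regime)."""
    return GroundTruth(
        couplings=[CouplingSpec(0, 2, "high_gamma", CONDITION_LAGS,
                                kappa=kappa, amplitude=amplitude)],
        bands=dict(TWO_BANDS),
    )


def recovery_experiment(
    n_replicates: int = 50,
    seed: int = 1,
    n_subjects: int = 5,
    epochs_per_condition: int = 32,
    n_perm: int = 100,
    kappa: float = 50.0,
    amplitude: float = 3.0,
    n_power_cohorts: int = 8,
) -> dict:
    """Planted-coupling recovery plus the power-control contrast.

    Per replicate, a cohort with exactly one planted (pair, band) coupling
    is pushed through the full inference chain; recovery is *unique* when
    the planted (pair, band) — and no other — carries a significant window.
    Because the coupling is phase-only, power-pattern decoding on the same
    cohorts must stay at chance; the first ``n_power_cohorts`` replicates
    are reused for that contrast.
    """
    layout = RoiLayout.reduced(2, 2, 2)
    grid = FrequencyGrid.from_bands(TWO_BANDS, 3)
    planted_key = ("STC-rh", "IFG-rh", "high_gamma")
    unique = []
    power_accs = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        truth = planted_truth(kappa=kappa, amplitude=amplitude)
        cohort = align_signs(
            simulate_cohort(
                layout, truth, n_subjects=n_subjects,
                epochs_per_condition=epochs_per_condition, epoch_length=2.5,
                sample_rate=250.0, seed=rep_seed,
            )
        )
        feats = connectivity_features(cohort, grid, seed=rep_seed)
        spec = DecoderSpec(n_repeats=20, seed=rep_seed)
        _, report = connectivity_inference(
            feats, spec, n_perm=n_perm, splits_per_perm=1, seed=rep_seed
        )
        sig = report.table.loc[report.table["significant"], "test"]
        pair_bands = {(t[0], t[1], t[2]) for t in sig}
        unique.append(pair_bands == {planted_key})
        if rep < n_power_cohorts:
            from .spectral import power_features

            pf = power_features(
                cohort, "STC-rh", grid=grid, seed=rep_seed,
                impulse=None, fmin=grid.frequencies[0], fmax=grid.frequencies[-1],
            )
            for band in grid.band_names:
                power_accs.append(
                    power_pattern_decode(pf.band_matrix(band)).accuracy
                )
    unique = np.asarray(unique)
    power_accs = np.asarray(power_accs)
    return {
        "unique_recovery_rate": float(unique.mean()),
        "n_replicates": n_replicates,
        "power_mean_accuracy": float(power_accs.mean()),
        "power_accuracies": power_accs,
        "kappa": kappa,
        "amplitude": amplitude,
    }


def svr_rule_calibration(
    n_sims: int = 200,
    n_perm: int = 100,
    seed: int = 1,
    n_subjects: int = 8,
    n_features: int = 6,
) -> dict:
    """False-positive rate of the both-windows min-RMSE SVR rule.

    Behavior independent of the features: per simulation, Gaussian
    connectivity features for 2 connections x 2 windows and behavior drawn
    around the typical 0.84 proportion correct; a connection counts as a
    false positive when its RMSE beats the pooled null threshold in both
    windows.
    """
    import warnings

    tests = [(c, w) for c in ("c1", "c2") for w in ("early", "late")]
    flags = []
    for sim in range(n_sims):
        rng = np.random.default_rng(derive_seed(seed, "svr-cal", sim))
        behavior = np.clip(rng.normal(0.84, 0.1, n_subjects), 0.0, 1.0)
        caches = {
            t: SvrFoldCache(rng.standard_normal((n_subjects, 4, n_features)))
            for t in tests
        }

        def svr_fn(test, perm_b, _caches=caches, _b=behavior):
            return _caches[test].rmse(_b, perm_b)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            _, report = svr_permutation_null(
                svr_fn, behavior, tests, n_perm=n_perm,
                seed=derive_seed(seed, "svr-null", sim),
            )
        flags.append(bool(report.table["significant"].any()))
    flags = np.asarray(flags)
    return {"fwer": float(flags.mean()), "n_sims": n_sims, "flags": flags}


def impulse_detection_experiment(
    n_replicates: int = 100,
    strength: float = 0.8,
    seed: int = 1,
    n_subjects: int = 4,
    epochs_per_condition: int = 32,
) -> dict:
    """Detection rate of the mixed-model impulse contrast.

    Per replicate: maintenance cohort whose impulse trials carry
    condition-specific power-gain patterns in the STC sub-ROIs (strength 0
    = null), power-pattern decoding with/without impulse, and the LME test
    of the impulse fixed effect (positive estimate, Bonferroni-adjusted
    p < 0.05 counts as detection).
    """
    bands = dict(TWO_BANDS)
    layout = RoiLayout.reduced(3, 2, 1)
    grid = FrequencyGrid.from_bands(bands, 3)
    detected = []
    estimates = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        gains = (
            make_impulse_gains(layout, bands, roi="STC-rh", strength=strength,
                               seed=rep_seed)
            if strength > 0
            else {}
        )
        truth = GroundTruth(impulse_gains=gains, bands=bands)
        cohort = simulate_cohort(
            layout, truth, n_subjects=n_subjects,
            epochs_per_condition=epochs_per_condition, epoch_length=3.0,
            sample_rate=250.0, seed=rep_seed, impulse_latency=2.0,
        )
        _, lme = impulse_contrast(
            cohort, rois=["STC-rh"], grid=grid, time_window=(2.0, 3.0),
            seed=rep_seed,
        )
        detected.append(
            lme.estimates["impulse"] > 0 and lme.pvalues["impulse"] < 0.05
        )
        estimates.append(lme.estimates["impulse"])
    detected = np.asarray(detected)
    return {
        "detection_rate": float(detected.mean()),
        "n_replicates": n_replicates,
        "strength": strength,
        "mean_effect": float(np.mean(estimates)),
    }
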