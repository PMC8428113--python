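"""Permutation-based statistical inference.

Significance of decoding accuracies uses label-permutation nulls pooled with
the maximum statistic across the whole family of tests (connection x band),
which controls the family-wise error rate without parametric assumptions.
p-values use the add-one convention p = (1 + exceedances) / (1 + n_perm), so
p is never exactly zero.

The impulse-sound contrast on power-decoding accuracies is a linear mixed
model with a subject random intercept and fixed effects of impulse presence
and log2 band center frequency, Bonferroni-corrected across the family of
reported t statistics.  The behavioral SVR uses a min-RMSE pooled null with
a both-windows decision rule, and the power-variation test is a band-level
sign-flip maximum-|t| permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = [
    "NullDistribution",
    "InferenceReport",
    "LmeResult",
    "label_permutation_null",
    "maxstat_correct",
    "impulse_effect_model",
    "svr_permutation_null",
    "power_variation_test",
]


@dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray  # (n_perm,)
    pooling: str = "per-test"  # "max" | "min" | "per-test"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null distribution contains non-finite values")

    @property
    def n_perm(self) -> int:
        return self.values.size


@dataclass
class InferenceReport:
    """Observed statistics, corrected p-values and the significant set."""

    table: pd.DataFrame  # columns: test, observed, p, significant
    alpha: float = 0.05
    pooled_null: np.ndarray | None = None
    notes: dict = field(default_factory=dict)

    @property
    def significant(self) -> list:
        return list(self.table.loc[self.table["significant"], "test"])


def _count_distinct_permutations(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    log_n = math.lgamma(len(y) + 1) - sum(math.lgamma(c + 1) for c in counts)
    return math.exp(min(log_n, 700.0))


def label_permutation_null(
    decode_fn,
    y: np.ndarray,
    n_perm: int = 500,
    seed: int = 0,
    statistic: str = "accuracy",
) -> NullDistribution:
    """Accuracy null from decoding with permuted training labels.

    ``decode_fn(y_perm)`` must rerun the decoder with ``y_perm`` substituted
    for the *training-side* labels and return an accuracy.  The ``n_perm``
    label permutations are unique (resampled on collision) and reproducible
    from ``seed``.
    """
    y = np.asarray(y)
    if n_perm > _count_distinct_permutations(y):
        raise ValueError("n_perm exceeds the number of distinct label permutations")
    rng = child_rng(seed, "label-permutation")
    seen = set()
    values = np.empty(n_perm)
    i = 0
    while i < n_perm:
        perm = rng.permutation(y)
        key = perm.tobytes()
        if key in seen:
            continue
        seen.add(key)
        values[i] = decode_fn(perm)
        i += 1
    return NullDistribution(statistic=statistic, values=values, pooling="per-test")


def maxstat_correct(
    observed: dict,
    nulls: dict,
    alpha: float = 0.05,
) -> InferenceReport:
    """Family-wise-corrected p-values via the maximum-statistic null.

    ``observed`` maps test id -> statistic; ``nulls`` maps the same ids to
    :class:`NullDistribution` objects sharing n_perm.  The pooled null is
    the per-permutation maximum across tests, and
    p = (1 + #{pooled >= observed}) / (1 + n_perm).
    """
    tests = sorted(observed)
    if sorted(nulls) != tests:
        raise ValueError("observed and nulls must cover the same tests")
    n_perms = {nulls[t].n_perm for t in tests}
    if len(n_perms) != 1:
        raise ValueError("all tests must share the same number of permutations")
    n_perm = n_perms.pop()
    null_matrix = np.vstack([nulls[t].values for t in tests])  # (n_tests, n_perm)
    pooled = null_matrix.max(axis=0)
    rows = []
    for t in tests:
        obs = float(observed[t])
        p = (1.0 + np.sum(pooled >= obs)) / (1.0 + n_perm)
        rows.append({"test": t, "observed": obs, "p": p, "significant": p <= alpha})
    return InferenceReport(
        table=pd.DataFrame(rows), alpha=alpha, pooled_null=pooled,
        notes={"pooling": "max", "n_perm": n_perm, "n_tests": len(tests)},
    )


@dataclass
class LmeResult:
    """Mixed-model impulse contrast on rescaled decoding accuracies."""

    estimates: dict  # term -> coefficient
    tvalues: dict
    dof: int
    pvalues: dict  # Bonferroni-adjusted
    raw_pvalues: dict
    n_comparisons: int
    random_intercept_sd: float


def impulse_effect_model(
    table: pd.DataFrame,
    n_comparisons: int = 13,
    random_intercept: bool = True,
) -> LmeResult:
    """Mixed model for the impulse-sound effect on decoding accuracy.

    ``table`` needs columns ``subject``, ``band_center`` (Hz), ``impulse``
    (bool/0-1) and ``accuracy``.  The response is accuracy rescaled by
    subtracting chance (1/6); fixed effects are impulse presence and log2
    band center frequency; subject identity enters as a random intercept
    (``random_intercept=False`` reduces the model to OLS).  t statistics use
    the residual degrees-of-freedom convention and p-values are Bonferroni
    adjusted across ``n_comparisons`` tests.
    """
    import statsmodels.api as sm

    req = {"subject", "band_center", "impulse", "accuracy"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    df = table.copy()
    df["y"] = df["accuracy"] - 1.0 / 6.0
    df["impulse"] = df["impulse"].astype(float)
    df["log2_cf"] = np.log2(df["band_center"].astype(float))
    exog = sm.add_constant(df[["impulse", "log2_cf"]])
    n, k = exog.shape
    dof = n - k

    params = bse = None
    re_sd = 0.0
    if random_intercept:
        import warnings as _warnings

        model = sm.MixedLM(df["y"], exog, groups=df["subject"])
        with _warnings.catch_warnings():
            # a zero random-intercept variance (boundary solution) is a valid
            # outcome here, not a failure
            _warnings.simplefilter("ignore")
            try:
                fit = model.fit(reml=True, method="lbfgs")
                params = fit.fe_params
                bse = fit.bse_fe
                re_sd = float(np.sqrt(max(float(fit.cov_re.iloc[0, 0]), 0.0)))
            except (np.linalg.LinAlgError, ValueError):
                params = None  # boundary degeneracy: fall back to OLS below
    if params is None or not np.all(np.isfinite(np.asarray(bse, dtype=float))):
        fit = sm.OLS(df["y"], exog).fit()
        params = fit.params
        bse = fit.bse
        re_sd = 0.0

    from scipy import stats

    estimates, tvals, pvals_raw, pvals = {}, {}, {}, {}
    for term in ("const", "impulse", "log2_cf"):
        est = float(params[term])
        se = float(bse[term])
        t = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan
        estimates[term] = est
        tvals[term] = t
        pvals_raw[term] = p
        pvals[term] = min(1.0, n_comparisons * p) if np.isfinite(p) else np.nan
    return LmeResult(
        estimates=estimates,
        tvalues=tvals,
        dof=dof,
        pvalues=pvals,
        raw_pvalues=pvals_raw,
        n_comparisons=n_comparisons,
        random_intercept_sd=re_sd,
    )


def svr_permutation_null(
    svr_fn,
    behavior: np.ndarray,
    tests: list,
    windows: tuple = ("early", "late"),
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_subsamples: int = 4,
) -> tuple[NullDistribution, InferenceReport]:
    """Min-RMSE pooled permutation null for the behavioral SVR.

    ``svr_fn(test, permuted_behavior)`` must return the cross-validated RMSE
    of one (connection, band, window) test; ``permuted_behavior`` is
    (n_subjects, n_subsamples) or None for the observed fit.  Each
    permutation shuffles the behavior values across subjects *within each
    subsample*, reruns every test, and contributes the minimum RMSE over all
    tests and windows to the pooled null.  A connection/band is significant
    when its RMSE beats the null's ``alpha/2`` quantile in *both* the early
    and the late window (two-tailed 0.05 rule).
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100: unstable null percentile", stacklevel=2)
    behavior = np.asarray(behavior, dtype=float)
    ns = behavior.size
    rng = child_rng(seed, "svr-permutation")

    observed = {test: float(svr_fn(test, None)) for test in tests}
    null_vals = np.empty(n_perm)
    for p in range(n_perm):
        perm_b = np.empty((ns, n_subsamples))
        for q in range(n_subsamples):
            perm_b[:, q] = behavior[rng.permutation(ns)]
        null_vals[p] = min(float(svr_fn(test, perm_b)) for test in tests)
    null = NullDistribution(statistic="min_rmse", values=null_vals, pooling="min")
    threshold = float(np.quantile(null_vals, alpha / 2.0))

    # group tests by connection/band, requiring significance in all windows
    def strip_window(test):
        return tuple(x for x in test if x not in windows)

    groups: dict = {}
    for test in tests:
        groups.setdefault(strip_window(test), []).append(test)
    rows = []
    for gkey, members in sorted(groups.items()):
        sig = len(members) == len(windows) and all(
            observed[m] < threshold for m in members
        )
        for m in members:
            rows.append(
                {"test": m, "observed": observed[m],
                 "p": (1.0 + np.sum(null_vals <= observed[m])) / (1.0 + n_perm),
                 "significant": sig}
            )
    report = InferenceReport(
        table=pd.DataFrame(rows), alpha=alpha, pooled_null=null_vals,
        notes={"threshold": threshold, "rule": "both-windows min-RMSE"},
    )
    return null, report


def power_variation_test(
    changes: np.ndarray,
    band_names: list | None = None,
    window_names: list | None = None,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> InferenceReport:
    """Sign-flip max-|t| permutation test on relative power changes.

    ``changes`` is (n_subjects, n_bands, n_windows).  A one-sample t
    statistic is computed per band/window; the null flips each subject's
    sign at random and pools the maximum |t| over all bands x windows
    (a discrete-family simplification of cluster-style correction).
    Degenerate cells (zero variance) are reported with p = 1 and flagged.
    """
    X = np.asarray(changes, dtype=float)
    if X.ndim == 2:
        X = X[:, :, None]
    ns, nb, nw = X.shape
    if ns < 2:
        raise ValueError("need at least 2 subjects")
    band_names = band_names or [f"band{i}" for i in range(nb)]
    window_names = window_names or [f"win{i}" for i in range(nw)]

    def tstats(data):
        m = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / (sd / np.sqrt(ns))
        return t

    t_obs = tstats(X)
    degenerate = ~np.isfinite(t_obs)
    rng = child_rng(seed, "sign-flip")
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=ns)
        t_null = tstats(X * flips[:, None, None])
        finite = np.abs(t_null[np.isfinite(t_null)])
        null_max[p] = finite.max() if finite.size else 0.0

    rows = []
    for bi in range(nb):
        for wi in range(nw):
            test = (band_names[bi], window_names[wi])
            if degenerate[bi, wi]:
                rows.append({"test": test, "observed": np.nan, "p": 1.0,
                             "significant": False, "degenerate": True})
                continue
            obs = abs(float(t_obs[bi, wi]))
            p = (1.0 + np.sum(null_max >= obs)) / (1.0 + n_perm)
            rows.append({"test": test, "observed": float(t_obs[bi, wi]), "p": p,
                         "significant": p <= alpha, "degenerate": False})
    return InferenceReport(
        table=pd.DataFrame(rows), alpha=alpha, pooled_null=null_max,
        notes={"pooling": "max |t|", "n_perm": n_perm},
    )
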