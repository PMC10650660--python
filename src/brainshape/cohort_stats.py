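"""Cohort-level statistics for biomarker evaluation.

The pipeline mirrors how imaging biomarkers of conversion are evaluated:
ROC analysis with a DeLong CI and paired DeLong comparison of correlated
curves, Youden-index cutoff selection, a PET-threshold sweep that picks the
fraction maximizing AUC, Kaplan–Meier curves with the log-rank test, a
univariate binary-covariate proportional-hazards hazard ratio, Spearman rank
correlation, and baseline group comparisons (Welch t / Pearson chi-square).

The cohort table is a pandas DataFrame with columns ``subject_id``, score
columns (``bass``, ``bai``, ``shape_feature``, optionally ``suvr`` and
covariates), ``event`` (0/1 conversion within the horizon) and
``time_months`` (event or censoring time).

Implementation notes. AUC uses the Mann–Whitney rank formulation with ties
counted 1/2; its variance (and the paired comparison) uses DeLong's
structural components, for which no installed package exists. The log-rank
chi-square and the hazard ratio are likewise computed in-package: the HR
comes from the partial likelihood of a single binary covariate with Breslow
tie handling, maximized by Newton iteration — deterministic, closed-form
derivatives, and cross-checkable against general-purpose survival fitters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .image_io import VoxelVolume
from .masking import largest_component, threshold_pet_voi
from .shape_metrics import compute_bass, compute_shape_feature, measure_surface_and_volume

__all__ = [
    "RocResult",
    "roc_auc",
    "delong_compare",
    "ThresholdSweepResult",
    "threshold_sweep",
    "KmLogrankResult",
    "km_logrank",
    "spearman",
    "compare_groups",
    "validate_cohort_table",
]

_MAX_LOG_HR = 30.0  # |beta| cap: beyond this the partial likelihood is flat (monotone likelihood)


def validate_cohort_table(table: pd.DataFrame, horizon_months: float | None = None) -> None:
    """Check the cohort-table contract used by the survival operations."""
    for col in ("event", "time_months"):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
        if table[col].isna().any():
            raise ValueError(f"cohort table has missing values in {col!r}")
    if not set(np.unique(table["event"])) <= {0, 1}:
        raise ValueError("event column must be 0/1")
    if (table["time_months"] < 0).any():
        raise ValueError("time_months must be >= 0")
    if horizon_months is not None and (table["time_months"] > horizon_months).any():
        raise ValueError("time_months exceeds the follow-up horizon")


# ---------------------------------------------------------------------------
# ROC / DeLong


@dataclass(frozen=True)
class RocResult:
    """AUC with DeLong CI, the full curve, and the Youden-index cutoff.

    The classification rule is ``score > cutoff`` (matching how published
    cutoffs like "shape feature > 1.54" are stated), so applying
    ``youden_cutoff`` back to the same cohort reproduces
    (``youden_sensitivity``, ``youden_specificity``) exactly.
    """

    auc: float
    ci95: tuple[float, float]
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    youden_cutoff: float
    youden_sensitivity: float
    youden_specificity: float


def _check_two_class(labels: np.ndarray) -> None:
    if not set(np.unique(labels)) == {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per case, V01 per control)."""
    x = scores[labels == 1][:, None]
    y = scores[labels == 0][None, :]
    psi = (x > y).astype(float) + 0.5 * (x == y)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def roc_auc(scores, labels) -> RocResult:
    """ROC analysis of one score against a binary outcome.

    AUC is the Mann–Whitney probability that a random case outscores a
    random control (ties count 1/2); the 95% CI is Wald on the DeLong
    structural-component variance, clipped to [0, 1]. The curve is evaluated
    at every unique score value; the Youden cutoff maximizes
    sensitivity + specificity - 1, ties resolved toward the lowest cutoff
    (the more sensitive rule).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    _check_two_class(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.96 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # cutoffs ascending; prepend one below min so the (sens=1, spec=0) corner exists
    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    pos, neg = scores[labels == 1], scores[labels == 0]
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first max = lowest cutoff
    return RocResult(
        auc=auc,
        ci95=ci,
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        youden_cutoff=float(thresholds[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
    )


def delong_compare(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test for two correlated ROC curves on the same subjects.

    Returns ``{"auc_a", "auc_b", "z", "p_value"}`` with a two-sided normal
    p-value. Identical score vectors give p = 1 by convention (zero variance,
    zero difference).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    _check_two_class(labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p_value": float(p)}


# ---------------------------------------------------------------------------
# PET-threshold sweep


@dataclass(frozen=True)
class ThresholdSweepResult:
    """Per-fraction AUC table and the AUC-maximizing fraction."""

    table: pd.DataFrame
    best_fraction: float
    dropped_subjects: tuple[int, ...] = ()


def threshold_sweep(
    pet_volumes: list[VoxelVolume],
    labels,
    fractions=(0.3, 0.4, 0.5, 0.6, 0.7),
    downstream: str = "bass",
    bai=None,
    method: str = "mesh",
    connectivity: int = 26,
) -> ThresholdSweepResult:
    """Recompute the chosen score at each PET threshold fraction and rank by AUC.

    This is the calibration experiment behind the default fraction of 0.5:
    the VOI is re-segmented at each fraction, the downstream score (``bass``,
    or ``shape_feature`` given a per-subject ``bai`` vector) recomputed, and
    the conversion-prediction AUC tabulated. Subjects whose VOI is empty at
    any fraction are dropped with a warning. Ties in the best AUC resolve to
    the lowest fraction. Deterministic.
    """
    labels = np.asarray(labels)
    if len(pet_volumes) != len(labels):
        raise ValueError("pet_volumes and labels must have equal length")
    if downstream not in ("bass", "shape_feature"):
        raise ValueError(f"unknown downstream score {downstream!r}")
    if downstream == "shape_feature":
        if bai is None:
            raise ValueError("downstream='shape_feature' requires a per-subject bai vector")
        bai = np.asarray(bai, dtype=float)
    fractions = [float(f) for f in fractions]
    if not all(0 < f < 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1)")

    scores = np.full((len(fractions), len(pet_volumes)), np.nan)
    dropped: set[int] = set()
    for i, pet in enumerate(pet_volumes):
        for k, frac in enumerate(fractions):
            try:
                voi = largest_component(threshold_pet_voi(pet, frac), connectivity)
                bass = compute_bass(measure_surface_and_volume(voi, method))
            except ValueError as exc:
                warnings.warn(f"subject {i} dropped from sweep (fraction {frac}): {exc}")
                dropped.add(i)
                break
            scores[k, i] = bass if downstream == "bass" else compute_shape_feature(bass, bai[i])
    keep = np.array([i not in dropped for i in range(len(pet_volumes))])
    if not keep.any():
        raise ValueError("all subjects failed the sweep")
    rows = [{"fraction": f, "auc": roc_auc(scores[k, keep], labels[keep]).auc, "n": int(keep.sum())}
            for k, f in enumerate(fractions)]
    table = pd.DataFrame(rows)
    best = float(table.loc[table["auc"].idxmax(), "fraction"])
    return ThresholdSweepResult(table=table, best_fraction=best, dropped_subjects=tuple(sorted(dropped)))


# ---------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class KmLogrankResult:
    """Two-stratum survival comparison at a score cutoff."""

    curves: dict
    chi2: float
    p_value: float
    hr: float
    hr_ci95: tuple[float, float]
    n_high: int
    n_low: int


def _risk_tables(time: np.ndarray, event: np.ndarray, high: np.ndarray):
    """Per-distinct-event-time risk/failure counts for both strata."""
    event_times = np.unique(time[event == 1])
    out = []
    for t in event_times:
        at_risk = time >= t
        fails = (time == t) & (event == 1)
        out.append(
            (
                int((at_risk & high).sum()),
                int((at_risk & ~high).sum()),
                int((fails & high).sum()),
                int((fails & ~high).sum()),
            )
        )
    return out


def _logrank_chi2(tables) -> float:
    o_minus_e, var = 0.0, 0.0
    for r1, r0, d1, d0 in tables:
        n, d = r1 + r0, d1 + d0
        if n == 0 or d == 0:
            continue
        o_minus_e += d1 - d * r1 / n
        if n > 1:
            var += d * (r1 / n) * (1 - r1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return o_minus_e**2 / var


def _cox_binary_breslow(tables, n_events_high: int) -> tuple[float, float]:
    """Newton maximization of the Breslow partial likelihood, binary covariate.

    l(b) = b * sum(d1) - sum_t d_t * log(r0_t + r1_t * e^b). Returns
    (beta_hat, se). Monotone-likelihood cases (all events in one stratum
    still at risk alongside the other) push beta to the +-30 cap.
    """
    beta = 0.0
    for _ in range(100):
        grad, hess = float(n_events_high), 0.0
        for r1, r0, d1, d0 in tables:
            d = d1 + d0
            if d == 0 or (r1 + r0) == 0:
                continue
            w = r1 * np.exp(beta)
            denom = r0 + w
            grad -= d * w / denom
            hess -= d * (w * r0) / denom**2
        if hess >= 0:  # flat likelihood (no informative risk sets)
            break
        step = -grad / hess
        beta = float(np.clip(beta + step, -_MAX_LOG_HR, _MAX_LOG_HR))
        if abs(step) < 1e-12 or abs(beta) >= _MAX_LOG_HR:
            break
    # observed information at the optimum
    info = 0.0
    for r1, r0, d1, d0 in tables:
        d = d1 + d0
        if d == 0 or (r1 + r0) == 0:
            continue
        w = r1 * np.exp(beta)
        info += d * (w * r0) / (r0 + w) ** 2
    se = np.sqrt(1.0 / info) if info > 0 else np.inf
    return beta, float(se)


def km_logrank(table: pd.DataFrame, score_name: str, cutoff: float) -> KmLogrankResult:
    """Compare conversion-free survival between score strata.

    Strata are ``score > cutoff`` ("high") vs ``score <= cutoff`` ("low").
    Returns Kaplan–Meier curves per stratum, the 1-df log-rank chi-square and
    p-value, and the hazard ratio (high vs low) with Wald 95% CI from the
    Breslow-tie partial likelihood. The HR is invariant to rescaling all
    times by a positive constant.
    """
    validate_cohort_table(table)
    if score_name not in table.columns:
        raise ValueError(f"no score column {score_name!r}")
    time = np.asarray(table["time_months"], dtype=float)
    event = np.asarray(table["event"], dtype=int)
    high = np.asarray(table[score_name], dtype=float) > cutoff
    if high.all() or (~high).all():
        raise ValueError("cutoff leaves an empty stratum")
    if event.sum() < 1:
        raise ValueError("no events in the cohort")

    tables = _risk_tables(time, event, high)
    chi2 = _logrank_chi2(tables)
    p = float(stats.chi2.sf(chi2, df=1))
    beta, se = _cox_binary_breslow(tables, int(event[high].sum()))
    hr = float(np.exp(beta))
    if np.isfinite(se):
        with np.errstate(over="ignore"):
            ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    else:
        ci = (0.0, float("inf"))

    curves = {}
    for name, sel in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=name)
        curves[name] = kmf.survival_function_
    return KmLogrankResult(
        curves=curves, chi2=float(chi2), p_value=p, hr=hr, hr_ci95=ci,
        n_high=int(high.sum()), n_low=int((~high).sum()),
    )


# ---------------------------------------------------------------------------
# Routine comparisons


def spearman(x, y) -> dict:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p)}


def compare_groups(table: pd.DataFrame, variable: str, group_col: str = "group") -> dict:
    """Baseline two-group comparison of one variable.

    Continuous variables get a Welch t-test; categorical variables (non-numeric
    dtype) get a Pearson chi-square on the group-by-category contingency table
    without continuity correction. Returns ``{"statistic", "p_value", "test"}``.
    """
    groups = np.unique(table[group_col])
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {list(groups)}")
    values = table[variable]
    if pd.api.types.is_numeric_dtype(values):
        a = values[table[group_col] == groups[0]].to_numpy(dtype=float)
        b = values[table[group_col] == groups[1]].to_numpy(dtype=float)
        if min(len(a), len(b)) < 2:
            raise ValueError("each group needs >= 2 observations")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return {"statistic": float(t), "p_value": float(p), "test": "welch_t"}
    contingency = pd.crosstab(table[group_col], values).to_numpy()
    chi2, p, _, _ = stats.chi2_contingency(contingency, correction=False)
    return {"statistic": float(chi2), "p_value": float(p), "test": "pearson_chi2"}
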