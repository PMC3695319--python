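"""Confound-adjusted age trajectories and the trajectory-shift test.

A region's per-subject GM values are first adjusted by removing the
group-specific mean and the variance explained by modelled confounds (TBV
and IQ scores — never age, which is the quantity of interest).  Quadratic
age curves are then fitted independently per group, and a nearest-neighbour
matching statistic asks whether the ASD curve is shifted along the age
axis: for each ASD subject, find the controls most similar in adjusted GM
volume ("most similar in brain development") and record how much older or
younger the best-matching control is.  A positive mean age difference means
the controls at the same developmental stage are older — a leftward shift
of the ASD trajectory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vbmtraj.glm import build_design, fit_voxelwise_glm

logger = logging.getLogger(__name__)

DEFAULT_CONFOUNDS = ("tbv", "fsiq", "viq", "piq")


@dataclass(frozen=True)
class AdjustedGM:
    """Per-subject GM values after removing group means and confound effects.

    Age effects and residual variance are retained.  Within each group the
    adjusted values are orthogonal to every modelled confound and have mean
    (numerically) zero.
    """

    subject_id: np.ndarray
    group: np.ndarray
    age: np.ndarray
    values: np.ndarray
    group_offset: dict
    site: str | int | None = None

    def group_sel(self, g: str) -> np.ndarray:
        return self.group == g

    def common_scale_values(self) -> np.ndarray:
        """Adjusted values with the group-specific means added back.

        ``values`` are centred within each group, which is the right view
        for plotting and per-group curve fits but not for comparing GM
        levels *across* groups: centring shifts the two groups by different
        constants.  This view removes only the confound contributions,
        leaving all subjects on one common GM scale — the scale on which
        "most similar in GM volume" is meaningful between groups.
        """
        offsets = np.array([self.group_offset[g] for g in self.group])
        return self.values + offsets


def adjust_gm(
    values: np.ndarray,
    cohort: pd.DataFrame,
    confounds: tuple[str, ...] = DEFAULT_CONFOUNDS,
    site: str | int | None = None,
) -> AdjustedGM:
    """Residualise one site's GM values on group means and confounds.

    ``confounds`` must not contain age terms: the adjustment removes the
    group-specific mean GM volume and the variance accounted for by the
    modelled confounds, leaving linear/quadratic age effects plus residual
    variance — the quantity plotted against age in trajectory figures.
    """
    banned = {"age", "age2"} & set(confounds)
    if banned:
        raise ValueError(
            f"confounds must not include age terms {sorted(banned)}: "
            "adjustment must retain age effects"
        )
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) != len(cohort):
        raise ValueError("values must be one number per cohort subject")
    design = build_design(cohort, covariates=tuple(confounds))
    X = design.matrix
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    # covariate columns are orthogonal to the indicators, so each group's
    # indicator coefficient is that group's mean GM level
    group_offset = {
        g: float(beta[design.column_index(f"group_{g}")]) for g in design.groups
    }
    return AdjustedGM(
        subject_id=cohort["subject_id"].to_numpy(),
        group=cohort["group"].to_numpy(),
        age=cohort["age"].to_numpy(dtype=float),
        values=resid,
        group_offset=group_offset,
        site=site,
    )


@dataclass(frozen=True)
class GroupCurve:
    """One group's fitted quadratic ``y = b0 + b1 age + b2 age^2``.

    ``peak_age = -b1/(2 b2)`` is reported only for inverted-U fits
    (``b2 < 0``); U-shaped fits (``b2 > 0``) report the trough age instead.
    """

    beta0: float
    beta1: float
    beta2: float
    n: int
    r2: float
    peak_age: float | None
    trough_age: float | None

    def predict(self, age: np.ndarray | float) -> np.ndarray | float:
        age = np.asarray(age, dtype=float)
        return self.beta0 + self.beta1 * age + self.beta2 * age**2


@dataclass(frozen=True)
class TrajectoryFit:
    """Independent per-group quadratic fits of adjusted GM on age."""

    curves: dict[str, GroupCurve]
    site: str | int | None = None

    @property
    def peak_shift(self) -> float | None:
        """``peak_age(CTRL) - peak_age(ASD)`` when both peaks exist."""
        a, c = self.curves.get("ASD"), self.curves.get("CTRL")
        if a and c and a.peak_age is not None and c.peak_age is not None:
            return c.peak_age - a.peak_age
        return None


def fit_group_trajectory(adj: AdjustedGM) -> TrajectoryFit:
    """Fit the second-order age regression independently to each group."""
    curves: dict[str, GroupCurve] = {}
    for g in sorted(np.unique(adj.group)):
        sel = adj.group_sel(g)
        if sel.sum() < 3:
            raise ValueError(
                f"group {g!r} has {int(sel.sum())} subjects; "
                "a quadratic needs at least 3"
            )
        age, y = adj.age[sel], adj.values[sel]
        X = np.column_stack([np.ones(sel.sum()), age, age**2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / tss if tss > 0 else float("nan")
        b0, b1, b2 = (float(b) for b in beta)
        extremum = -b1 / (2.0 * b2) if b2 != 0 else None
        curves[g] = GroupCurve(
            beta0=b0,
            beta1=b1,
            beta2=b2,
            n=int(sel.sum()),
            r2=r2,
            peak_age=extremum if b2 < 0 else None,
            trough_age=extremum if b2 > 0 else None,
        )
    return TrajectoryFit(curves=curves, site=adj.site)


def one_sample_t(diffs: np.ndarray) -> tuple[float, int, float]:
    """One-sample t-test of the mean against zero (two-sided).

    Degenerate zero-variance inputs return ``t = 0, p = 1`` when the mean is
    also zero and ``t = +/-inf, p = 0`` (with a warning) otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("one-sample t-test needs at least 2 observations")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        warnings.warn(
            "zero variance with nonzero mean: t is infinite", UserWarning, stacklevel=2
        )
        return float(np.sign(mean) * np.inf), df, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


@dataclass(frozen=True)
class ShiftTestResult:
    """Matched age differences and their one-sample test.

    ``deltas[i] = age(matched control) - age(ASD subject i)`` in years; a
    positive mean indicates the controls at the same developmental stage are
    older, i.e. a leftward shift of the trajectory in ASD.  ``direction`` is
    ``"none"`` when the test is not significant at ``alpha``.
    """

    deltas: np.ndarray
    matched_index: np.ndarray
    mean_delta: float
    t: float
    df: int
    p: float
    direction: str
    k: int
    site: str | int | None = None


def shift_test(
    adj: AdjustedGM,
    k: int = 5,
    selection: str = "min_age",
    alpha: float = 0.05,
    test_group: str = "ASD",
    ref_group: str = "CTRL",
    match_scale: str = "common",
) -> ShiftTestResult:
    """Nearest-neighbour test for a left/rightward trajectory shift.

    For each subject of ``test_group``: rank the ``ref_group`` subjects by
    absolute difference in adjusted GM, keep the ``k`` most similar, and
    take the signed age difference with minimum absolute value among them
    (``selection="min_age"``; ``"min_gm"`` instead takes the single most
    similar subject in GM).  The per-subject differences are then tested
    against zero with a one-sample t-test.  Ties in GM similarity and in age
    distance resolve to the smaller subject index, making the statistic
    deterministic.

    ``match_scale="common"`` (default) matches on confound-adjusted values
    with the group means retained, so "similar in GM volume" compares both
    groups on one scale; ``"centered"`` matches on the group-mean-removed
    values, which introduces an arbitrary vertical offset between the
    groups and is kept only for comparison.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if selection not in ("min_age", "min_gm"):
        raise ValueError("selection must be 'min_age' or 'min_gm'")
    if match_scale not in ("common", "centered"):
        raise ValueError("match_scale must be 'common' or 'centered'")
    test_sel = adj.group_sel(test_group)
    ref_sel = adj.group_sel(ref_group)
    n_test, n_ref = int(test_sel.sum()), int(ref_sel.sum())
    if n_test == 0 or n_ref == 0:
        raise ValueError("both groups must be non-empty")
    if k > n_ref:
        warnings.warn(
            f"k={k} exceeds {n_ref} available {ref_group} subjects; clipped",
            UserWarning,
            stacklevel=2,
        )
        k = n_ref

    gm = adj.common_scale_values() if match_scale == "common" else adj.values
    gm_test, age_test = gm[test_sel], adj.age[test_sel]
    gm_ref, age_ref = gm[ref_sel], adj.age[ref_sel]
    ref_rows = np.flatnonzero(ref_sel)

    deltas = np.empty(n_test)
    matched = np.empty(n_test, dtype=int)
    for i in range(n_test):
        order = np.argsort(np.abs(gm_ref - gm_test[i]), kind="stable")
        candidates = order[:k]
        if selection == "min_gm":
            j = candidates[0]
        else:
            age_dist = np.abs(age_ref[candidates] - age_test[i])
            j = candidates[int(np.argsort(age_dist, kind="stable")[0])]
        deltas[i] = age_ref[j] - age_test[i]
        matched[i] = ref_rows[j]

    mean_delta = float(deltas.mean())
    if n_test >= 2:
        t, df, p = one_sample_t(deltas)
    else:  # a single test subject carries no variance information
        t, df, p = float("nan"), 0, float("nan")
    if not np.isfinite(p) or p >= alpha or mean_delta == 0.0:
        direction = "none"
    else:
        direction = "leftward" if mean_delta > 0 else "rightward"
    return ShiftTestResult(
        deltas=deltas,
        matched_index=matched,
        mean_delta=mean_delta,
        t=t,
        df=df,
        p=p,
        direction=direction,
        k=k,
        site=adj.site,
    )


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cohen's d: mean difference over the pooled (n-1 weighted) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        warnings.warn("pooled SD is zero; d undefined", UserWarning, stacklevel=2)
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class AncovaResult:
    """Nested-model F-test of the group factor in a global-volume ANCOVA."""

    F: float
    p: float
    df_num: int
    df_den: int


def global_volume_ancova(
    volume: np.ndarray,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "age2", "fsiq", "viq", "piq"),
) -> AncovaResult:
    """Test a group effect on a global volume controlling for covariates.

    Compares the model with separate group means (plus grand-mean-centred
    covariates) to the one with a single intercept, via the residual
    sum-of-squares F-ratio.  Singular covariate blocks are handled by
    pseudoinverse fitting with the rank reflected in the degrees of freedom.
    """
    y = np.asarray(volume, dtype=float)
    if len(y) != len(cohort):
        raise ValueError("volume must have one value per cohort subject")
    groups = pd.unique(cohort["group"])
    for g in groups:
        if (cohort["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")

    full = build_design(cohort, covariates=covariates, per_group_interactions=False)
    fit_full = fit_voxelwise_glm(y[:, None], full)

    cov_cols = [i for i, name in enumerate(full.names) if not name.startswith("group_")]
    X_red = np.column_stack(
        [np.ones(len(cohort))] + [full.matrix[:, i] for i in cov_cols]
    )
    beta_red = np.linalg.pinv(X_red) @ y
    rss_red = float(np.sum((y - X_red @ beta_red) ** 2))
    rank_red = int(np.linalg.matrix_rank(X_red))

    rss_full = float(fit_full.rss[0])
    df_num = full.rank - rank_red
    df_den = fit_full.df_resid
    if df_num <= 0:
        raise ValueError("group factor adds no rank to the design")
    F = ((rss_red - rss_full) / df_num) / (rss_full / df_den) if rss_full > 0 else (
        float("inf") if rss_red > rss_full else 0.0
    )
    p = float(stats.f.sf(F, df_num, df_den))
    return AncovaResult(F=float(F), p=p, df_num=df_num, df_den=df_den)
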