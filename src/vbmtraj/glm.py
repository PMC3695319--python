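"""Voxel-wise general linear models for second-level VBM analyses.

Design matrices follow the "mean-corrected by group interactions"
convention: every covariate (age, age squared, total brain volume, the IQ
scores) enters once per group, mean-centred within that group and zero
elsewhere.  Centring makes each covariate column orthogonal to every group
indicator, so covariate effects explain variance beyond the group means and
group comparisons are unaffected by covariate offsets.

Fitting is massively univariate ordinary least squares over all sites at
once; contrasts are formed from the shared ``(X'X)^-`` so a whole-brain
F or t map costs one matrix product.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from vbmtraj.simulate import GMDataset

logger = logging.getLogger(__name__)

#: full covariate set of the standard group x age ANCOVA
DEFAULT_COVARIATES = ("age", "age2", "tbv", "fsiq", "viq", "piq")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _covariate_values(cohort: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a covariate column; ``age2`` is raw age in years, squared."""
    if name == "age2":
        return cohort["age"].to_numpy(dtype=float) ** 2
    if name not in cohort.columns:
        raise ValueError(f"covariate {name!r} not present in cohort table")
    return cohort[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class DesignMatrix:
    """Named design matrix with one indicator per group and covariate columns.

    With ``per_group_interactions`` each covariate contributes one column per
    group (centred within the group, zero elsewhere); otherwise a single
    grand-mean-centred column.  ``rank`` is the numerical rank; rank-deficient
    designs (e.g. a covariate constant within a group) are fitted via
    pseudoinverse downstream.
    """

    matrix: np.ndarray
    names: tuple[str, ...]
    groups: tuple[str, ...]
    group_labels: np.ndarray
    rank: int = field(default=0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValueError(f"design has no column {name!r}") from None


def build_design(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    per_group_interactions: bool = True,
) -> DesignMatrix:
    """Build the group + covariate design for a cohort.

    Group indicator columns come first (groups in sorted label order), then
    covariate columns in the order given.  Covariate-by-group columns are
    exactly orthogonal to all indicator columns by construction.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    group_labels = cohort["group"].to_numpy()
    groups = tuple(sorted(pd.unique(group_labels)))
    for g in groups:
        if np.sum(group_labels == g) < 1:
            raise ValueError(f"group {g!r} is empty")

    columns: list[np.ndarray] = []
    names: list[str] = []
    for g in groups:
        columns.append((group_labels == g).astype(float))
        names.append(f"group_{g}")

    for cov in covariates:
        values = _covariate_values(cohort, cov)
        if per_group_interactions:
            for g in groups:
                sel = group_labels == g
                col = np.zeros(len(cohort))
                centred = values[sel] - values[sel].mean()
                if np.allclose(centred, 0.0):
                    warnings.warn(
                        f"covariate {cov!r} is constant within group {g!r}; "
                        "its column is all-zero and the design is rank deficient",
                        UserWarning,
                        stacklevel=2,
                    )
                    centred = np.zeros(sel.sum())
                col[sel] = centred
                columns.append(col)
                names.append(f"{cov}_{g}")
        else:
            centred = values - values.mean()
            if np.allclose(centred, 0.0):
                warnings.warn(
                    f"covariate {cov!r} is constant; its column is all-zero",
                    UserWarning,
                    stacklevel=2,
                )
                centred = np.zeros(len(cohort))
            columns.append(centred)
            names.append(cov)

    X = np.column_stack(columns)
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        logger.info("design is rank deficient: rank %d < %d columns", rank, X.shape[1])
    return DesignMatrix(
        matrix=X,
        names=tuple(names),
        groups=groups,
        group_labels=group_labels,
        rank=rank,
    )


@dataclass(frozen=True)
class GLMFit:
    """Per-site least-squares solution of one design.

    ``beta`` is regressors x sites; ``rss`` the residual sum of squares per
    site; ``df_resid = n - rank(X)``.  ``xtx_pinv`` caches ``(X'X)^-`` for
    contrast standard errors.
    """

    design: DesignMatrix
    beta: np.ndarray
    rss: np.ndarray
    df_resid: int
    xtx_pinv: np.ndarray

    @property
    def sigma2(self) -> np.ndarray:
        """Residual variance estimate per site."""
        return self.rss / self.df_resid


def fit_voxelwise_glm(data: GMDataset | np.ndarray, design: DesignMatrix) -> GLMFit:
    """Fit ordinary least squares at every site of ``data``.

    Rank-deficient designs are solved with the Moore–Penrose pseudoinverse
    (minimum-norm solution); ``df_resid`` uses the design rank, not the
    column count.
    """
    Y = data.values if isinstance(data, GMDataset) else np.asarray(data, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"data has {Y.shape[0]} rows but design has {X.shape[0]}"
        )
    df_resid = X.shape[0] - design.rank
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom: n <= rank(design)")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    return GLMFit(
        design=design,
        beta=beta,
        rss=rss,
        df_resid=df_resid,
        xtx_pinv=np.linalg.pinv(X.T @ X),
    )


def f_contrast(fit: GLMFit, contrast: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """General F-test of ``C beta = 0`` at every site.

    ``contrast`` is a q x p matrix.  The statistic equals the nested-model
    comparison ``((RSS_r - RSS_f)/q) / (RSS_f/df_f)`` of the model with and
    without the constraint.
    """
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    if C.shape[1] != fit.design.p:
        raise ValueError("contrast has wrong number of columns")
    q = C.shape[0]
    A = C @ fit.beta  # q x sites
    M = C @ fit.xtx_pinv @ C.T
    quad = np.einsum("qs,qs->s", A, np.linalg.pinv(M) @ A)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (quad / q) / fit.sigma2
    # perfect fits: zero residual variance
    F = np.where(fit.rss == 0, np.where(quad > 0, np.inf, 0.0), F)
    p = stats.f.sf(F, q, fit.df_resid)
    return F, p


def f_contrast_differential_age(fit: GLMFit) -> tuple[np.ndarray, np.ndarray]:
    """F-test that the groups' (age, age squared) coefficients differ.

    Tests equality across groups of the per-group linear and quadratic age
    coefficients jointly — the differential-regression contrast asking
    whether the GM-on-age growth curves differ between groups in their
    linear, quadratic or compound age effects.
    """
    design = fit.design
    rows = []
    for cov in ("age", "age2"):
        cols = []
        for g in design.groups:
            name = f"{cov}_{g}"
            if name not in design.names:
                raise ValueError(
                    f"design lacks per-group column {name!r}; build it with "
                    "covariates including 'age' and 'age2' and "
                    "per_group_interactions=True"
                )
            cols.append(design.column_index(name))
        for other in cols[1:]:
            row = np.zeros(design.p)
            row[cols[0]] = 1.0
            row[other] = -1.0
            rows.append(row)
    return f_contrast(fit, np.vstack(rows))


def contrast_estimate(
    fit: GLMFit, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site contrast estimate ``c'beta`` and its standard error."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (fit.design.p,):
        raise ValueError(
            f"contrast weights must have length {fit.design.p}, got {w.shape}"
        )
    est = w @ fit.beta
    var_scale = float(w @ fit.xtx_pinv @ w)
    se = np.sqrt(var_scale * fit.sigma2)
    return est, se


def t_contrast(fit: GLMFit, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t-test of a single linear contrast at every site (two-sided p)."""
    w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise ValueError("contrast weights are all zero")
    est, se = contrast_estimate(fit, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    degenerate = se == 0
    if np.any(degenerate):
        warnings.warn(
            "zero-variance contrast at some sites; statistics undefined there",
            UserWarning,
            stacklevel=2,
        )
        t = np.where(degenerate, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
    return t, p


def fdr_threshold(
    pvals: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up FDR control.

    Returns the boolean significance mask (same shape as ``pvals``) and the
    adaptive p-threshold actually applied (0 when nothing survives).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(p.shape, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0]
    threshold = float(p.ravel()[reject].max()) if reject.any() else 0.0
    return reject.reshape(p.shape), threshold


@dataclass(frozen=True)
class Cluster:
    """A connected suprathreshold component on the voxel grid."""

    indices: np.ndarray  # k x 3 voxel coordinates
    extent: int
    peak_ijk: tuple[int, int, int]
    peak_stat: float


def find_clusters(
    mask: np.ndarray,
    min_extent: int = 100,
    connectivity: int = 18,
    stat_map: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of a 3-D mask, dropping those below ``min_extent``.

    ``connectivity`` is the voxel neighbourhood (6 faces, 18 faces+edges,
    26 faces+edges+corners).  Peaks are taken from ``stat_map`` (ties and a
    missing map fall back to the first voxel in scan order); clusters are
    returned sorted by peak statistic, then extent, descending.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D voxel grid")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_labels = ndimage.label(mask, structure=structure)
    clusters = []
    for lab in range(1, n_labels + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_extent:
            continue
        if stat_map is not None:
            vals = stat_map[tuple(coords.T)]
            peak_row = int(np.argmax(vals))
            peak_stat = float(vals[peak_row])
        else:
            peak_row, peak_stat = 0, float("nan")
        clusters.append(
            Cluster(
                indices=coords,
                extent=len(coords),
                peak_ijk=tuple(int(v) for v in coords[peak_row]),
                peak_stat=peak_stat,
            )
        )
    clusters.sort(
        key=lambda c: (
            -(c.peak_stat if np.isfinite(c.peak_stat) else -np.inf),
            -c.extent,
        )
    )
    return clusters


def peak_table(clusters: list[Cluster], affine: np.ndarray) -> pd.DataFrame:
    """Tabulate cluster peaks in mm coordinates via the voxel-to-mm affine.

    Rows are sorted by peak statistic descending and carry a formatted
    ``"(x, y, z)"`` mm triple alongside the numeric coordinates.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")
    rows = []
    for c in clusters:
        ijk1 = np.array([*c.peak_ijk, 1.0])
        x, y, z = (affine @ ijk1)[:3]
        rows.append(
            {
                "x_mm": x,
                "y_mm": y,
                "z_mm": z,
                "peak_mm": f"({x:g}, {y:g}, {z:g})",
                "peak_stat": c.peak_stat,
                "extent": c.extent,
            }
        )
    table = pd.DataFrame(
        rows, columns=["x_mm", "y_mm", "z_mm", "peak_mm", "peak_stat", "extent"]
    )
    if len(table):
        table = table.sort_values(
            "peak_stat", ascending=False, kind="stable"
        ).reset_index(drop=True)
    return table
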