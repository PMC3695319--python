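"""Synthetic cohorts and modulated grey-matter data with known structure.

The generators in this module produce data with the statistical structure
the downstream analyses assume: two groups of male subjects spanning
childhood to middle adulthood, regional GM volumes following group-specific
quadratic (inverted-U) age trajectories whose peak age may be shifted
between groups, additive confound effects (total brain volume and three IQ
scores), i.i.d. Gaussian voxel noise and Gaussian spatial smoothing.

Every generator is a pure function of its arguments including ``seed``:
the same call twice yields byte-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

GROUPS = ("ASD", "CTRL")

#: multiply a FWHM by this to get the Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: covariate columns a cohort table always carries
COVARIATE_COLUMNS = ("fsiq", "viq", "piq", "tbv")


@dataclass(frozen=True)
class DemographicParams:
    """Distribution settings for :func:`generate_cohort`.

    Ages are drawn from normal distributions truncated to the requested age
    range.  By default the two groups share one age distribution (its mean
    and spread pooled from a typical cross-sectional ASD/control morphometry
    sample) — the groups are age-matched, as such studies require; per-group
    means/SDs can be set to emulate demographic mismatch.  IQ scores and
    total brain volume (TBV, ml) are likewise drawn from the same
    distribution in both groups by default; ``piq_asd_offset`` can introduce
    the lower performance IQ often seen in ASD samples.  ADOS-G total scores
    (symptom severity) are generated for ASD subjects only.
    """

    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 19.8, "CTRL": 19.8}
    )
    age_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 8.8, "CTRL": 8.8}
    )
    fsiq_mean: float = 110.0
    fsiq_sd: float = 14.5
    viq_mean: float = 107.8
    viq_sd: float = 17.7
    piq_mean: float = 104.8
    piq_sd: float = 14.2
    piq_asd_offset: float = 0.0
    tbv_mean: float = 1373.6
    tbv_sd: float = 126.3
    scanner_b_fraction: float = 10.0 / 98.0
    ados_mean: float = 12.0
    ados_sd: float = 3.5


@dataclass(frozen=True)
class GroupTrajectory:
    """One group's quadratic age trajectory ``y = a - c (age - mu)^2``.

    ``curvature`` c > 0 encodes an inverted U peaking at ``peak_age`` mu with
    value ``amplitude`` a; c < 0 a U shape with a trough; c = 0 a flat
    (age-independent) mean.  The equivalent raw polynomial
    ``y = b0 + b1 age + b2 age^2`` has ``b2 = -c``, ``b1 = 2 c mu`` and
    ``b0 = a - c mu^2``.
    """

    amplitude: float
    curvature: float
    peak_age: float

    def poly_coeffs(self) -> tuple[float, float, float]:
        """Return ``(b0, b1, b2)`` of the equivalent raw quadratic."""
        a, c, mu = self.amplitude, self.curvature, self.peak_age
        return (a - c * mu * mu, 2.0 * c * mu, -c)

    def value(self, age: np.ndarray | float) -> np.ndarray | float:
        age = np.asarray(age, dtype=float)
        d = age - self.peak_age
        return self.amplitude - self.curvature * d * d


@dataclass(frozen=True)
class TrajectoryParams:
    """Generative model for one region/voxel population.

    ``y_i = a_g - c_g (age_i - mu_g)^2 + sum_k lambda_k cov_ik + eps_i``
    with ``eps ~ Normal(0, noise_sd^2)`` and g the subject's group.

    ``confound_slopes`` maps covariate column names (``tbv``, ``fsiq``,
    ``viq``, ``piq``) to additive slopes lambda_k in GM units per covariate
    unit.  ``shift`` is ``peak_age(CTRL) - peak_age(ASD)``; a positive shift
    means the ASD curve peaks earlier, i.e. is shifted leftward along the
    age axis.
    """

    groups: Mapping[str, GroupTrajectory]
    confound_slopes: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        unknown = set(self.confound_slopes) - set(COVARIATE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown confound columns: {sorted(unknown)}")

    @property
    def shift(self) -> float:
        """Peak-age shift delta = mu_CTRL - mu_ASD in years."""
        return self.groups["CTRL"].peak_age - self.groups["ASD"].peak_age

    @classmethod
    def shifted(
        cls,
        amplitude: float,
        curvature: float,
        peak_age_ctrl: float,
        delta: float,
        noise_sd: float = 0.0,
        confound_slopes: Mapping[str, float] | None = None,
    ) -> "TrajectoryParams":
        """Identical trajectories except the ASD peak sits ``delta`` years earlier."""
        return cls(
            groups={
                "ASD": GroupTrajectory(amplitude, curvature, peak_age_ctrl - delta),
                "CTRL": GroupTrajectory(amplitude, curvature, peak_age_ctrl),
            },
            confound_slopes=dict(confound_slopes or {}),
            noise_sd=noise_sd,
        )

    @classmethod
    def null(
        cls,
        amplitude: float,
        curvature: float,
        peak_age: float,
        noise_sd: float = 0.0,
        confound_slopes: Mapping[str, float] | None = None,
    ) -> "TrajectoryParams":
        """Both groups share one trajectory: no group effect of any kind."""
        return cls.shifted(amplitude, curvature, peak_age, 0.0, noise_sd, confound_slopes)

    def mean_values(self, cohort: pd.DataFrame) -> np.ndarray:
        """Noise-free model value for every subject of ``cohort``."""
        y = np.empty(len(cohort), dtype=float)
        ages = cohort["age"].to_numpy(dtype=float)
        for g, traj in self.groups.items():
            sel = (cohort["group"] == g).to_numpy()
            y[sel] = traj.value(ages[sel])
        for name, lam in self.confound_slopes.items():
            y += lam * cohort[name].to_numpy(dtype=float)
        return y


@dataclass(frozen=True)
class GMDataset:
    """Subjects x sites matrix of modulated GM values plus grid geometry.

    ``kind`` is ``"voxel_grid"`` (sites are voxels of a 3-D grid, and
    ``grid_dims``/``voxel_size``/``affine`` describe the geometry) or
    ``"region"`` (sites are scalar regional summaries, no geometry).
    Voxel sites are stored flattened in C order.
    """

    values: np.ndarray
    kind: str = "region"
    grid_dims: tuple[int, int, int] | None = None
    voxel_size: tuple[float, float, float] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a subjects x sites matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("GM values must all be finite")
        if self.kind not in ("voxel_grid", "region"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if self.kind == "voxel_grid":
            if self.grid_dims is None:
                raise ValueError("voxel_grid dataset requires grid_dims")
            if values.shape[1] != int(np.prod(self.grid_dims)):
                raise ValueError("site count does not match grid_dims product")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def site_map(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a per-site vector onto the 3-D grid (voxel_grid only)."""
        if self.kind != "voxel_grid":
            raise ValueError("site_map only applies to voxel_grid datasets")
        return np.asarray(flat).reshape(self.grid_dims)


def default_affine(
    grid_dims: Sequence[int], voxel_size: Sequence[float]
) -> np.ndarray:
    """MNI-style affine: axes scaled in mm, origin at the grid centre."""
    affine = np.eye(4)
    for ax in range(3):
        affine[ax, ax] = voxel_size[ax]
        affine[ax, 3] = -voxel_size[ax] * (grid_dims[ax] - 1) / 2.0
    return affine


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def smooth_volume(
    volume: np.ndarray,
    fwhm: float,
    voxel_size: Sequence[float] = (2.0, 2.0, 2.0),
) -> np.ndarray:
    """Gaussian-smooth one 3-D volume at the given FWHM (mm).

    Uses a wrap-around boundary, which conserves the image sum exactly —
    the natural choice for modulated data where total volume is meaningful.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = [fwhm * FWHM_TO_SIGMA / vs for vs in voxel_size]
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma_vox, mode="wrap")


def generate_cohort(
    n_asd: int,
    n_ctrl: int,
    age_range: tuple[float, float] = (8.0, 50.0),
    demo_params: DemographicParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a seeded synthetic subject table.

    Returns a DataFrame with columns ``subject_id``, ``group``, ``age``,
    ``fsiq``, ``viq``, ``piq``, ``tbv``, ``scanner`` and ``ados`` (ADOS-G
    total, NaN for controls).  Group sizes are exactly as requested; ages
    lie within ``age_range``.
    """
    if n_asd < 0 or n_ctrl < 0:
        raise ValueError("group sizes must be non-negative")
    lo, hi = float(age_range[0]), float(age_range[1])
    if not lo < hi:
        raise ValueError(f"age_range min must be < max, got {age_range}")
    demo = demo_params or DemographicParams()
    rng = np.random.default_rng(seed)

    frames = []
    for g, n in (("ASD", n_asd), ("CTRL", n_ctrl)):
        age = _truncated_normal(rng, demo.age_mean[g], demo.age_sd[g], lo, hi, n)
        piq_mean = demo.piq_mean + (demo.piq_asd_offset if g == "ASD" else 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{g}{i + 1:03d}" for i in range(n)],
                    "group": g,
                    "age": age,
                    "fsiq": rng.normal(demo.fsiq_mean, demo.fsiq_sd, n),
                    "viq": rng.normal(demo.viq_mean, demo.viq_sd, n),
                    "piq": rng.normal(piq_mean, demo.piq_sd, n),
                    "tbv": rng.normal(demo.tbv_mean, demo.tbv_sd, n),
                    "scanner": np.where(
                        rng.random(n) < demo.scanner_b_fraction, "B", "A"
                    ),
                    "ados": (
                        rng.normal(demo.ados_mean, demo.ados_sd, n)
                        if g == "ASD"
                        else np.full(n, np.nan)
                    ),
                }
            )
        )
    cohort = pd.concat(frames, ignore_index=True)
    logger.info(
        "generated cohort n_asd=%d n_ctrl=%d age_range=(%g, %g) seed=%d",
        n_asd, n_ctrl, lo, hi, seed,
    )
    return cohort


def simulate_regional_gm(
    cohort: pd.DataFrame,
    params: TrajectoryParams,
    seed: int = 0,
    n_sites: int = 1,
) -> GMDataset:
    """Simulate regional GM values for every cohort subject.

    Each of the ``n_sites`` sites is an independent realisation of the same
    generative trajectory model (fresh noise per site), which makes this the
    workhorse for calibration studies over many null sites.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(seed)
    mean = params.mean_values(cohort)
    noise = rng.normal(0.0, params.noise_sd, size=(len(cohort), n_sites))
    return GMDataset(values=mean[:, None] + noise, kind="region")


@dataclass(frozen=True)
class Blob:
    """A spherical region on the voxel grid with its own trajectory model."""

    name: str
    center: tuple[int, int, int]
    radius: float
    params: TrajectoryParams

    def mask(self, grid_dims: Sequence[int]) -> np.ndarray:
        for ax in range(3):
            if (
                self.center[ax] - self.radius < 0
                or self.center[ax] + self.radius > grid_dims[ax] - 1
            ):
                raise ValueError(
                    f"blob {self.name!r} (center {self.center}, radius "
                    f"{self.radius}) does not fit within grid {tuple(grid_dims)}"
                )
        grids = np.ogrid[tuple(slice(0, d) for d in grid_dims)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return dist2 <= self.radius**2


DEFAULT_BACKGROUND = TrajectoryParams.null(
    amplitude=5.0, curvature=0.004, peak_age=22.0, noise_sd=0.5
)


def simulate_gm_images(
    cohort: pd.DataFrame,
    blobs: Sequence[Blob],
    fwhm: float = 8.0,
    grid_dims: tuple[int, int, int] = (20, 20, 20),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    background: TrajectoryParams = DEFAULT_BACKGROUND,
    seed: int = 0,
) -> GMDataset:
    """Simulate per-subject modulated GM images on a small voxel grid.

    Voxels inside each blob follow that blob's trajectory model; everything
    else follows ``background`` (a no-group-difference model by default).
    Each subject's image is then convolved with a Gaussian kernel of the
    requested full width at half maximum.  Smoothing uses a wrap-around
    boundary so the image sum — the "modulated" total-volume semantics of
    VBM data — is conserved exactly.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(cohort)

    mean_site = np.tile(background.mean_values(cohort)[:, None], (1, int(np.prod(grid_dims))))
    sd_site = np.full(int(np.prod(grid_dims)), background.noise_sd)
    for blob in blobs:
        flat = blob.mask(grid_dims).ravel()
        mean_site[:, flat] = blob.params.mean_values(cohort)[:, None]
        sd_site[flat] = blob.params.noise_sd

    values = mean_site + rng.normal(0.0, 1.0, size=(n, mean_site.shape[1])) * sd_site
    if fwhm > 0:
        for i in range(n):
            values[i] = smooth_volume(
                values[i].reshape(grid_dims), fwhm, voxel_size
            ).ravel()

    return GMDataset(
        values=values,
        kind="voxel_grid",
        grid_dims=tuple(grid_dims),
        voxel_size=tuple(float(v) for v in voxel_size),
        affine=default_affine(grid_dims, voxel_size),
    )
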