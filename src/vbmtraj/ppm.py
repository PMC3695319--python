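"""Empirical-Bayes posterior probability maps (PPMs) for group differences.

Instead of asking whether a group difference is non-zero, the PPM asks with
what posterior probability the contrast exceeds an effect-size threshold
gamma interpreted as the background noise level.  A voxel is reported when
that probability passes a cut (0.99 by default), so the map simultaneously
quantifies confidence in the presence *and* the absence of differences.

The model is a single-level Normal–Normal shrinkage ("parametric empirical
Bayes") scheme: the true contrast at each site is a priori
``Normal(0, tau^2)`` with one global tau^2 moment-matched across sites, and
the observed estimate is ``c_hat ~ Normal(contrast, s^2)`` with the per-site
sampling variance from the GLM.  The posterior at each site is then
``Normal(w c_hat, w s^2)`` with shrinkage weight ``w = tau^2/(tau^2 + s^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from vbmtraj.glm import GLMFit, contrast_estimate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PPMConfig:
    """Effect-size threshold gamma and posterior-probability cut.

    ``gamma`` is in GM units; the string ``"auto"`` sets it to one prior
    standard deviation (sqrt of the moment-matched tau^2), the conventional
    reading of "background noise level".
    """

    gamma: float | str = "auto"
    pp_cut: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 < self.pp_cut < 1.0:
            raise ValueError("pp_cut must lie strictly between 0 and 1")
        if self.gamma != "auto":
            if not np.isfinite(self.gamma) or self.gamma < 0:
                raise ValueError("numeric gamma must be finite and >= 0")


@dataclass(frozen=True)
class PPMResult:
    """Per-site posterior summaries of a contrast.

    ``chat``/``se`` are the frequentist contrast estimate and its standard
    error; ``mean``/``sd`` the posterior moments after shrinkage toward the
    zero prior mean; ``pp`` the posterior probability that the contrast
    exceeds ``gamma``.  ``tau2`` and ``weights`` are the global prior
    variance and the per-site shrinkage weights.
    """

    chat: np.ndarray
    se: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    pp: np.ndarray
    tau2: float
    gamma: float
    weights: np.ndarray
    pp_cut: float


def estimate_prior(chat: np.ndarray, se: np.ndarray) -> float:
    """Moment-matched prior variance tau^2 of the contrast across sites.

    Marginally ``var(c_hat) = tau^2 + s^2``, so
    ``tau^2 = max(0, var(c_hat) - mean(s^2))`` with the prior mean fixed at
    zero (no group difference).  Floored at zero when the observed spread is
    entirely explained by sampling noise.
    """
    chat = np.asarray(chat, dtype=float)
    se = np.asarray(se, dtype=float)
    if chat.shape != se.shape:
        raise ValueError("chat and se must have the same shape")
    if chat.size < 2:
        raise ValueError("prior estimation needs at least 2 sites")
    tau2 = float(np.var(chat, ddof=1) - np.mean(se**2))
    if tau2 < 0:
        logger.info(
            "observed contrast spread below sampling noise; tau^2 floored at 0"
        )
        tau2 = 0.0
    return tau2


def posterior_probability_map(
    fit: GLMFit, weights: np.ndarray, config: PPMConfig | None = None
) -> PPMResult:
    """Posterior probability that a contrast exceeds gamma, at every site.

    ``weights`` is the contrast vector (e.g. control-minus-ASD group
    difference).  Degenerate sites with zero posterior sd get probability
    1 when the posterior mean clears gamma and 0 otherwise.
    """
    config = config or PPMConfig()
    chat, se = contrast_estimate(fit, weights)
    tau2 = estimate_prior(chat, se)
    gamma = float(np.sqrt(tau2)) if config.gamma == "auto" else float(config.gamma)

    s2 = se**2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(tau2 + s2 > 0, tau2 / (tau2 + s2), 0.0)
    mean = w * chat
    sd = np.sqrt(w) * se

    pp = np.empty_like(mean)
    ok = sd > 0
    pp[ok] = stats.norm.sf((gamma - mean[ok]) / sd[ok])
    degenerate = ~ok
    if np.any(degenerate):
        logger.info(
            "%d sites have zero posterior sd; probabilities set to 0/1 limits",
            int(degenerate.sum()),
        )
        pp[degenerate] = np.where(mean[degenerate] > gamma, 1.0, 0.0)

    return PPMResult(
        chat=chat,
        se=se,
        mean=mean,
        sd=sd,
        pp=pp,
        tau2=tau2,
        gamma=gamma,
        weights=w,
        pp_cut=config.pp_cut,
    )


def threshold_ppm(ppm: PPMResult, pp_cut: float | None = None) -> np.ndarray:
    """Boolean mask of sites whose posterior probability exceeds the cut."""
    cut = ppm.pp_cut if pp_cut is None else pp_cut
    return ppm.pp > cut
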