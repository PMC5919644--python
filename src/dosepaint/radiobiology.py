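"""Oxygen-dependent linear-quadratic (LQ) cell survival.

The survival fraction of cells irradiated with dose ``d`` at oxygen partial
pressure ``p`` is

    SF(d, p) = exp[-alpha_h * OER_alpha(p) * d - beta_h * (OER_beta(p) * d)**2]

where ``alpha_h = alpha / OERalpha_max`` and ``beta_h = beta / OERbeta_max**2``
are the radiosensitivities under fully hypoxic (anoxic) conditions and the
oxygen enhancement ratios follow the Wouters-Brown form

    OER(p) = (k + p * OER_max) / (p + k).

At ``p = 0`` the OER is 1 (maximum radioresistance); at high ``p`` it
saturates at ``OER_max`` and the plain oxic LQ model ``exp(-alpha d -
beta d^2)`` is recovered.

All functions broadcast over numpy arrays.  Survivor counts returned here are
*expected* (real-valued); stochastic integerized killing lives in
:mod:`dosepaint.tumor_model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: pO2 used to evaluate the fully oxic limit numerically (mmHg).  At this
#: tension the OERs are within 1e-3 of their maxima for k ~ 3 mmHg.
FULLY_OXIC_PO2 = 1.0e6


@dataclass(frozen=True)
class LQParams:
    """LQ radiosensitivity under fully oxic conditions.

    alpha : Gy^-1, linear coefficient (head-and-neck default 0.35)
    beta : Gy^-2, quadratic coefficient (default 0.035)
    sigma_alpha : Gy^-1, population SD of alpha for inter-patient variation
    """

    alpha: float = 0.35
    beta: float = 0.035
    sigma_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.sigma_alpha < 0:
            raise ValueError(f"sigma_alpha must be >= 0, got {self.sigma_alpha}")

    def with_alpha(self, alpha: float) -> "LQParams":
        """Copy with a different alpha (per-patient radiosensitivity draw)."""
        return LQParams(alpha=alpha, beta=self.beta, sigma_alpha=self.sigma_alpha)


@dataclass(frozen=True)
class OERParams:
    """Oxygen enhancement ratio parameters (Wouters-Brown form).

    oer_alpha_max, oer_beta_max : dimensionless maxima reached under aerobic
        conditions (defaults 2.5 and 3.0)
    k : mmHg, slope parameter of the OER curve (default 3.28)
    """

    oer_alpha_max: float = 2.5
    oer_beta_max: float = 3.0
    k: float = 3.28

    def __post_init__(self) -> None:
        if self.oer_alpha_max < 1 or self.oer_beta_max < 1:
            raise ValueError("OER maxima must be >= 1")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")


def oer(p, oer_max: float, k: float):
    """Oxygen enhancement ratio ``(k + p*oer_max) / (p + k)``.

    Parameters
    ----------
    p : array_like
        Oxygen partial pressure, mmHg (>= 0).
    oer_max : float
        Aerobic saturation value (>= 1).
    k : float
        Slope parameter, mmHg (> 0).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    if oer_max < 1:
        raise ValueError(f"oer_max must be >= 1, got {oer_max}")
    out = (k + p * oer_max) / (p + k)
    return out if out.ndim else float(out)


def lq_coefficients(p, lq: LQParams, oer_params: OERParams):
    """Effective LQ coefficients at oxygen tension ``p``.

    Returns ``(a, b)`` such that ``SF = exp(-a*d - b*d**2)`` with
    ``a = alpha_h * OER_alpha(p)`` and ``b = beta_h * OER_beta(p)**2``
    (the OER_beta factor multiplies the dose inside the square).
    """
    alpha_h = lq.alpha / oer_params.oer_alpha_max
    beta_h = lq.beta / oer_params.oer_beta_max**2
    a = alpha_h * oer(p, oer_params.oer_alpha_max, oer_params.k)
    b = beta_h * np.square(oer(p, oer_params.oer_beta_max, oer_params.k))
    return a, b


def survival_fraction(d, p, lq: LQParams, oer_params: OERParams):
    """Cell survival fraction after dose ``d`` (Gy) at oxygen tension ``p`` (mmHg).

    Broadcasts ``d`` against ``p``.  Monotone non-increasing in both the dose
    and the oxygenation.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    a, b = lq_coefficients(p, lq, oer_params)
    out = np.exp(-a * d - b * np.square(d))
    return out if out.ndim else float(out)


def voxel_survivors(viable, hist, d, lq: LQParams, oer_params: OERParams) -> float:
    """Expected surviving cells in one voxel with pO2 histogram ``hist``.

    The viable cells are partitioned over the 16 histogram bins by the bin
    weights; each sub-population is killed with the survival fraction at its
    bin pO2: ``sum_j viable * w_j * SF(d, p_j)``.
    """
    if viable < 0:
        raise ValueError("viable count must be >= 0")
    centers = np.asarray(hist.bin_centers, dtype=float)
    weights = np.asarray(hist.weights, dtype=float)
    if centers.shape != weights.shape:
        raise ValueError("histogram bin_centers and weights length mismatch")
    sf = survival_fraction(d, centers, lq, oer_params)
    return float(viable * np.sum(weights * sf))


def expected_survivors(viable, weights, doses, bin_centers, lq: LQParams,
                       oer_params: OERParams, alpha=None):
    """Vectorized expected survivors per voxel.

    Parameters
    ----------
    viable : (..., N) array
        Viable cells per voxel (leading axes broadcast, e.g. a patient batch).
    weights : (..., N, J) array
        pO2-histogram weights per voxel.
    doses : (N,) array
        Dose per voxel, Gy.
    bin_centers : (J,) array
        Histogram bin pO2 values, mmHg.
    alpha : optional array broadcastable to the leading axes of ``viable``
        Per-patient alpha overriding ``lq.alpha`` (beta stays fixed).

    Returns
    -------
    (..., N) array of expected surviving cells.
    """
    a, b = lq_coefficients(bin_centers, lq, oer_params)  # (J,)
    if alpha is not None:
        scale = np.asarray(alpha, dtype=float)[..., None, None] / lq.alpha
        a = a * scale  # alpha_h scales linearly with alpha
    d = np.asarray(doses, dtype=float)[..., :, None]  # (N, 1)
    sf = np.exp(-a * d - b * d * d)  # (..., N, J)
    return np.asarray(viable) * np.sum(weights * sf, axis=-1)


def total_survivors(viable, weights, doses, bin_centers, lq: LQParams,
                    oer_params: OERParams) -> float:
    """Expected surviving cells summed over all tumor voxels.

    ``viable``/``weights``/``doses`` are mask-flattened per-voxel arrays; this
    is the double sum over voxels and histogram bins that every objective
    function and treatment step consumes.
    """
    viable = np.asarray(viable, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if viable.shape[0] != doses.shape[0]:
        raise ValueError("dose plan and grid voxel counts differ")
    return float(np.sum(expected_survivors(viable, weights, doses, bin_centers,
                                           lq, oer_params)))
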