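"""Elementary rate laws shared by the community model.

All responses are dimensionless factors in [0, 1] that multiply maximal
rates: Monod saturation for substrate uptake/growth, a logistic pH
permissivity curve for acid inhibition of growth, and Hill transition
functions for environment-triggered phenotype switching.
"""

from __future__ import annotations

import numpy as np

__all__ = ["monod_factor", "ph_factor", "hill", "hill_response", "emergent_ph"]


def monod_factor(conc, k_m):
    """Saturating uptake factor ``conc / (conc + K_M)``.

    Parameters
    ----------
    conc : float or array
        Substrate concentration (mM), must be >= 0.
    k_m : float or array
        Half-saturation constant (mM), must be > 0.
    """
    conc = np.asarray(conc, dtype=float)
    k_m = np.asarray(k_m, dtype=float)
    if np.any(k_m <= 0):
        raise ValueError("K_M must be positive")
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    out = conc / (conc + k_m)
    return float(out) if out.ndim == 0 else out


def ph_factor(ph, ph_opt, ph_steep):
    """Logistic growth-permissivity factor, 0.5 at ``ph_opt``.

    Monotone increasing in pH: acid-sensitive subpopulations (large
    ``ph_steep``, high ``ph_opt``) are shut down below their optimum,
    acid-tolerant ones (low ``ph_opt``) are barely affected over the
    physiological range.
    """
    ph = np.asarray(ph, dtype=float)
    z = np.clip(ph_steep * (ph - ph_opt), -500.0, 500.0)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def hill(signal, theta, n_hill, direction="activating"):
    """Hill transition function of a nonnegative signal.

    ``activating``: s^n / (theta^n + s^n) -- high signal promotes.
    ``repressing``: theta^n / (theta^n + s^n) -- high signal blocks.
    Both equal 0.5 at ``signal == theta``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if n_hill < 1:
        raise ValueError("n_hill must be >= 1")
    s = np.asarray(signal, dtype=float)
    if np.any(s < 0):
        raise ValueError("signal must be nonnegative")
    # work with (s/theta)^n for numerical range safety
    ratio = (s / theta) ** n_hill
    if direction == "activating":
        out = ratio / (1.0 + ratio)
    elif direction == "repressing":
        out = 1.0 / (1.0 + ratio)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if out.ndim == 0 else out


def hill_response(signal, rule):
    """Evaluate a :class:`~gutswitch.community.TransitionRule`'s Hill curve."""
    return hill(signal, rule.theta, rule.n_hill, rule.direction)


def emergent_ph(acid_concs, acid_coeffs, base_ph, ph_floor):
    """pH of the culture as a linear acid-weighted drop from ``base_ph``.

    ``ph = clip(base_ph - sum_m coeff[m] * conc[m], ph_floor, base_ph)``

    The map is monotone non-increasing in every organic-acid
    concentration; coefficients (pH units per mM) are calibration
    targets of the community model.
    """
    drop = 0.0
    for met, coeff in acid_coeffs.items():
        drop += coeff * acid_concs.get(met, 0.0)
    return float(np.clip(base_ph - drop, ph_floor, base_ph))
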