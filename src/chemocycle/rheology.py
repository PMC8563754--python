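"""Blood rheology in microvessels (Pries–Secomb in-vitro viscosity law).

Apparent blood viscosity in a microvessel depends strongly on the vessel
diameter and the hematocrit (red-cell volume fraction).  The empirical
in-vitro law used here expresses the relative apparent viscosity as a
function of diameter ``D_v`` (µm) and hematocrit ``H``, anchored at the
reference hematocrit of 0.45.  The law is singular at D_v = 1.1 µm, below
which a red cell cannot pass; all functions reject that regime.

Note on symbols: the vessel diameter is called ``d_um`` (µm) throughout this
package to avoid any clash with the free-drug diffusivity ``D_diff``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mu_45", "xi_hematocrit", "relative_viscosity", "apparent_viscosity"]

#: Diameter (µm) at which the diameter correction (D/(D-1.1))^2 diverges.
SINGULAR_DIAMETER_UM = 1.1


def mu_45(d_um):
    """Relative apparent viscosity at the fixed hematocrit H = 0.45.

    Parameters
    ----------
    d_um : float or array
        Vessel diameter in µm, > 0.

    Returns
    -------
    float or ndarray
        mu_45 = 6 e^(-0.085 D) + 3.2 - 2.44 e^(-0.06 D^0.645),
        dimensionless; tends to 3.2 for large diameters.
    """
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("vessel diameter must be positive (µm)")
    out = 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    return out if out.ndim else float(out)


def xi_hematocrit(d_um):
    """Shape exponent xi(D) of the hematocrit dependence of viscosity."""
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("vessel diameter must be positive (µm)")
    frac = 1.0 / (1.0 + 1e-11 * d**12)
    out = (0.8 + np.exp(-0.075 * d)) * (-1.0 + frac) + frac
    return out if out.ndim else float(out)


def relative_viscosity(d_um, hematocrit):
    """Relative apparent viscosity mu_rel(D_v, H) of blood in a microvessel.

    Parameters
    ----------
    d_um : float or array
        Vessel diameter in µm; must exceed 1.1 µm.
    hematocrit : float or array
        Red-cell volume fraction in [0, 1).

    Returns
    -------
    float or ndarray
        mu_rel = [1 + (mu_45 - 1) * ((1-H)^xi - 1)/((1-0.45)^xi - 1)
                      * (D/(D-1.1))^2] * (D/(D-1.1))^2

    Notes
    -----
    At H = 0 the hematocrit bracket collapses and mu_rel = (D/(D-1.1))^2.
    For large D at H = 0.45 the value tends to mu_45 -> 3.2.
    """
    d = np.asarray(d_um, dtype=float)
    h = np.asarray(hematocrit, dtype=float)
    if np.any(d <= SINGULAR_DIAMETER_UM):
        raise ValueError(
            f"vessel diameter must exceed {SINGULAR_DIAMETER_UM} µm "
            "(viscosity law singular)"
        )
    if np.any((h < 0) | (h >= 1)):
        raise ValueError("hematocrit must lie in [0, 1)")
    m45 = np.asarray(mu_45(d))
    xi = np.asarray(xi_hematocrit(d))
    dcorr = (d / (d - SINGULAR_DIAMETER_UM)) ** 2
    hfac = ((1.0 - h) ** xi - 1.0) / ((1.0 - 0.45) ** xi - 1.0)
    out = (1.0 + (m45 - 1.0) * hfac * dcorr) * dcorr
    return out if out.ndim else float(out)


def apparent_viscosity(mu_plasma, mu_rel):
    """Apparent viscosity mu_app = mu_plasma * mu_rel (Pa·s)."""
    mp = np.asarray(mu_plasma, dtype=float)
    if np.any(mp <= 0):
        raise ValueError("plasma viscosity must be positive")
    out = mp * np.asarray(mu_rel, dtype=float)
    return out if out.ndim else float(out)
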