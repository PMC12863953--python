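"""Scale machinery for binary-trait evaluations.

Three scales coexist in a binary-trait evaluation:

* the **observed** 0/1 scale, on which the linear model estimates its
  variance components and breeding values;
* the **liability** scale of the threshold model, a latent standard
  normal axis cut at the threshold t = Phi^-1(1 - alpha) for a trait of
  prevalence alpha;
* the **probability** scale, the expected defect frequency among the
  offspring-equivalents of an animal, the most interpretable form for
  breeders.

The Dempster-Lerner relationship links heritabilities on the first two:

    h2_o = z^2 * h2_l / (alpha * (1 - alpha)),    z = phi(t)

and two alternative linear adjustments take observed-scale breeding
values to the liability scale before the probit map to probabilities:
a variance-heritability scaling based on the observed-scale residual
variance, and a threshold-density scaling that divides by the normal
ordinate at the threshold. Both adjustments are linear, so animal
rankings are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .containers import GEBVTable

__all__ = [
    "ScaleParams",
    "scale_params",
    "h2_liability_to_observed",
    "h2_observed_to_liability",
    "gebv_var_heritability_adjust",
    "gebv_threshold_density_adjust",
    "gebv_to_probability",
]


@dataclass(frozen=True)
class ScaleParams:
    """Threshold geometry for a trait of prevalence ``alpha``."""

    alpha: float
    t: float  # liability threshold Phi^-1(1 - alpha)
    z: float  # normal ordinate phi(t)


def scale_params(alpha: float) -> ScaleParams:
    """Threshold t = Phi^-1(1 - alpha) and ordinate z = phi(t)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {alpha}")
    t = float(norm.ppf(1.0 - alpha))
    return ScaleParams(alpha=alpha, t=t, z=float(norm.pdf(t)))


def h2_liability_to_observed(h2_l: float, alpha: float) -> float:
    """Dempster-Lerner conversion h2_o = z^2 h2_l / (alpha (1 - alpha)).

    Strictly contracts (z^2 < alpha(1-alpha) for all alpha), so the
    observed-scale heritability of a binary trait is always below its
    liability-scale value.
    """
    if not (0.0 < h2_l < 1.0):
        raise ValueError(f"h2_l must lie strictly in (0, 1), got {h2_l}")
    p = scale_params(alpha)
    h2_o = p.z**2 * h2_l / (alpha * (1.0 - alpha))
    if h2_o >= 1.0:
        raise ValueError(
            f"inconsistent inputs: converted h2_o = {h2_o:.3f} >= 1 "
            f"(h2_l={h2_l}, alpha={alpha})"
        )
    return h2_o


def h2_observed_to_liability(h2_o: float, alpha: float) -> float:
    """Exact inverse of :func:`h2_liability_to_observed`."""
    if not (0.0 < h2_o < 1.0):
        raise ValueError(f"h2_o must lie strictly in (0, 1), got {h2_o}")
    p = scale_params(alpha)
    h2_l = h2_o * alpha * (1.0 - alpha) / p.z**2
    if h2_l >= 1.0:
        raise ValueError(
            f"inconsistent inputs: converted h2_l = {h2_l:.3f} >= 1 "
            f"(h2_o={h2_o}, alpha={alpha})"
        )
    return h2_l


def gebv_var_heritability_adjust(
    bv_o: GEBVTable,
    sigma2_e_o: float,
    h2_o: float,
    h2_l: float,
    parse: str = "scale_by_ratio",
) -> GEBVTable:
    """Variance-heritability adjustment of observed-scale GEBVs.

    Approach 1: scale observed-scale breeding values to the liability
    scale using the observed-scale residual variance and the ratio of
    heritabilities. Two algebraic parses of the published scaling are in
    circulation; both are linear through the origin and therefore
    rank-preserving:

    * ``"scale_by_ratio"`` (default): BV_l = (BV_o / sigma2_e_o) * (1 - h2_o/h2_l)
    * ``"divide"``: BV_l = BV_o / (sigma2_e_o * (1 - h2_o/h2_l))
    """
    if sigma2_e_o <= 0.0:
        raise ValueError(f"sigma2_e_o must be positive, got {sigma2_e_o}")
    if not (0.0 < h2_o < h2_l < 1.0):
        raise ValueError(
            f"need 0 < h2_o < h2_l < 1 for the adjustment, got h2_o={h2_o}, h2_l={h2_l}"
        )
    factor = 1.0 - h2_o / h2_l
    if parse == "scale_by_ratio":
        values = bv_o.values / sigma2_e_o * factor
    elif parse == "divide":
        values = bv_o.values / (sigma2_e_o * factor)
    else:
        raise ValueError(f"parse must be 'scale_by_ratio' or 'divide', got {parse!r}")
    return bv_o.with_values(
        values, "liability",
        method="variance_heritability", parse=parse,
        sigma2_e_o=sigma2_e_o, h2_o=h2_o, h2_l=h2_l,
    )


def gebv_threshold_density_adjust(
    bv_o: GEBVTable, h2_o: float, h2_l: float, alpha: float
) -> GEBVTable:
    """Threshold-density adjustment of observed-scale GEBVs.

    Approach 2: divide by z* = sqrt((h2_o / h2_l) * alpha * (1 - alpha)).
    When h2_o and h2_l are Dempster-Lerner-consistent, z* equals the
    normal ordinate phi(t) at the threshold exactly, which is what gives
    the adjustment its name. Linear, hence rank-preserving.
    """
    if not (0.0 < h2_o < 1.0 and 0.0 < h2_l < 1.0):
        raise ValueError(f"heritabilities must lie in (0, 1), got h2_o={h2_o}, h2_l={h2_l}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {alpha}")
    z_star = float(np.sqrt((h2_o / h2_l) * alpha * (1.0 - alpha)))
    if z_star == 0.0:
        raise ValueError("zero scaling factor: degenerate inputs")
    return bv_o.with_values(
        bv_o.values / z_star, "liability",
        method="threshold_density", z_star=z_star, h2_o=h2_o, h2_l=h2_l, alpha=alpha,
    )


def gebv_to_probability(
    bv_l: GEBVTable,
    alpha: float,
    sigma_e: float = 1.0,
    reference_mean: float | None = None,
    orientation: str = "defect_increasing",
) -> GEBVTable:
    """Probability of expressing the defect from liability-scale GEBVs.

    P_i = 1 - Phi((t - (U_i - mu_U)) / sigma_e) with t = Phi^-1(1-alpha):
    strictly increasing in the liability GEBV U_i, and equal to alpha for
    the reference-mean animal (by default mu_U is the mean GEBV over the
    whole table). ``orientation="printed"`` flips to the decreasing form
    Phi((t - mu_U - U_i) / sigma_e) used by some published summaries.
    """
    if bv_l.scale != "liability":
        raise ValueError(f"expected liability-scale input, got {bv_l.scale!r}")
    if sigma_e <= 0.0:
        raise ValueError(f"sigma_e must be positive, got {sigma_e}")
    p = scale_params(alpha)
    u = bv_l.values.to_numpy()
    mu = float(u.mean()) if reference_mean is None else float(reference_mean)
    if orientation == "defect_increasing":
        prob = 1.0 - norm.cdf((p.t - (u - mu)) / sigma_e)
    elif orientation == "printed":
        prob = norm.cdf((p.t - mu - u) / sigma_e)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return bv_l.with_values(
        prob, "probability",
        alpha=alpha, sigma_e=sigma_e, reference_mean=mu, orientation=orientation,
    )
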