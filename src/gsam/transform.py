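"""The Box-Cox power transformation and its exact inverse.

psi(s; lambda) = (s**lambda - 1)/lambda for lambda != 0, ln s for lambda = 0.
The log-Jacobian of the transformation, (lambda - 1) * sum(ln s), is carried
alongside the transformed values: it is what makes log-likelihoods at
different lambda comparable on the same untransformed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransformedResponse", "boxcox", "boxcox_inverse"]

#: values of |lambda| below this are routed to the exact log branch
LOG_BRANCH_TOL = 1e-8


@dataclass(frozen=True)
class TransformedResponse:
    """Box-Cox-transformed observations with the transformation's Jacobian."""

    values: np.ndarray
    lambda_used: float
    log_jacobian: float


def boxcox(values, lam: float, shift: bool = True) -> TransformedResponse:
    """Box-Cox transform strictly positive values.

    With ``shift=True`` (default) lambda = 1 is the genuine Box-Cox member
    z = s - 1; with ``shift=False`` lambda = 1 is treated as the identity
    z = s.  Slope coefficients of any linear predictor fitted to z are the
    same under both conventions; only an intercept moves by 1.
    """
    s = np.asarray(values, dtype=float)
    bad = np.nonzero(~(s > 0))[0]
    if bad.size:
        raise ValueError(f"Box-Cox requires positive values; offending rows: "
                         f"{bad.tolist()}")
    log_s = np.log(s)
    if abs(lam) < LOG_BRANCH_TOL:
        z = log_s
        lam_eff = 0.0
    elif lam == 1.0 and not shift:
        z = s
        lam_eff = 1.0
    else:
        z = (s ** lam - 1.0) / lam
        lam_eff = lam
    return TransformedResponse(z, lam_eff, (lam_eff - 1.0) * float(log_s.sum()))


def boxcox_inverse(z, lam: float, shift: bool = True):
    """Exact inverse of :func:`boxcox`: (lambda*z + 1)**(1/lambda), or e**z.

    Requires lambda*z + 1 > 0 when lambda != 0.
    """
    z = np.asarray(z, dtype=float)
    if abs(lam) < LOG_BRANCH_TOL:
        return np.exp(z)
    if lam == 1.0 and not shift:
        return z.copy()
    base = lam * z + 1.0
    if np.any(base <= 0):
        raise ValueError("transformed value outside image of transformation "
                         f"(lambda*z + 1 <= 0 at lambda={lam:g})")
    return base ** (1.0 / lam)
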