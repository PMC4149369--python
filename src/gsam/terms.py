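"""The systematic-component term algebra and design-matrix construction.

The linear predictor of a generalized species-area model is built from three
polynomial families in the sampled area A: powers of A, powers of log A and
inverse powers of A, plus an optional intercept.  Any combination of such
terms defines a model's systematic component; classical species-area curves
correspond to particular small term sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SystematicTerm", "GSAMSpec", "DesignMatrix",
    "build_design_matrix", "generalized_binomial", "power_log_expansion_terms",
    "intercept", "area_power", "log_area_power", "inverse_area_power",
]

_KINDS = ("intercept", "area_power", "log_area_power", "inverse_area_power")


class CollinearityError(np.linalg.LinAlgError):
    """Raised when the systematic component yields a rank-deficient matrix."""


@dataclass(frozen=True)
class SystematicTerm:
    """One column of the systematic component.

    ``intercept`` evaluates to 1; ``area_power`` to A**exponent;
    ``log_area_power`` to (ln A)**exponent; ``inverse_area_power`` to
    A**(-exponent).  Exponents are positive reals.
    """

    kind: str
    exponent: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind != "intercept" and not self.exponent > 0:
            raise ValueError("exponent must be > 0 for non-intercept terms")
        if self.kind == "intercept":
            object.__setattr__(self, "exponent", 0.0)

    def __call__(self, area) -> np.ndarray:
        a = np.asarray(area, dtype=float)
        if np.any(a <= 0):
            raise ValueError("term evaluation requires area > 0")
        if self.kind == "intercept":
            return np.ones_like(a)
        if self.kind == "area_power":
            return a ** self.exponent
        if self.kind == "log_area_power":
            return np.log(a) ** self.exponent
        return a ** (-self.exponent)

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "1"
        e = self.exponent
        es = f"{int(e)}" if float(e).is_integer() else f"{e:g}"
        if self.kind == "area_power":
            return f"A^{es}" if e != 1 else "A"
        if self.kind == "log_area_power":
            return f"(ln A)^{es}" if e != 1 else "ln A"
        return f"A^-{es}" if e != 1 else "1/A"

    def __repr__(self):  # compact, used in summaries
        return f"Term[{self.label}]"


def intercept() -> SystematicTerm:
    return SystematicTerm("intercept")


def area_power(exponent: float = 1.0) -> SystematicTerm:
    return SystematicTerm("area_power", exponent)


def log_area_power(exponent: float = 1.0) -> SystematicTerm:
    return SystematicTerm("log_area_power", exponent)


def inverse_area_power(exponent: float = 1.0) -> SystematicTerm:
    return SystematicTerm("inverse_area_power", exponent)


@dataclass(frozen=True)
class GSAMSpec:
    """Complete description of a generalized species-area model.

    Parameters
    ----------
    terms : sequence of SystematicTerm
        Columns of the systematic component, in order.  Must be unique;
        an intercept, when present, comes first.
    family : {"normal", "gamma", "inverse_gaussian"}
        Response distribution of the Box-Cox-transformed richness.
    link : {"identity", "reciprocal", "inverse_squared", "log"}
        Link between the mean of the transformed response and the linear
        predictor.
    lam : float or None
        Box-Cox exponent; ``None`` requests profile-likelihood estimation.
    """

    terms: tuple
    family: str = "normal"
    link: str = "identity"
    lam: float | None = 1.0
    label: str = field(default="", compare=False)

    def __post_init__(self):
        terms = tuple(self.terms)
        if not terms:
            raise ValueError("at least one systematic term is required")
        keys = [(t.kind, t.exponent) for t in terms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicated systematic terms")
        has_icpt = [t.kind == "intercept" for t in terms]
        if any(has_icpt) and not has_icpt[0]:
            raise ValueError("the intercept must be the first term")
        object.__setattr__(self, "terms", terms)

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def profiled(self) -> bool:
        return self.lam is None

    def describe(self) -> str:
        fam = {"normal": "Normal", "gamma": "Gamma",
               "inverse_gaussian": "Inv. Gaussian"}[self.family]
        lam = "profiled" if self.profiled else f"{self.lam:g}"
        terms = " + ".join(t.label for t in self.terms)
        return f"{fam}/{self.link}, lambda={lam}: {terms}"


@dataclass(frozen=True)
class DesignMatrix:
    """An n x p model matrix together with its column labels."""

    values: np.ndarray
    column_labels: tuple

    @property
    def shape(self):
        return self.values.shape


def build_design_matrix(area, spec: GSAMSpec | Sequence[SystematicTerm],
                        rank_tol: float = 1e-10,
                        check_rank: bool = True) -> DesignMatrix:
    """Evaluate the systematic-component terms at each area.

    Raises :class:`CollinearityError`, naming the dependent columns, when the
    matrix is rank deficient relative to ``rank_tol`` (largest singular
    value as reference).  ``check_rank=False`` skips the check, e.g. when
    evaluating the matrix at prediction points only.
    """
    terms = spec.terms if isinstance(spec, GSAMSpec) else tuple(spec)
    a = np.asarray(getattr(area, "area", area), dtype=float)
    if np.any(a <= 0):
        raise ValueError("all areas must be > 0")
    X = np.column_stack([t(a) for t in terms])
    labels = tuple(t.label for t in terms)
    if not check_rank:
        pass
    elif X.shape[0] >= X.shape[1]:
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        if s[-1] <= rank_tol * s[0]:
            v = vt[-1]
            involved = [labels[j] for j in np.nonzero(np.abs(v) > 1e-3)[0]]
            raise CollinearityError(
                "collinear systematic component: columns "
                + ", ".join(involved) + " are linearly dependent")
    else:
        raise CollinearityError(
            f"more terms ({X.shape[1]}) than observations ({X.shape[0]})")
    return DesignMatrix(X, labels)


def generalized_binomial(z: float, k: int) -> float:
    """Generalized binomial coefficient C(z, k) = z(z-1)...(z-k+1)/k!.

    Defined for any real upper index z and integer k >= 0; for integer z it
    reduces to the ordinary binomial coefficient (0 when k > z >= 0).
    """
    if k < 0 or int(k) != k:
        raise ValueError("k must be a nonnegative integer")
    out = 1.0
    for j in range(int(k)):
        out *= (z - j) / (j + 1)
    return out


def power_log_expansion_terms(z: float, kmax: int, c: float = 1.0,
                              max_log_area: float | None = None,
                              tol: float = 1e-3):
    """Truncated binomial expansion of (c + ln A)**z onto log-power terms.

    (c + ln A)**z = sum_k C(z, k) c**(z-k) (ln A)**k, truncated at ``kmax``.
    Returns a list of (coefficient, SystematicTerm) pairs; the k = 0 term is
    the intercept.  The expansion converges for ``abs(ln A) < c``; when
    ``max_log_area`` is given and the magnitude of the first omitted term at
    that point exceeds ``tol``, a truncation warning is emitted.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if c <= 0:
        raise ValueError("c must be > 0 (expansion point)")
    pairs = []
    for k in range(kmax + 1):
        coef = generalized_binomial(z, k) * c ** (z - k)
        term = intercept() if k == 0 else log_area_power(float(k))
        pairs.append((coef, term))
    if max_log_area is not None:
        nxt = abs(generalized_binomial(z, kmax + 1)
                  * c ** (z - kmax - 1) * max_log_area ** (kmax + 1))
        if nxt > tol:
            warnings.warn(
                f"power-log expansion truncated at k={kmax}: next-term bound "
                f"{nxt:.3g} exceeds tolerance {tol:g} at |ln A|={max_log_area:g}",
                RuntimeWarning, stacklevel=2)
    return pairs
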