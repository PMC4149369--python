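"""Catalogue of classical species-area curves and their transformed-GLM forms.

Every curve here is a special case of the transformed-GLM framework: the
log-linearizable forms (power law, persistence models, polynomial
power-functions) correspond to a log transform (lambda = 0) of richness with
a linear predictor in powers of ln A, A and 1/A; the linear forms
(MacArthur-Wilson, Gleason, the quadratic and general power-logarithmic
curves) keep richness on its own scale (lambda = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .terms import (GSAMSpec, SystematicTerm, area_power, intercept,
                    inverse_area_power, log_area_power,
                    power_log_expansion_terms)

__all__ = ["ClassicalModel", "list_classical_models", "get_classical_model",
           "mean_curve"]


@dataclass(frozen=True)
class ClassicalModel:
    """A named classical SAR form with its transformed-GLM equivalent.

    ``mean`` evaluates the deterministic (noise-free) richness curve on the
    original scale; ``to_beta``, where defined, maps the curve's natural
    coefficients onto the linear predictor of the equivalent transformed
    model (for lambda = 0 forms the identity mean == exp(X beta) holds
    exactly; for the linear lambda = 1 forms mean == X beta).
    """

    name: str
    description: str
    arity: int
    gsam_equivalent: GSAMSpec
    mean: Callable
    to_beta: Callable | None = None

    def mean_curve(self, coefficients: Sequence[float], areas) -> np.ndarray:
        if len(coefficients) != self.arity:
            raise ValueError(f"{self.name} takes {self.arity} coefficients, "
                             f"got {len(coefficients)}")
        a = np.asarray(areas, dtype=float)
        if np.any(a <= 0):
            raise ValueError("areas must be > 0")
        return np.asarray(self.mean(np.asarray(coefficients, float), a), float)


def _spec(lam, *terms, label):
    return GSAMSpec(terms=terms, family="normal", link="identity",
                    lam=lam, label=label)


def _build() -> dict:
    L = np.log
    models = [
        ClassicalModel(
            "arrhenius_power",
            "Power law S = c A^z",
            2,
            _spec(0.0, intercept(), log_area_power(1), label="arrhenius_power"),
            lambda b, a: b[0] * a ** b[1],
            lambda b: np.array([np.log(b[0]), b[1]]),
        ),
        ClassicalModel(
            "plotkin_P1",
            "Persistence curve S = c A^z exp(k A)",
            3,
            _spec(0.0, intercept(), log_area_power(1), area_power(1),
                  label="plotkin_P1"),
            lambda b, a: b[0] * a ** b[1] * np.exp(b[2] * a),
            lambda b: np.array([np.log(b[0]), b[1], b[2]]),
        ),
        ClassicalModel(
            "plotkin_P1_full",
            "Persistence curve with quadratic exponent "
            "S = c A^z exp(k1 A + k2 A^2)",
            4,
            _spec(0.0, intercept(), log_area_power(1), area_power(1),
                  area_power(2), label="plotkin_P1_full"),
            lambda b, a: b[0] * a ** b[1] * np.exp(b[2] * a + b[3] * a ** 2),
            lambda b: np.array([np.log(b[0]), b[1], b[2], b[3]]),
        ),
        ClassicalModel(
            "ulrich_buszko_P2",
            "Inverse-persistence curve S = c A^z exp(k / A)",
            3,
            _spec(0.0, intercept(), log_area_power(1), inverse_area_power(1),
                  label="ulrich_buszko_P2"),
            lambda b, a: b[0] * a ** b[1] * np.exp(b[2] / a),
            lambda b: np.array([np.log(b[0]), b[1], b[2]]),
        ),
        ClassicalModel(
            "ulrich_buszko_P2_full",
            "Inverse-persistence curve with quadratic inverse exponent "
            "S = c A^z exp(k1/A + k2/A^2)",
            4,
            _spec(0.0, intercept(), log_area_power(1), inverse_area_power(1),
                  inverse_area_power(2), label="ulrich_buszko_P2_full"),
            lambda b, a: b[0] * a ** b[1]
            * np.exp(b[2] / a + b[3] / a ** 2),
            lambda b: np.array([np.log(b[0]), b[1], b[2], b[3]]),
        ),
        ClassicalModel(
            "chiarucci_quadratic",
            "Quadratic power-function ln S = ln b0 + b1 ln A + b2 (ln A)^2",
            3,
            _spec(0.0, intercept(), log_area_power(1), log_area_power(2),
                  label="chiarucci_quadratic"),
            lambda b, a: b[0] * np.exp(b[1] * L(a) + b[2] * L(a) ** 2),
            lambda b: np.array([np.log(b[0]), b[1], b[2]]),
        ),
        ClassicalModel(
            "chiarucci_polynomial",
            "Cubic polynomial power-function in ln A",
            4,
            _spec(0.0, intercept(), log_area_power(1), log_area_power(2),
                  log_area_power(3), label="chiarucci_polynomial"),
            lambda b, a: b[0] * np.exp(b[1] * L(a) + b[2] * L(a) ** 2
                                       + b[3] * L(a) ** 3),
            lambda b: np.array([np.log(b[0]), b[1], b[2], b[3]]),
        ),
        ClassicalModel(
            "macarthur_wilson_linear",
            "Linear curve S = b0 + b1 A",
            2,
            _spec(1.0, intercept(), area_power(1),
                  label="macarthur_wilson_linear"),
            lambda b, a: b[0] + b[1] * a,
            lambda b: np.array([b[0], b[1]]),
        ),
        ClassicalModel(
            "gleason_log",
            "Logarithmic curve S = b0 + b1 ln A",
            2,
            _spec(1.0, intercept(), log_area_power(1), label="gleason_log"),
            lambda b, a: b[0] + b[1] * L(a),
            lambda b: np.array([b[0], b[1]]),
        ),
        ClassicalModel(
            "gitay_quadratic_log",
            "Quadratic logarithmic curve S = (b0 + b1 ln A)^2",
            2,
            _spec(1.0, intercept(), log_area_power(1), log_area_power(2),
                  label="gitay_quadratic_log"),
            lambda b, a: (b[0] + b[1] * L(a)) ** 2,
            None,  # the expanded 3-term predictor frees the constraint b1^2 = 4 b0 b2
        ),
        ClassicalModel(
            "gitay_power_log",
            "General power-logarithmic curve S = (b0 + b1 ln A)^z, "
            "represented by its truncated binomial expansion",
            3,
            _spec(1.0, intercept(), log_area_power(1), log_area_power(2),
                  log_area_power(3), label="gitay_power_log"),
            lambda b, a: (b[0] + b[1] * L(a)) ** b[2],
            None,
        ),
    ]
    return {m.name: m for m in models}


_CATALOG = _build()


def list_classical_models() -> tuple:
    """All classical SAR forms, as :class:`ClassicalModel` entries."""
    return tuple(_CATALOG.values())


def get_classical_model(name: str) -> ClassicalModel:
    try:
        return _CATALOG[name]
    except KeyError:
        raise ValueError(f"unknown classical model {name!r}; choose from "
                         f"{sorted(_CATALOG)}") from None


def mean_curve(model, coefficients, areas) -> np.ndarray:
    """Deterministic mean richness of a classical form at the given areas."""
    if isinstance(model, str):
        model = get_classical_model(model)
    return model.mean_curve(coefficients, areas)
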