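"""Synthetic species-area data generators.

Two generators are provided.  The neutral-lattice generator emulates the
colonization of a square region by ecologically equivalent species drawn
from a metacommunity pool without dispersal limitation: a relative-abundance
vector is drawn from a symmetric Dirichlet, every lattice cell receives an
independent draw from it, and nested square quadrats are counted for
distinct species — yielding the familiar concave species-area curve.  The
second generator samples directly from a specified transformed-GLM (terms,
family, link, coefficients, Box-Cox exponent, dispersion), which is what
parameter-recovery and coverage experiments need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import SARDataset
from .families import get_family, get_link
from .terms import GSAMSpec, build_design_matrix
from .transform import boxcox_inverse

__all__ = ["LatticeCommunity", "simulate_metacommunity", "populate_lattice",
           "nested_sar", "expected_nested_richness", "generate_gsam_data"]

#: defaults of the neutral experiment: an 80-species pool on a 200 x 200 grid
DEFAULT_SIDE = 200
DEFAULT_N_SPECIES = 80
DEFAULT_THETA = 0.5


@dataclass(frozen=True)
class LatticeCommunity:
    """A square grid of species identities with its metacommunity pool.

    ``cells`` is an L x L integer array of identities in 1..n_species;
    ``pool`` the relative-abundance vector they were drawn from.
    """

    cells: np.ndarray
    pool: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cells)
        p = np.asarray(self.pool, float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("cells must be a square grid")
        if not np.isclose(p.sum(), 1.0) or np.any(p <= 0):
            raise ValueError("pool must be strictly positive and sum to 1")
        if c.min() < 1 or c.max() > p.size:
            raise ValueError("cell identities must lie in 1..n_species")
        object.__setattr__(self, "cells", c)
        object.__setattr__(self, "pool", p)

    @property
    def side(self) -> int:
        return self.cells.shape[0]

    @property
    def n_species(self) -> int:
        return self.pool.size

    def richness(self) -> int:
        return int(np.unique(self.cells).size)


def simulate_metacommunity(n_species: int = DEFAULT_N_SPECIES,
                           theta: float = DEFAULT_THETA,
                           seed=None) -> np.ndarray:
    """Relative metacommunity abundances from a symmetric Dirichlet(theta).

    Small ``theta`` gives strongly uneven pools (a few dominant species, a
    long rare tail, as in neutral metacommunities); theta -> infinity tends
    to the uniform pool.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_species, float(theta)))
    # guard against exact zeros from extreme draws
    p = np.maximum(p, 1e-300)
    return p / p.sum()


def populate_lattice(side: int = DEFAULT_SIDE, abundances=None,
                     seed=None) -> LatticeCommunity:
    """Fill an L x L lattice with i.i.d. draws from the abundance vector.

    Independent cells are the zero-dispersal-limitation limit of a neutral
    community: every individual is a fresh recruit from the metacommunity.
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    rng = np.random.default_rng(seed)
    if abundances is None:
        abundances = simulate_metacommunity(seed=rng)
    p = np.asarray(abundances, float)
    cells = rng.choice(p.size, size=(side, side), p=p / p.sum()) + 1
    return LatticeCommunity(cells=cells, pool=p / p.sum())


def nested_sar(community: LatticeCommunity,
               quadrat_sides: Sequence[int] | None = None,
               anchor: str = "corner") -> SARDataset:
    """Resample a lattice into nested square quadrats and count species.

    For each quadrat side q the area is q**2 cells and the richness is the
    number of distinct identities inside the q x q window.  ``anchor``
    places the window: ``"corner"`` (default) grows from the top-left
    corner; ``"average"`` averages the richness over all four corner
    anchors (rounded to the nearest count).
    """
    L = community.side
    if quadrat_sides is None:
        quadrat_sides = _default_quadrats(L)
    q = np.asarray(sorted(quadrat_sides), int)
    if q.min() < 1 or q.max() > L:
        raise ValueError(f"quadrat sides must lie in 1..{L}")
    cells = community.cells
    corners = {"corner": ((0, 0),),
               "average": ((0, 0), (0, 1), (1, 0), (1, 1))}
    if anchor not in corners:
        raise ValueError("anchor must be 'corner' or 'average'")
    rich = []
    for side in q:
        counts = []
        for ci, cj in corners[anchor]:
            ri = slice(0, side) if ci == 0 else slice(L - side, L)
            rj = slice(0, side) if cj == 0 else slice(L - side, L)
            counts.append(np.unique(cells[ri, rj]).size)
        rich.append(max(1, int(round(float(np.mean(counts))))))
    return SARDataset(area=(q ** 2).astype(float),
                      species=np.asarray(rich, int),
                      label=f"lattice-L{L}")


def _default_quadrats(L: int) -> list:
    """Roughly geometric ladder of quadrat sides up to the full lattice."""
    q = sorted({max(1, int(round(L * f)))
                for f in (0.02, 0.05, 0.1, 0.15, 0.25, 0.35, 0.5, 0.7, 0.85, 1.0)})
    return [s for s in q if s <= L]


def expected_nested_richness(pool, area_cells) -> np.ndarray:
    """Closed-form mean richness of i.i.d.-filled quadrats.

    With independent multinomial cells, species i occupies at least one of
    the a cells with probability 1 - (1 - p_i)**a, so
    E[S(a)] = sum_i [1 - (1 - p_i)**a].
    """
    p = np.asarray(pool, float)
    a = np.asarray(area_cells, float)
    return np.sum(1.0 - (1.0 - p[None, :]) ** a[:, None], axis=1)


def generate_gsam_data(spec: GSAMSpec, beta, lam: float, dispersion: float,
                       areas, seed=None, shift: bool = True,
                       max_attempts: int = 1000) -> SARDataset:
    """Sample a species-area dataset from a fully specified transformed GLM.

    Draws the transformed response from the family at mean mu = g^{-1}(x'b)
    and dispersion phi, back-transforms, and rounds to the nearest positive
    integer (richness is a count; the model itself is continuous).  Draws
    falling outside the image of the transformation (lam*z + 1 <= 0) or
    rounding below 1 are rejected and redrawn, at most ``max_attempts``
    times per observation.
    """
    rng = np.random.default_rng(seed)
    areas = np.asarray(areas, float)
    X = build_design_matrix(areas, spec, check_rank=False).values
    fam = get_family(spec.family)
    link = get_link(spec.link)
    mu = link.inverse(X @ np.asarray(beta, float))
    if fam.positive_support and np.any(mu <= 0):
        raise ValueError("mean outside family support at the given areas")
    if float(dispersion) == 0.0:
        s = np.rint(boxcox_inverse(mu, lam, shift=shift))
        if np.any(s < 1):
            raise ValueError("noise-free mean rounds below 1 species")
        return SARDataset(areas, s.astype(int), label="gsam-sim")
    species = np.empty(areas.size, dtype=int)
    for i in range(areas.size):
        for _ in range(max_attempts):
            z = float(fam.sample(rng, mu[i], float(dispersion)))
            if abs(lam) >= 1e-8 and not (lam == 1.0 and not shift):
                if lam * z + 1.0 <= 0:
                    continue
            s = int(round(float(boxcox_inverse(z, lam, shift=shift))))
            if s >= 1:
                species[i] = s
                break
        else:
            raise RuntimeError(
                "model-parameter combination incompatible with positive "
                f"richness at area {areas[i]:g}")
    return SARDataset(areas, species, label="gsam-sim")
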