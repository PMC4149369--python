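"""Species-area datasets: the container, CSV I/O and the embedded Hymenoptera fixture.

A species-area dataset is a paired sample of sampled areas (any consistent
unit: m², lattice cells, ...) and the species richness observed in each.
Replicated areas are allowed; richness must be a positive integer because
log- and Box-Cox transforms with non-positive exponents require positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SARDataset", "read_dataset", "write_dataset", "hymenoptera"]


class ValidationError(ValueError):
    """Raised when a dataset violates the (area > 0, species >= 1) contract."""


@dataclass(frozen=True)
class SARDataset:
    """Paired (area, species richness) observations — the unit of all fitting.

    Parameters
    ----------
    area : array-like of float
        Sampled areas, all strictly positive, in one consistent unit.
    species : array-like of int
        Observed species richness per area, all >= 1.
    """

    area: np.ndarray
    species: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self):
        a = np.asarray(self.area, dtype=float)
        s = np.asarray(self.species)
        if a.ndim != 1 or s.ndim != 1 or a.shape != s.shape:
            raise ValidationError("area and species must be 1-D of equal length")
        bad = np.nonzero(~(a > 0))[0]
        if bad.size:
            raise ValidationError(f"non-positive area at rows {bad.tolist()}")
        if not np.all(np.isfinite(a)):
            raise ValidationError("non-finite area values")
        s_int = np.asarray(np.rint(np.asarray(s, dtype=float)), dtype=int)
        if not np.allclose(np.asarray(s, dtype=float), s_int, atol=1e-9):
            bad = np.nonzero(~np.isclose(np.asarray(s, float), s_int))[0]
            raise ValidationError(f"non-integer species count at rows {bad.tolist()}")
        bad = np.nonzero(s_int < 1)[0]
        if bad.size:
            raise ValidationError(f"species count < 1 at rows {bad.tolist()}")
        object.__setattr__(self, "area", a)
        object.__setattr__(self, "species", s_int)

    def __len__(self) -> int:
        return self.area.size

    @property
    def n(self) -> int:
        return self.area.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"area": self.area, "species": self.species})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "SARDataset":
        missing = {"area", "species"} - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        return cls(df["area"].to_numpy(), df["species"].to_numpy(), label=label)


def read_dataset(path) -> SARDataset:
    """Read a two-column CSV with header ``area,species`` into a SARDataset."""
    df = pd.read_csv(path)
    return SARDataset.from_frame(df, label=str(path))


def write_dataset(data: SARDataset, path) -> None:
    """Write a SARDataset as the standard two-column CSV."""
    data.to_frame().to_csv(path, index=False)


# Cumulative richness of parasitic Hymenoptera in nested plots of a beech
# forest on limestone (Göttingen forest); areas in m², 25 observations.
_HYMENOPTERA = (
    (1, 55), (2, 89), (4, 167), (4, 116), (4, 148),
    (6, 133), (6, 157), (6, 147), (6, 146), (8, 226),
    (12, 246), (12, 204), (12, 200), (16, 258), (16, 260),
    (20, 274), (20, 310), (24, 311), (24, 311), (30, 344),
    (36, 379), (49, 409), (61, 454), (73, 473), (89, 521),
)


def hymenoptera() -> SARDataset:
    """The 25-observation parasitic-Hymenoptera species-area dataset.

    A long-term survey (8 years) of parasitic Hymenoptera in 144 m² of
    forest soil in a ~120-year-old German beech forest on limestone,
    resampled into nested plots of 1–89 m².
    """
    area, species = zip(*_HYMENOPTERA)
    return SARDataset(np.array(area, float), np.array(species, int),
                      label="hymenoptera")
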