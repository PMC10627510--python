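"""Domain types for the RAF paradoxical-activation equilibrium models.

The system is a RAF kinase pool at thermodynamic equilibrium with a RAF
inhibitor. A RAF monomer interconverts between an autoinhibited conformation
(which can neither dimerize nor bind drug) and a non-autoinhibited
conformation (which can do both). Three drug-coupled mechanisms are modeled:

* **CA** — conformational autoinhibition: drug binding sequesters monomers in
  the non-autoinhibited, dimerization-competent state.
* **DP** — dimer potentiation: a dimer containing at least one drug-bound
  protomer has its dissociation constant scaled by ``f`` (``f < 1``
  strengthens the dimer).
* **NC** — negative cooperativity: the second drug-binding event within a
  dimer is weakened by the factor ``g`` (``g > 1``).

The **UNIFIED** variant combines all three; each single-mechanism variant is
the unified model with the other mechanisms' parameters pinned to their
neutral values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Variant",
    "ModelParams",
    "DimensionlessGroups",
    "SpeciesState",
    "DoseGrid",
]


class Variant(str, Enum):
    """Which mechanisms are active. Explicit — never inferred from values.

    ``f = 1`` inside a UNIFIED fit is a legal outcome, not a variant switch.
    """

    CA = "CA"
    DP = "DP"
    NC = "NC"
    UNIFIED = "UNIFIED"


@dataclass(frozen=True)
class ModelParams:
    """Equilibrium constants defining one model instance (one drug, one cell
    context).

    Parameters
    ----------
    K_A:
        Autoinhibition equilibrium constant, the concentration ratio
        [autoinhibited]/[non-autoinhibited] of drug-free monomer.
        Dimensionless, >= 0.
    K_dim:
        Dissociation constant of the drug-free RAF dimer, uM.
    K_d:
        Dissociation constant of drug binding a non-autoinhibited monomer, uM.
    f:
        Dimer-potentiation factor. A dimer containing at least one drug-bound
        protomer has dissociation constant ``f * K_dim``; equivalently the
        first drug-binding event on a dimer site has dissociation constant
        ``f * K_d`` (per site). Dimensionless, > 0; ``f < 1`` potentiates.
    g:
        Negative-cooperativity factor: the second drug-binding event within a
        dimer has its dissociation constant scaled by ``g``. Dimensionless,
        > 0; ``g > 1`` is negative cooperativity.
    raf_total:
        Total RAF protomer concentration, uM.
    variant:
        Which mechanism set is active (see :class:`Variant`).
    """

    K_A: float
    K_dim: float
    K_d: float
    f: float = 1.0
    g: float = 1.0
    raf_total: float = 0.04
    variant: Variant = Variant.UNIFIED

    def __post_init__(self) -> None:
        if not (self.K_dim > 0 and self.K_d > 0 and self.raf_total > 0):
            raise ValueError("K_dim, K_d and raf_total must be positive")
        if not (self.f > 0 and self.g > 0):
            raise ValueError("f and g must be positive")
        if self.K_A < 0:
            raise ValueError("K_A must be nonnegative")
        v = Variant(self.variant)
        object.__setattr__(self, "variant", v)
        if v is Variant.CA and not (self.f == 1.0 and self.g == 1.0):
            raise ValueError("CA variant requires f = 1 and g = 1")
        if v is Variant.DP and not (self.K_A == 0.0 and self.g == 1.0):
            raise ValueError("DP variant requires K_A = 0 and g = 1")
        if v is Variant.NC and not (self.K_A == 0.0 and self.f == 1.0):
            raise ValueError("NC variant requires K_A = 0 and f = 1")

    # -- derived scales ----------------------------------------------------
    @property
    def raf_rel(self) -> float:
        """Total RAF in units of the dimer dissociation constant."""
        return self.raf_total / self.K_dim

    def d_rel(self, drug_free: float) -> float:
        """Free drug in units of the monomer drug dissociation constant."""
        return drug_free / self.K_d

    def as_unified(self) -> "ModelParams":
        """The same parameter point expressed in the UNIFIED variant."""
        return replace(self, variant=Variant.UNIFIED)

    # -- flat-config round trip -------------------------------------------
    _KEYS = ("K_A", "K_dim_uM", "K_d_uM", "f", "g", "raf_total_uM", "variant")

    def to_dict(self) -> dict:
        return {
            "K_A": self.K_A,
            "K_dim_uM": self.K_dim,
            "K_d_uM": self.K_d,
            "f": self.f,
            "g": self.g,
            "raf_total_uM": self.raf_total,
            "variant": self.variant.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
        return cls(
            K_A=float(d["K_A"]),
            K_dim=float(d["K_dim_uM"]),
            K_d=float(d["K_d_uM"]),
            f=float(d.get("f", 1.0)),
            g=float(d.get("g", 1.0)),
            raf_total=float(d.get("raf_total_uM", 0.04)),
            variant=Variant(d.get("variant", "UNIFIED")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class DimensionlessGroups:
    """The dimensionless groups in which every closed form is written.

    ``d_rel`` and ``RAF_rel`` are the two natural scales (drug over K_d, RAF
    over K_dim). The ``E`` symbols are the abbreviated expressions that cast
    all four variants' solutions into a common functional shape; each is
    documented in :func:`rafpa.closed_forms.dimensionless_groups`.
    """

    d_rel: float
    RAF_rel: float
    E1: float
    E1d: float
    E1n: float
    E2c: float
    E2d: float
    E2n: float
    E2u: float
    E3: float


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (uM) of the six RAF species plus free drug.

    Species: ``A`` autoinhibited monomer; ``R`` non-autoinhibited drug-free
    monomer; ``RD`` drug-bound monomer; ``R2`` drug-free dimer; ``R2D``
    singly drug-bound dimer; ``R2D2`` doubly drug-bound dimer; ``D_free``
    free drug.
    """

    A: float
    R: float
    RD: float
    R2: float
    R2D: float
    R2D2: float
    D_free: float

    CONSERVATION_RTOL = 1e-10

    def __post_init__(self) -> None:
        for name in ("A", "R", "RD", "R2", "R2D", "R2D2", "D_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration for {name}")

    @property
    def protomer_total(self) -> float:
        """Total RAF protomers: monomers plus two per dimer."""
        return self.A + self.R + self.RD + 2.0 * (self.R2 + self.R2D + self.R2D2)

    @property
    def active_protomers(self) -> float:
        """Protomers that are in a dimer and not bound to drug."""
        return 2.0 * self.R2 + self.R2D

    @property
    def dimer_total(self) -> float:
        return self.R2 + self.R2D + self.R2D2

    def check_conservation(self, raf_total: float) -> None:
        if not np.isclose(
            self.protomer_total, raf_total, rtol=self.CONSERVATION_RTOL, atol=0.0
        ):
            raise AssertionError(
                f"protomer conservation violated: {self.protomer_total} != {raf_total}"
            )


@dataclass(frozen=True)
class DoseGrid:
    """Ordered grid of free-drug concentrations (uM), starting at 0.

    The zero dose is mandatory so the drug-free baseline is always defined.
    """

    doses: tuple[float, ...]

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.doses)
        if len(d) == 0:
            raise ValueError("empty dose grid")
        if d[0] != 0.0:
            raise ValueError("dose grid must start at 0 (baseline)")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("doses must be strictly increasing")
        object.__setattr__(self, "doses", d)

    def __len__(self) -> int:
        return len(self.doses)

    def __iter__(self) -> Iterable[float]:
        return iter(self.doses)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.doses, dtype=float)

    @classmethod
    def log(
        cls, lo: float = 1e-4, hi: float = 1e2, points_per_decade: int = 25
    ) -> "DoseGrid":
        """Decade-spaced logarithmic grid with a prepended zero dose.

        Drug response spans orders of magnitude, so log spacing is the
        default; 25 points per decade resolves peak location to a few
        percent before local refinement.
        """
        if not (0 < lo < hi):
            raise ValueError("need 0 < lo < hi")
        n = int(round(np.log10(hi / lo) * points_per_decade)) + 1
        grid = np.logspace(np.log10(lo), np.log10(hi), n)
        return cls((0.0, *grid))
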