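"""Brute-force detailed-balance equilibrium solver.

This module is deliberately independent of :mod:`rafpa.closed_forms`: it
knows nothing about the analytic solutions. It builds the reaction network
from pairwise equilibrium edges (each a dissociation constant plus an
explicit statistical site-multiplicity weight), verifies thermodynamic
consistency (every closed reaction cycle must have an equilibrium-constant
product of one), and solves the conservation equations numerically by
safeguarded bracketing. It is the ground truth against which every closed
form is validated.

Network (unified mechanism; single-mechanism variants pin the neutral
values):

* ``A <-> R`` — conformational opening, concentration ratio ``[A]/[R] = K_A``
* ``R + D <-> RD`` — drug binds the open monomer, ``K_d``
* ``R + R <-> R2`` — dimerization of open monomers, ``K_dim``
* ``R2 + D <-> R2D`` — first drug on a dimer, per-site constant ``f*K_d``,
  statistical weight 2 (two equivalent empty sites, one way back)
* ``R2D + D <-> R2D2`` — second drug, ``g*f'... `` no: constant ``g*K_d``
  scaled by NC only, statistical weight 1/2 (one empty site, two ways back)

Cycle-closure then forces the redundant dimerization routes
``R + RD <-> R2D`` (``f*K_dim``, weight 2) and ``RD + RD <-> R2D2``
(``f*g*K_dim``, weight 1): a drug-containing dimer is potentiated by one
factor of ``f`` regardless of how it was assembled. These redundant edges
are carried in the network purely as consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .closed_forms import _effective_fga
from .params import ModelParams, SpeciesState

__all__ = ["Edge", "ReactionNetwork", "build_network", "solve_equilibrium",
           "write_species_table"]

SPECIES = ("A", "R", "RD", "R2", "R2D", "R2D2", "D")

_CYCLE_RTOL = 1e-10
_ROOT_RTOL = 4 * np.finfo(float).eps


@dataclass(frozen=True)
class Edge:
    """One equilibrium: ``reactants <-> product`` with dissociation constant
    ``K`` and statistical multiplicity ``mult`` (forward site count over
    reverse site count), so ``[product] = mult * prod([reactants]) / K``.

    A single-reactant edge is a conformational isomerization with ``K`` the
    product/reactant concentration ratio: ``[product] = K * [reactant]``.
    """

    reactants: tuple[str, ...]
    product: str
    K: float
    mult: float = 1.0
    redundant: bool = False  # consistency-check edge, not used to build

    def predict(self, conc: dict[str, float]) -> float:
        if len(self.reactants) == 1:
            return self.K * conc[self.reactants[0]]
        prod = 1.0
        for s in self.reactants:
            prod *= conc[s]
        return self.mult * prod / self.K


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    edges: tuple[Edge, ...]
    raf_total_default: float

    def concentrations(self, R: float, D: float) -> dict[str, float]:
        """Propagate pairwise equilibria from free monomer and free drug."""
        conc: dict[str, float] = {"R": R, "D": D}
        pending = [e for e in self.edges if not e.redundant]
        while pending:
            progressed = False
            for e in list(pending):
                if all(s in conc for s in e.reactants):
                    conc[e.product] = e.predict(conc)
                    pending.remove(e)
                    progressed = True
            if not progressed:  # pragma: no cover - malformed network
                raise ValueError("network is not connected from (R, D)")
        return conc

    def check_cycles(self) -> None:
        """Every redundant route must reproduce the spanning-tree value.

        Equivalent to requiring an equilibrium-constant product of one
        around each closed cycle; evaluated at a reference state.
        """
        conc = self.concentrations(R=1.0, D=1.0)
        for e in self.edges:
            if not e.redundant:
                continue
            predicted = e.predict(conc)
            actual = conc[e.product]
            if not np.isclose(predicted, actual, rtol=_CYCLE_RTOL, atol=0.0):
                loop = f"{'+'.join(e.reactants)}->{e.product}"
                raise ValueError(
                    f"detailed-balance cycle violation on {loop}: "
                    f"{predicted} != {actual}"
                )


def build_network(params: ModelParams) -> ReactionNetwork:
    """Assemble the reaction network for one parameter point.

    The placement of ``f`` (both the dimer-site drug affinity and, via
    cycle closure, the dimerization affinity of drug-bound monomers) and
    ``g`` (second dimer site only) is the unique assignment consistent
    with detailed balance; :meth:`ReactionNetwork.check_cycles` enforces
    it at construction.
    """
    f, g, K_A = _effective_fga(params)
    K_d, K_dim = params.K_d, params.K_dim
    edges = (
        Edge(("R",), "A", K_A),
        Edge(("R", "D"), "RD", K_d),
        Edge(("R", "R"), "R2", K_dim),
        Edge(("R2", "D"), "R2D", f * K_d, mult=2.0),
        Edge(("R2D", "D"), "R2D2", g * K_d, mult=0.5),
        # redundant assembly routes (cycle-closure checks)
        Edge(("R", "RD"), "R2D", f * K_dim, mult=2.0, redundant=True),
        Edge(("RD", "RD"), "R2D2", f * g * K_dim, mult=1.0, redundant=True),
    )
    net = ReactionNetwork(SPECIES, edges, params.raf_total)
    net.check_cycles()
    return net


def _protomer_total(conc: dict[str, float]) -> float:
    return (
        conc["A"]
        + conc["R"]
        + conc["RD"]
        + 2.0 * (conc["R2"] + conc["R2D"] + conc["R2D2"])
    )


def _bound_drug(conc: dict[str, float]) -> float:
    return conc["RD"] + conc["R2D"] + 2.0 * conc["R2D2"]


def _solve_R(network: ReactionNetwork, raf_total: float, D: float) -> float:
    """Free open monomer from protomer conservation at fixed free drug.

    The protomer total is strictly increasing in R, so the root is unique
    and bracketed by (0, raf_total]."""

    def h(R: float) -> float:
        return _protomer_total(network.concentrations(R, D)) - raf_total

    if h(raf_total) < 0:  # pragma: no cover - impossible for admissible input
        raise RuntimeError("conservation root not bracketed")
    return brentq(h, 0.0, raf_total, xtol=1e-300, rtol=_ROOT_RTOL)


def solve_equilibrium(
    network: ReactionNetwork,
    raf_total: float,
    drug: float,
    drug_mode: Literal["buffered", "conserved"] = "buffered",
) -> SpeciesState:
    """Numerical equilibrium state of the network.

    ``buffered`` (the default, matching the closed forms): ``drug`` is the
    free drug concentration, held fixed. ``conserved``: ``drug`` is the
    total drug; the free concentration is solved jointly with R by nested
    bracketing.
    """
    if raf_total <= 0:
        raise ValueError("raf_total must be positive")
    if drug < 0:
        raise ValueError("drug must be nonnegative")

    if drug_mode == "buffered" or drug == 0.0:
        D = drug
        R = _solve_R(network, raf_total, D)
    elif drug_mode == "conserved":

        def excess(D: float) -> float:
            R = _solve_R(network, raf_total, D)
            return D + _bound_drug(network.concentrations(R, D)) - drug

        D = brentq(excess, 0.0, drug, xtol=1e-300, rtol=_ROOT_RTOL)
        R = _solve_R(network, raf_total, D)
    else:
        raise ValueError(f"unknown drug_mode {drug_mode!r}")

    conc = network.concentrations(R, D)
    state = SpeciesState(
        A=conc["A"],
        R=conc["R"],
        RD=conc["RD"],
        R2=conc["R2"],
        R2D=conc["R2D"],
        R2D2=conc["R2D2"],
        D_free=D,
    )
    state.check_conservation(raf_total)
    return state


def write_species_table(
    params: ModelParams,
    doses: Sequence[float],
    path: str | Path,
    drug_mode: Literal["buffered", "conserved"] = "buffered",
) -> None:
    """Emit an oracle species table as CSV for use as a frozen fixture.

    Columns: dose_uM, A, R, RD, R2, R2D, R2D2, active_fraction.
    """
    net = build_network(params)
    lines = ["dose_uM,A,R,RD,R2,R2D,R2D2,active_fraction"]
    for dose in doses:
        s = solve_equilibrium(net, params.raf_total, float(dose), drug_mode)
        frac = s.active_protomers / params.raf_total
        lines.append(
            f"{dose:.10g},{s.A:.12e},{s.R:.12e},{s.RD:.12e},"
            f"{s.R2:.12e},{s.R2D:.12e},{s.R2D2:.12e},{frac:.12e}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
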