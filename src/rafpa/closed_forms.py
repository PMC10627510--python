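"""Closed-form equilibrium solutions for the four model variants.

Every quantity is a function of two dimensionless scales — ``d_rel = D/K_d``
(free drug over monomer drug affinity) and ``RAF_rel = [RAF]_tot/K_dim``
(total RAF over dimer affinity) — plus the mechanism parameters ``K_A``,
``f`` and ``g``. The solutions all share one functional shape: the free
non-autoinhibited monomer concentration R solves a quadratic whose stable
root is ``R = 2*T / (E1 + sqrt(E1^2 + E2))``, and every observable is a
rational function of that root.

Resolved functional forms (derived from the mass-action network and pinned
to the brute-force detailed-balance oracle in :mod:`rafpa.oracle`; dimer
occupancy weights within a dimer are ``1 : 2*d_rel/f : d_rel^2/(f*g)`` for
0/1/2 bound drugs):

==========  ==========================================================
baseline    CA/unified:  E3 / (1 + sqrt(1 + E3))^2,  E3 = 8*RAF_rel/(1+K_A)^2
            DP/NC:       same with K_A = 0  (E3 -> 8*RAF_rel)
active      unified:  X^2 * g*(f+d) / (E2u * (f*g + 2*g*d + d^2)),
            X = -E1 + sqrt(E1^2 + E2u),  E1 = 1 + K_A + d,
            E2u = 8*RAF_rel*(f*g + 2*g*d + d^2)/(f*g)
            CA:  X^2 / (E2c*(1+d)) with E2c = 8*RAF_rel*(1+d)^2
            DP:  Y^2 * (f+d) / (E2d*(f + 2*d + d^2)),
            Y = -E1d + sqrt(E1d^2 + E2d), E1d = f*(1+d),
            E2d = 8*f*RAF_rel*(f + 2*d + d^2)
            NC:  Z^2 * g^2*(1+d) / (E2n*(g + 2*g*d + d^2)),
            Z = -E1n + sqrt(E1n^2 + E2n/g), E1n = 1 + d,
            E2n = 8*RAF_rel*(g + 2*g*d + d^2)
dimers /    CA: (1+d)/2      DP: (f + 2d + d^2) / (2*(f+d))
active      NC: (g + 2gd + d^2) / (2*g*(1+d))
            unified: (f*g + 2*g*d + d^2) / (2*g*(f+d))
==========  ==========================================================

(The CA dimer-ratio column is (1+d)/2: each drug-free dimer carries two
active protomers at d = 0 and the ratio grows linearly with d; this is
forced both by the oracle species counts and by the unified column at
f = g = 1.)
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .params import DimensionlessGroups, ModelParams, SpeciesState, Variant

__all__ = [
    "dimensionless_groups",
    "baseline_active_fraction",
    "active_raf_fraction",
    "total_dimer_ratio",
    "species_distribution",
]

ArrayLike = Union[float, np.ndarray]

_DISC_TOL = 1e-12


def _check_drug(drug_free: ArrayLike) -> np.ndarray:
    d = np.asarray(drug_free, dtype=float)
    if np.any(d < 0):
        raise ValueError("drug concentration must be nonnegative")
    return d


def _stable_root(E1: ArrayLike, E2: ArrayLike) -> np.ndarray:
    """-E1 + sqrt(E1^2 + E2), evaluated without cancellation as
    E2 / (E1 + sqrt(E1^2 + E2)). Valid for E1 > 0, E2 >= 0."""
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    disc = E1 * E1 + E2
    if np.any(disc < -_DISC_TOL):
        raise FloatingPointError("negative discriminant in closed form")
    return E2 / (E1 + np.sqrt(disc))


def dimensionless_groups(params: ModelParams, drug_free: float) -> DimensionlessGroups:
    """All dimensionless abbreviations at one free-drug concentration.

    ``E1``-family symbols are the linear (monomer) coefficients of the
    conservation quadratic; ``E2``-family symbols are ``4 * quadratic
    coefficient * raf_total`` in dimer units; ``E3`` is the zero-drug
    limit of ``E2`` for the autoinhibited variants, rescaled by
    ``(1+K_A)^2``.
    """
    d = float(_check_drug(drug_free))
    K_A, f, g = params.K_A, params.f, params.g
    raf_rel = params.raf_rel
    return DimensionlessGroups(
        d_rel=params.d_rel(drug_free),
        RAF_rel=raf_rel,
        E1=d / params.K_d + 1.0 + K_A,
        E1d=(d / params.K_d + 1.0) * f,
        E1n=d / params.K_d + 1.0,
        E2c=8.0 * raf_rel * (1.0 + d / params.K_d) ** 2,
        E2d=8.0 * f * raf_rel * (f + 2.0 * (d / params.K_d) + (d / params.K_d) ** 2),
        E2n=8.0
        * raf_rel
        * (g + 2.0 * g * (d / params.K_d) + (d / params.K_d) ** 2),
        E2u=8.0
        * raf_rel
        * (f * g + 2.0 * g * (d / params.K_d) + (d / params.K_d) ** 2)
        / (f * g),
        E3=8.0 * raf_rel / (1.0 + K_A) ** 2,
    )


def baseline_active_fraction(params: ModelParams) -> float:
    """Drug-free active-RAF fraction (protomers in a dimer / total RAF).

    The CA and unified variants carry the ``(1+K_A)^2`` autoinhibition
    penalty through ``E3``; DP and NC are the plain dimerization
    equilibrium (``K_A = 0``).
    """
    if params.variant in (Variant.CA, Variant.UNIFIED):
        E3 = 8.0 * params.raf_rel / (1.0 + params.K_A) ** 2
    else:
        E3 = 8.0 * params.raf_rel
    # (-1 + sqrt(1 + E3))^2 / E3 without cancellation:
    return float(E3 / (1.0 + np.sqrt(1.0 + E3)) ** 2)


def active_raf_fraction(params: ModelParams, drug_free: ArrayLike) -> ArrayLike:
    """Fraction of total RAF that is active: in a dimer and not drug-bound.

    Vectorized over ``drug_free`` (uM). Continuous in dose; equals
    :func:`baseline_active_fraction` at zero drug and tends to 0 as the
    drug saturates every dimer site.
    """
    d = _check_drug(drug_free) / params.K_d
    raf_rel = params.raf_rel
    f, g, K_A = params.f, params.g, params.K_A
    v = params.variant

    if v is Variant.DP:
        E1d = f * (1.0 + d)
        poly = f + 2.0 * d + d * d
        E2d = 8.0 * f * raf_rel * poly
        Y = _stable_root(E1d, E2d)
        out = Y * Y * (f + d) / (E2d * poly)
    elif v is Variant.NC:
        E1n = 1.0 + d
        poly = g + 2.0 * g * d + d * d
        E2n = 8.0 * raf_rel * poly
        Z = _stable_root(E1n, E2n / g)
        out = Z * Z * (g * g) * (1.0 + d) / (E2n * poly)
    else:  # CA and UNIFIED share the (1 + K_A)-containing form
        fe = 1.0 if v is Variant.CA else f
        ge = 1.0 if v is Variant.CA else g
        E1 = 1.0 + K_A + d
        poly = fe * ge + 2.0 * ge * d + d * d
        E2u = 8.0 * raf_rel * poly / (fe * ge)
        X = _stable_root(E1, E2u)
        out = X * X * ge * (fe + d) / (E2u * poly)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def total_dimer_ratio(params: ModelParams, drug_free: ArrayLike) -> ArrayLike:
    """Total RAF dimers relative to active RAF protomers.

    Equals 1/2 at zero drug for every variant (each drug-free dimer carries
    exactly two active protomers) and grows with dose as drug-bound dimers
    accumulate. A zero active-RAF level (possible only in degenerate limits)
    is signalled explicitly.
    """
    active = active_raf_fraction(params, drug_free)
    if np.any(np.asarray(active) == 0.0):
        raise ZeroDivisionError("active RAF is zero; dimer ratio undefined")
    d = _check_drug(drug_free) / params.K_d
    f, g = params.f, params.g
    v = params.variant
    if v is Variant.CA:
        out = (1.0 + d) / 2.0
    elif v is Variant.DP:
        out = (f + 2.0 * d + d * d) / (2.0 * (f + d))
    elif v is Variant.NC:
        out = (g + 2.0 * g * d + d * d) / (2.0 * g * (1.0 + d))
    else:
        out = (f * g + 2.0 * g * d + d * d) / (2.0 * g * (f + d))
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def _effective_fga(params: ModelParams) -> tuple[float, float, float]:
    """(f, g, K_A) with the variant's neutral pins applied."""
    v = params.variant
    if v is Variant.CA:
        return 1.0, 1.0, params.K_A
    if v is Variant.DP:
        return params.f, 1.0, 0.0
    if v is Variant.NC:
        return 1.0, params.g, 0.0
    return params.f, params.g, params.K_A


def species_distribution(params: ModelParams, drug_free: float) -> SpeciesState:
    """Full six-species decomposition at one free-drug concentration.

    Solves the conservation quadratic for the free non-autoinhibited
    monomer R and propagates the pairwise equilibria; consistent with
    :func:`active_raf_fraction` by construction
    (``2*R2 + R2D = active_fraction * raf_total``).
    """
    drug = float(_check_drug(drug_free))
    d = drug / params.K_d
    f, g, K_A = _effective_fga(params)
    K_dim, T = params.K_dim, params.raf_total

    # dimer occupancy weights relative to R^2/K_dim
    w1 = 2.0 * d / f
    w2 = d * d / (f * g)
    P = 1.0 + w1 + w2
    E1 = 1.0 + K_A + d
    E2 = 8.0 * (T / K_dim) * P
    disc = E1 * E1 + E2
    if disc < -_DISC_TOL:
        raise FloatingPointError("negative discriminant in species solve")
    R = 2.0 * T / (E1 + np.sqrt(disc))
    R2 = R * R / K_dim
    return SpeciesState(
        A=K_A * R,
        R=R,
        RD=R * d,
        R2=R2,
        R2D=w1 * R2,
        R2D2=w2 * R2,
        D_free=drug,
    )
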