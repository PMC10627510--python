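"""Dose–response curves, paradoxical-activation metrics and phase maps.

Paradoxical activation (PA) is an *increase* of active RAF above its
drug-free baseline at intermediate inhibitor concentrations, with
inhibition recovered at high concentrations. Two scalar summaries are
used throughout:

* **PA fold change** — peak activity over baseline activity (>= 1).
* **PA range** — the dose interval over which activity exceeds baseline;
  its upper endpoint is the baseline re-crossing, which makes it robust
  to monotone transformations of the readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .closed_forms import active_raf_fraction, baseline_active_fraction, total_dimer_ratio
from .params import DoseGrid, ModelParams, Variant

__all__ = [
    "DoseResponse",
    "PAMetrics",
    "PACondition",
    "PhaseScan",
    "dose_response",
    "pa_metrics",
    "pa_condition",
    "phase_scan",
    "dose_response_to_csv",
    "phase_scan_to_csv",
]

# dose endpoints located to 1e-4 relative; activity compared at 1e-9 absolute
DOSE_RTOL = 1e-4
ACTIVITY_ATOL = 1e-9


@dataclass(frozen=True)
class DoseResponse:
    """Active-RAF levels across a drug concentration grid."""

    params: ModelParams
    grid: DoseGrid
    active_fraction: np.ndarray
    active_normalized: np.ndarray
    dimer_total_uM: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name in ("active_fraction", "active_normalized", "dimer_total_uM"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match grid")


@dataclass(frozen=True)
class PAMetrics:
    """Scalar PA summaries of one dose–response."""

    baseline: float
    peak: float
    peak_dose_uM: float
    pa_fold_change: float
    pa_range_uM: Optional[tuple[float, float]]  # None when no PA
    has_pa: bool


@dataclass(frozen=True)
class PACondition:
    """Outcome of the analytic PA-condition predicate.

    ``pa_predicted`` is ``True``/``False`` for a decided case and ``None``
    (indeterminate) when a *sufficient-only* condition fails: PA may still
    occur and must then be decided numerically. ``condition_kind`` records
    the logical strength of the printed condition for the variant.
    """

    pa_predicted: Optional[bool]
    condition_kind: str  # necessary_and_sufficient | sufficient | impossible


def dose_response(params: ModelParams, grid: DoseGrid) -> DoseResponse:
    """Evaluate the closed-form active fraction over a dose grid."""
    doses = grid.array
    frac = np.atleast_1d(active_raf_fraction(params, doses))
    ratio = np.atleast_1d(total_dimer_ratio(params, doses))
    dimers = ratio * frac * params.raf_total
    peak = frac.max()
    normalized = frac / peak if peak > 0 else frac.copy()
    return DoseResponse(params, grid, frac, normalized, dimers)


def _refine_peak(params: ModelParams, doses: np.ndarray, i: int) -> tuple[float, float]:
    """Golden-section refinement of the grid maximum between its
    bracketing grid points. Returns (peak_dose, peak_value)."""
    lo = doses[i - 1] if i > 0 else doses[i]
    hi = doses[i + 1] if i + 1 < len(doses) else doses[i]
    if hi <= lo:
        return doses[i], float(active_raf_fraction(params, doses[i]))
    res = minimize_scalar(
        lambda d: -active_raf_fraction(params, d),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": max(DOSE_RTOL * max(hi, 1e-30), 1e-30)},
    )
    cand_d, cand_v = float(res.x), float(-res.fun)
    grid_v = float(active_raf_fraction(params, doses[i]))
    if grid_v >= cand_v:
        return float(doses[i]), grid_v
    return cand_d, cand_v


def pa_metrics(dr: DoseResponse, tol: float = ACTIVITY_ATOL) -> PAMetrics:
    """PA fold change and PA range of a dose–response.

    The peak is the grid maximum refined locally; range endpoints are the
    baseline crossings of ``activity(d) - baseline``, located by bisection
    between bracketing grid points.
    """
    doses = dr.grid.array
    if doses[0] != 0.0:
        raise ValueError("dose 0 must be present to define the baseline")
    baseline = float(dr.active_fraction[0])
    if len(doses) == 1:
        return PAMetrics(baseline, baseline, 0.0, 1.0, None, False)

    i = int(np.argmax(dr.active_fraction))
    peak_dose, peak = _refine_peak(dr.params, doses, i)
    if peak < baseline:  # baseline is the true maximum
        peak, peak_dose = baseline, 0.0
    fold = peak / baseline if baseline > 0 else 1.0
    has_pa = peak > baseline + tol
    if not has_pa:
        return PAMetrics(baseline, peak, peak_dose, max(fold, 1.0), None, False)

    def excess(d: float) -> float:
        return float(active_raf_fraction(dr.params, d)) - baseline

    above = dr.active_fraction > baseline + tol
    idx = np.nonzero(above[1:])[0] + 1  # ignore the baseline point itself

    # lower endpoint: first entry into the PA region
    j = idx[0]
    if j == 1 or excess(doses[j - 1]) > 0:
        lo = 0.0 if excess(doses[1]) > 0 and j == 1 else doses[j - 1]
        if lo > 0 and excess(lo) > 0:
            lo = 0.0  # activity already above baseline at the first grid step
    else:
        lo = brentq(excess, doses[j - 1], doses[j], rtol=DOSE_RTOL)
    # Immediate rise from zero dose: the region starts at 0
    if j == 1:
        lo = 0.0

    # upper endpoint: baseline re-crossing after the peak
    k = idx[-1]
    if k + 1 < len(doses) and excess(doses[k + 1]) < 0:
        hi = brentq(excess, doses[k], doses[k + 1], rtol=DOSE_RTOL)
    else:
        hi = float("inf")  # not re-crossed within the grid
    return PAMetrics(baseline, peak, peak_dose, fold, (float(lo), float(hi)), True)


def pa_condition(params: ModelParams) -> PACondition:
    """Analytic PA-condition predicate for the variant.

    * CA — necessary and sufficient: PA occurs iff
      ``RAF_rel < (1 + 3*K_A) * (K_A - 1) / 8`` (so never for K_A <= 1:
      the autoinhibited form must be favored at equilibrium).
    * DP — sufficient: ``f < 1/2`` and ``8*RAF_rel < (1 - 2f)(3 - 2f)``.
    * NC — PA impossible.
    * unified — sufficient: ``g >= 1``, ``2f < 1 + K_A`` and
      ``8*RAF_rel < (1 + K_A - 2f)(3*(1 + K_A) - 2f)``; reduces to the CA
      condition at f = g = 1 and to the DP condition at K_A = 0.

    Sufficient-only conditions return *indeterminate* (``None``) when the
    inequality fails — PA may still be decided numerically.
    """
    raf_rel = params.raf_rel
    v = params.variant
    if v is Variant.NC:
        return PACondition(False, "impossible")
    if v is Variant.CA:
        ok = raf_rel < (1.0 + 3.0 * params.K_A) * (params.K_A - 1.0) / 8.0
        return PACondition(bool(ok), "necessary_and_sufficient")
    if v is Variant.DP:
        f = params.f
        ok = f < 0.5 and 8.0 * raf_rel < (1.0 - 2.0 * f) * (3.0 - 2.0 * f)
        return PACondition(True if ok else None, "sufficient")
    f, g, K_A = params.f, params.g, params.K_A
    ok = (
        g >= 1.0
        and 2.0 * f < 1.0 + K_A
        and 8.0 * raf_rel < (1.0 + K_A - 2.0 * f) * (3.0 * (1.0 + K_A) - 2.0 * f)
    )
    return PACondition(True if ok else None, "sufficient")


@dataclass(frozen=True)
class PhaseScan:
    """PA fold change and range over a (K_A, raf_total) parameter plane."""

    K_A_grid: np.ndarray
    raf_total_grid: np.ndarray  # uM
    fold_change: np.ndarray  # shape (len(K_A), len(raf))
    range_lo_uM: np.ndarray  # NaN where no PA
    range_hi_uM: np.ndarray


def phase_scan(
    variant: Variant,
    K_A_grid: Sequence[float],
    raf_total_grid: Sequence[float],
    *,
    K_dim: float = 0.1,
    K_d: float = 0.1,
    f: float = 1.0,
    g: float = 1.0,
    dose_grid: DoseGrid | None = None,
) -> PhaseScan:
    """Dense PA map over autoinhibition strength and RAF abundance."""
    if dose_grid is None:
        dose_grid = DoseGrid.log(1e-5 * K_d / 0.1, 1e4 * K_d / 0.1, 10)
    K_As = np.asarray(K_A_grid, dtype=float)
    rafs = np.asarray(raf_total_grid, dtype=float)
    shape = (len(K_As), len(rafs))
    fold = np.ones(shape)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    for a, K_A in enumerate(K_As):
        for b, raf in enumerate(rafs):
            p = ModelParams(
                K_A=K_A, K_dim=K_dim, K_d=K_d, f=f, g=g,
                raf_total=raf, variant=variant,
            )
            m = pa_metrics(dose_response(p, dose_grid))
            fold[a, b] = m.pa_fold_change
            if m.pa_range_uM is not None:
                lo[a, b], hi[a, b] = m.pa_range_uM
    return PhaseScan(K_As, rafs, fold, lo, hi)


def dose_response_to_csv(dr: DoseResponse, path: str | Path, header: str = "") -> None:
    lines = [header] if header else []
    lines.append("dose_uM,active_fraction,active_normalized,dimer_total_uM")
    for d, af, an, dt in zip(
        dr.grid.array, dr.active_fraction, dr.active_normalized, dr.dimer_total_uM
    ):
        lines.append(f"{d:.10g},{af:.12e},{an:.12e},{dt:.12e}")
    Path(path).write_text("\n".join(lines) + "\n")


def phase_scan_to_csv(scan: PhaseScan, path: str | Path, header: str = "") -> None:
    """Long-format export: K_A, raf_total_uM, fold_change, range_lo_uM, range_hi_uM."""
    lines = [header] if header else []
    lines.append("K_A,raf_total_uM,fold_change,range_lo_uM,range_hi_uM")
    for a, K_A in enumerate(scan.K_A_grid):
        for b, raf in enumerate(scan.raf_total_grid):
            lines.append(
                f"{K_A:.10g},{raf:.10g},{scan.fold_change[a, b]:.10g},"
                f"{scan.range_lo_uM[a, b]:.10g},{scan.range_hi_uM[a, b]:.10g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
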