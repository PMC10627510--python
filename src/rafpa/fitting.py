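"""Inverse problem: fit the unified model to normalized dose–response panels.

The data are a drugs x doses matrix of max-normalized active-RAF readouts.
One autoinhibition constant ``K_A`` is shared across drugs (it is a
property of the cell, not of the inhibitor) while ``K_d``, ``f`` and ``g``
are drug-specific; RAF abundance and the drug-free dimer constant are fixed
by default (0.04 uM and 0.1 uM) but can be freed, at the cost of a known
``K_dim``–``K_A`` non-identifiability.

The protocol is multi-start bounded local optimization: starts are drawn
log-uniformly inside the box bounds, each start runs SLSQP on the
log-transformed parameters, and the reported ensemble is every converged
solution whose metric is within 10% of the best one. Two metrics are used:

* ``chisq`` — mean squared relative deviation (the fitting objective),
* ``absolute`` — mean absolute relative deviation; x100 it is the
  "mean percentage error" used to compare sub-models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "METHODS_BOUNDS",
    "ParameterLayout",
    "FitProblem",
    "FitResult",
    "IdentifiabilityReport",
    "fit_metric_chisq",
    "fit_metric_absolute",
    "predict_matrix",
    "multistart_fit",
    "compare_submodels",
    "identifiability_report",
    "read_dose_response_csv",
]

GLOBAL_NAMES = ("K_A", "K_dim", "raf_total")
PER_DRUG_NAMES = ("K_d", "f", "g")

# box bounds of the fitting search domain (uM where dimensional)
METHODS_BOUNDS: dict[str, tuple[float, float]] = {
    "f": (1e-5, 1e2),
    "g": (1.0, 1e4),
    "K_A": (1e-3, 1e2),
    "K_d": (1e-4, 1e4),
    "K_dim": (1e-4, 1e4),
    "raf_total": (1e-4, 1e3),
}

DEFAULT_FIXED = {"K_dim": 0.1, "raf_total": 0.04}

_PENALTY = 1e6


def _active_unified(K_A, K_dim, K_d, f, g, raf_total, doses):
    """Vectorized unified-model active fraction.

    Per-drug parameters are 1-D arrays of length n_drugs; ``doses`` is an
    (n_drugs, n_doses) matrix. Shares its algebra with
    :func:`rafpa.closed_forms.active_raf_fraction` but avoids per-call
    object construction for speed inside the optimizer loop.
    """
    d = doses / np.asarray(K_d)[:, None]
    f = np.asarray(f)[:, None]
    g = np.asarray(g)[:, None]
    raf_rel = raf_total / K_dim
    E1 = 1.0 + K_A + d
    poly = f * g + 2.0 * g * d + d * d
    E2 = 8.0 * raf_rel * poly / (f * g)
    X = E2 / (E1 + np.sqrt(E1 * E1 + E2))
    return X * X * g * (f + d) / (E2 * poly)


@dataclass(frozen=True)
class ParameterLayout:
    """Which parameters are free (global vs per drug) and which are pinned.

    ``fixed`` supplies the value of every non-free parameter; a per-drug
    pin (e.g. ``f = 1`` for a no-DP sub-model) applies to all drugs.
    """

    drugs: tuple[str, ...]
    global_free: tuple[str, ...] = ("K_A",)
    per_drug_free: tuple[str, ...] = ("K_d", "f", "g")
    fixed: dict = field(default_factory=lambda: dict(DEFAULT_FIXED))
    bounds: dict = field(default_factory=lambda: dict(METHODS_BOUNDS))

    def __post_init__(self) -> None:
        for name in self.global_free:
            if name not in GLOBAL_NAMES:
                raise ValueError(f"unknown global parameter {name!r}")
        for name in self.per_drug_free:
            if name not in PER_DRUG_NAMES:
                raise ValueError(f"unknown per-drug parameter {name!r}")
        free = set(self.global_free) | set(self.per_drug_free)
        for name in GLOBAL_NAMES + PER_DRUG_NAMES:
            if name not in free and name not in self.fixed and name not in ("f", "g"):
                raise ValueError(f"parameter {name!r} neither free nor fixed")

    @property
    def n_params(self) -> int:
        return len(self.global_free) + len(self.drugs) * len(self.per_drug_free)

    @property
    def names(self) -> list[str]:
        out = list(self.global_free)
        for drug in self.drugs:
            out.extend(f"{drug}:{p}" for p in self.per_drug_free)
        return out

    def _value(self, name: str, default: float = 1.0) -> float:
        return float(self.fixed.get(name, default))

    def unpack(self, theta: np.ndarray) -> dict:
        """Linear-space vector -> full parameter set (globals + per-drug arrays)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError("parameter vector does not match layout")
        out: dict = {}
        k = len(self.global_free)
        for name in GLOBAL_NAMES:
            if name in self.global_free:
                out[name] = theta[self.global_free.index(name)]
            else:
                out[name] = self._value(name, {"K_A": 0.0}.get(name, 1.0))
        per = theta[k:].reshape(len(self.drugs), len(self.per_drug_free))
        for name in PER_DRUG_NAMES:
            if name in self.per_drug_free:
                out[name] = per[:, self.per_drug_free.index(name)].copy()
            else:
                out[name] = np.full(len(self.drugs), self._value(name, 1.0))
        return out

    def pack(self, values: dict) -> np.ndarray:
        """Full parameter set -> linear-space vector (inverse of unpack)."""
        head = [float(values[name]) for name in self.global_free]
        tail = []
        for i in range(len(self.drugs)):
            for name in self.per_drug_free:
                tail.append(float(np.asarray(values[name]).reshape(-1)[i]))
        return np.asarray(head + tail)

    @property
    def log_bounds(self) -> list[tuple[float, float]]:
        out = []
        for name in self.global_free:
            lo, hi = self.bounds[name]
            out.append((np.log10(lo), np.log10(hi)))
        for _ in self.drugs:
            for name in self.per_drug_free:
                lo, hi = self.bounds[name]
                out.append((np.log10(lo), np.log10(hi)))
        return out


@dataclass(frozen=True)
class FitProblem:
    """Observed panel plus the parameter layout and normalization convention.

    ``Y`` is the (n_drugs, n_doses) max-normalized observed matrix;
    ``dose_grids`` the matching dose matrix in uM. Predictions are
    normalized exactly as the data were (per-drug maximum) before any
    metric is evaluated.
    """

    Y: np.ndarray
    dose_grids: np.ndarray
    layout: ParameterLayout

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        grids = np.asarray(self.dose_grids, dtype=float)
        if Y.ndim != 2 or Y.shape != grids.shape:
            raise ValueError("Y and dose_grids must be matching 2-D arrays")
        if Y.shape[0] != len(self.layout.drugs):
            raise ValueError("row count does not match layout drugs")
        if not np.all(np.isfinite(Y)) or np.any(Y <= 0):
            raise ValueError("observations must be finite and positive")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "dose_grids", grids)

    @property
    def drugs(self) -> tuple[str, ...]:
        return self.layout.drugs

    def with_layout(self, layout: ParameterLayout) -> "FitProblem":
        return FitProblem(self.Y, self.dose_grids, layout)


def fit_metric_chisq(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean over all points of ((pred - obs)/obs)^2."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("shape mismatch")
    if np.any(obs == 0):
        raise ValueError("zero observation in relative metric")
    return float(np.mean(((pred - obs) / obs) ** 2))


def fit_metric_absolute(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean over all points of |pred - obs|/obs (proportionate deviation)."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("shape mismatch")
    if np.any(obs == 0):
        raise ValueError("zero observation in relative metric")
    return float(np.mean(np.abs(pred - obs) / obs))


_METRICS = {"chisq": fit_metric_chisq, "absolute": fit_metric_absolute}


def predict_matrix(theta: np.ndarray, problem: FitProblem) -> np.ndarray:
    """Predicted normalized panel for a linear-space parameter vector."""
    v = problem.layout.unpack(theta)
    raw = _active_unified(
        v["K_A"], v["K_dim"], v["K_d"], v["f"], v["g"], v["raf_total"],
        problem.dose_grids,
    )
    peak = raw.max(axis=1, keepdims=True)
    if np.any(peak <= 0) or not np.all(np.isfinite(peak)):
        raise FloatingPointError("degenerate prediction (zero or non-finite peak)")
    return raw / peak


@dataclass(frozen=True)
class FitResult:
    """Ensemble of best fits (metric within 10% of the minimum)."""

    param_names: tuple[str, ...]
    drugs: tuple[str, ...]
    ensemble: np.ndarray  # (n_members, n_params), linear space
    metrics: np.ndarray  # (n_members,)
    best: np.ndarray  # linear space
    best_metric: float
    curves_mean: np.ndarray  # (n_drugs, n_doses)
    curves_std: np.ndarray
    dose_grids: np.ndarray
    n_starts: int
    n_converged: int
    seed: int
    metric_name: str

    @property
    def n_members(self) -> int:
        return self.ensemble.shape[0]

    def ensemble_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ensemble, columns=list(self.param_names))
        df.insert(0, "metric", self.metrics)
        return df

    def best_params(self) -> dict:
        return dict(zip(self.param_names, self.best))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "param_names": list(self.param_names),
            "drugs": list(self.drugs),
            "best": self.best.tolist(),
            "best_metric": self.best_metric,
            "ensemble_size": int(self.n_members),
            "metrics": self.metrics.tolist(),
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "seed": self.seed,
            "metric_name": self.metric_name,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def ensemble_to_csv(self, path: str | Path, header: str = "") -> None:
        text = self.ensemble_frame().to_csv(index=False)
        Path(path).write_text((header + "\n" if header else "") + text)

    def curves_to_csv(self, path: str | Path, header: str = "") -> None:
        rows = []
        for i, drug in enumerate(self.drugs):
            for j in range(self.dose_grids.shape[1]):
                rows.append(
                    {
                        "drug": drug,
                        "dose_uM": self.dose_grids[i, j],
                        "predicted_mean": self.curves_mean[i, j],
                        "predicted_std": self.curves_std[i, j],
                    }
                )
        text = pd.DataFrame(rows).to_csv(index=False)
        Path(path).write_text((header + "\n" if header else "") + text)


def _objective(theta_log: np.ndarray, problem: FitProblem, metric) -> float:
    try:
        pred = predict_matrix(10.0 ** theta_log, problem)
    except FloatingPointError:
        return _PENALTY
    val = metric(pred, problem.Y)
    return val if np.isfinite(val) else _PENALTY


def _refine_drug_blocks(
    theta_log: np.ndarray,
    problem: FitProblem,
    metric,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
    inner_starts: int,
) -> np.ndarray:
    """Block-coordinate rescue: re-fit each drug's own parameters.

    Given the shared globals, the metric decomposes over drug rows, so a
    drug stuck in a wrong local basin can be refit on its 2–3 own
    parameters from a handful of fresh log-uniform starts without
    disturbing the rest. Returns the (possibly improved) full vector.
    """
    layout = problem.layout
    k = len(layout.global_free)
    m = len(layout.per_drug_free)
    if m == 0 or inner_starts <= 0:
        return theta_log
    theta_log = theta_log.copy()
    for i, _ in enumerate(layout.drugs):
        sl = slice(k + i * m, k + (i + 1) * m)

        def row_obj(x_block: np.ndarray) -> float:
            full = theta_log.copy()
            full[sl] = x_block
            try:
                pred = predict_matrix(10.0 ** full, problem)
            except FloatingPointError:
                return _PENALTY
            val = metric(pred[i : i + 1], problem.Y[i : i + 1])
            return val if np.isfinite(val) else _PENALTY

        best_x = theta_log[sl].copy()
        best_v = row_obj(best_x)
        starts = [best_x] + list(
            rng.uniform(lb[sl], ub[sl], size=(inner_starts, m))
        )
        for x0 in starts:
            res = minimize(
                row_obj,
                x0,
                method="SLSQP",
                bounds=list(zip(lb[sl], ub[sl])),
                options={"ftol": 1e-10, "maxiter": 150},
            )
            if np.isfinite(res.fun) and res.fun < best_v:
                best_v = float(res.fun)
                best_x = np.clip(res.x, lb[sl], ub[sl])
        theta_log[sl] = best_x
    return theta_log


def multistart_fit(
    problem: FitProblem,
    n_starts: int = 100,
    seed: int = 0,
    metric: Literal["chisq", "absolute"] = "chisq",
    ensemble_window: float = 1.1,
    maxiter: int = 300,
    inner_starts: int = 5,
) -> FitResult:
    """Multi-start bounded SLSQP fit over log-transformed parameters.

    Starts are log-uniform within the box bounds. Each start runs a joint
    SLSQP solve, a block-coordinate per-drug rescue pass (the metric
    decomposes over drug rows given the shared globals, so each drug's
    2–3 parameters can be refit from ``inner_starts`` fresh positions),
    and a final joint SLSQP polish to a stationary point. Individual
    convergence failures are skipped. The returned ensemble contains
    every completed solution whose metric is within ``ensemble_window``
    of the minimum (default: 10%). Fully reproducible from ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    layout = problem.layout
    mfun = _METRICS[metric]
    lb = np.array([b[0] for b in layout.log_bounds])
    ub = np.array([b[1] for b in layout.log_bounds])
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lb, ub, size=(n_starts, layout.n_params))
    bounds = list(zip(lb, ub))
    opts = {"ftol": 1e-10, "maxiter": maxiter}

    sols: list[np.ndarray] = []
    vals: list[float] = []
    n_converged = 0
    for x0 in starts:
        res = minimize(
            _objective, x0, args=(problem, mfun),
            method="SLSQP", bounds=bounds, options=opts,
        )
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        x = np.clip(res.x, lb, ub)
        refined = _refine_drug_blocks(x, problem, mfun, lb, ub, rng, inner_starts)
        if not np.array_equal(refined, x):
            res = minimize(
                _objective, refined, args=(problem, mfun),
                method="SLSQP", bounds=bounds, options=opts,
            )
            if np.isfinite(res.fun) and res.fun < _PENALTY:
                x = np.clip(res.x, lb, ub)
        if res.success:
            n_converged += 1
        sols.append(x)
        vals.append(float(_objective(x, problem, mfun)))
    if not sols:
        raise RuntimeError(
            f"all {n_starts} starts failed to produce a finite fit "
            f"(bounds {layout.bounds}, metric {metric})"
        )

    vals_arr = np.asarray(vals)
    order = np.argsort(vals_arr, kind="stable")
    best_val = float(vals_arr[order[0]])
    keep = [i for i in order if vals_arr[i] <= ensemble_window * max(best_val, 1e-300)]
    ensemble_log = np.array([sols[i] for i in keep])
    ensemble = 10.0 ** ensemble_log
    metrics = vals_arr[keep]

    curves = np.stack([predict_matrix(t, problem) for t in ensemble])
    return FitResult(
        param_names=tuple(layout.names),
        drugs=layout.drugs,
        ensemble=ensemble,
        metrics=metrics,
        best=ensemble[0],
        best_metric=best_val,
        curves_mean=curves.mean(axis=0),
        curves_std=curves.std(axis=0),
        dose_grids=problem.dose_grids,
        n_starts=n_starts,
        n_converged=n_converged,
        seed=seed,
        metric_name=metric,
    )


# -- sub-model comparison ---------------------------------------------------

SUBMODELS: dict[str, dict] = {
    # pins applied on top of the unified layout; name -> {param: fixed value}
    "UNIFIED": {},
    "no-NC": {"g": 1.0},
    "no-DP": {"f": 1.0},
    "no-CA": {"K_A": 0.0},
    "CA-only": {"f": 1.0, "g": 1.0},
    "DP-only": {"K_A": 0.0, "g": 1.0},
    "NC-only": {"K_A": 0.0, "f": 1.0},
}


def submodel_layout(layout: ParameterLayout, name: str) -> ParameterLayout:
    """Unified layout with the named mechanism(s) pinned to neutral values."""
    pins = SUBMODELS[name]
    global_free = tuple(p for p in layout.global_free if p not in pins)
    per_drug_free = tuple(p for p in layout.per_drug_free if p not in pins)
    fixed = dict(layout.fixed)
    fixed.update(pins)
    return replace(
        layout, global_free=global_free, per_drug_free=per_drug_free, fixed=fixed
    )


def compare_submodels(
    problem: FitProblem,
    variants: Sequence[str] = ("UNIFIED", "no-NC", "no-DP", "no-CA"),
    n_starts: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each mechanism-excluded sub-model to the same panel.

    Each variant runs the same multi-start protocol, optimizing the
    absolute (proportionate-deviation) metric; the table reports the best
    value x100 as mean percentage error, sorted ascending.
    """
    rows = []
    for i, name in enumerate(variants):
        sub = problem.with_layout(submodel_layout(problem.layout, name))
        res = multistart_fit(
            sub, n_starts=n_starts, seed=seed + i, metric="absolute"
        )
        rows.append(
            {
                "variant": name,
                "mean_pct_error": 100.0 * res.best_metric,
                "n_free_params": sub.layout.n_params,
                "ensemble_size": res.n_members,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("mean_pct_error").reset_index(drop=True)
    )


# -- identifiability --------------------------------------------------------


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Ensemble spread per parameter plus strongly correlated pairs."""

    summary: pd.DataFrame  # columns: parameter, min, max, cv
    correlated_pairs: tuple[tuple[str, str, float], ...]  # |r| > threshold

    def correlation(self, a: str, b: str) -> float:
        for x, y, r in self.correlated_pairs:
            if {x, y} == {a, b}:
                return r
        raise KeyError(f"pair ({a}, {b}) not flagged")


def identifiability_report(
    result: FitResult, corr_threshold: float = 0.9
) -> IdentifiabilityReport:
    """Structural-identifiability diagnostics from the best-fit ensemble.

    Well-constrained parameters have a narrow [min, max] interval and a
    small coefficient of variation; parameter pairs trading off along a
    ridge show up as |Pearson r| > ``corr_threshold`` on log10-scaled
    ensemble values.
    """
    if result.n_members < 2:
        if result.n_members == 0:
            raise ValueError("empty ensemble")
    ens = result.ensemble
    names = result.param_names
    summary = pd.DataFrame(
        {
            "parameter": names,
            "min": ens.min(axis=0),
            "max": ens.max(axis=0),
            "cv": ens.std(axis=0) / np.maximum(ens.mean(axis=0), 1e-300),
        }
    )
    pairs: list[tuple[str, str, float]] = []
    if result.n_members >= 2:
        logs = np.log10(ens)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(logs, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = corr[i, j]
                if np.isfinite(r) and abs(r) > corr_threshold:
                    pairs.append((names[i], names[j], float(r)))
    return IdentifiabilityReport(summary, tuple(pairs))


# -- IO ---------------------------------------------------------------------


def read_dose_response_csv(
    path: str | Path, layout_kwargs: dict | None = None
) -> FitProblem:
    """Load a (drug, dose_uM, response_normalized) CSV as a FitProblem.

    Dose counts must be balanced across drugs (the metrics average over a
    rectangular matrix). Lines starting with '#' are ignored.
    """
    df = pd.read_csv(path, comment="#")
    required = {"drug", "dose_uM", "response_normalized"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    drugs = tuple(dict.fromkeys(df["drug"]))
    counts = df.groupby("drug").size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced panel: all drugs need the same dose count")
    n_doses = int(counts.iloc[0])
    Y = np.empty((len(drugs), n_doses))
    grids = np.empty_like(Y)
    for i, drug in enumerate(drugs):
        sub = df[df["drug"] == drug].sort_values("dose_uM")
        grids[i] = sub["dose_uM"].to_numpy()
        Y[i] = sub["response_normalized"].to_numpy()
    layout = ParameterLayout(drugs=drugs, **(layout_kwargs or {}))
    return FitProblem(Y, grids, layout)
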