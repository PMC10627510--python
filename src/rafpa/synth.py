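"""Synthetic dose–response panels with known ground truth.

Emulates the statistical design of a cell-line RAF-inhibitor panel — nine
drugs, seven inhibitor concentrations each, max-normalized active-RAF
readouts (63 points) — from unified-model ground truth, so that the
fitting pipeline can be exercised as a parameter-recovery experiment.

Drugs are drawn from three archetypes mirroring the kinase-inhibitor type
classification:

* ``type_I`` — strong dimer potentiation (f well below 1), potent binding;
* ``type_I5`` — weaker potentiation and weaker binding (larger K_d);
* ``type_II`` — f near 1 (little or no potentiation).

The archetype parameter ranges are package choices (documented constants
sitting inside the fitting search bounds, with non-overlapping f ranges),
not measured values. Noise is multiplicative log-normal — readouts are
positive band-intensity-like quantities — with a default 5% coefficient of
variation, and each drug's curve is re-normalized to its maximum *after*
noise, as real normalized blots are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitProblem, ParameterLayout
from .params import ModelParams, Variant

__all__ = [
    "DrugArchetype",
    "ARCHETYPES",
    "SyntheticPanel",
    "make_panel",
    "simulate_responses",
    "write_panel",
    "read_panel",
    "DEFAULT_SHARED",
    "DEFAULT_DOSES_UM",
]


@dataclass(frozen=True)
class DrugArchetype:
    """Log-uniform generating ranges for one inhibitor class."""

    label: str
    K_d_range: tuple[float, float]  # uM
    f_range: tuple[float, float]
    g_range: tuple[float, float]

    def sample(self, rng: np.random.Generator) -> dict:
        def lu(lo: float, hi: float) -> float:
            return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

        return {
            "K_d": lu(*self.K_d_range),
            "f": lu(*self.f_range),
            "g": lu(*self.g_range),
        }


# Non-overlapping f ranges order the archetypes type_I < type_I5 < type_II;
# K_d separates type I (potent) from type I.5 (weak); all within the fitting
# search bounds. Negative cooperativity is strong (g >> 1) for every class:
# with g in the hundreds the high-dose fall of each curve is governed by
# monomer capture at K_d, which keeps K_d and f identifiable from a 7-point
# curve while leaving g itself only weakly constrained.
ARCHETYPES: dict[str, DrugArchetype] = {
    "type_I": DrugArchetype("type_I", K_d_range=(2e-3, 2e-2),
                            f_range=(1e-2, 5e-2), g_range=(1e2, 1e3)),
    "type_I5": DrugArchetype("type_I5", K_d_range=(1e-1, 1e0),
                             f_range=(1e-1, 4e-1), g_range=(1e2, 1e3)),
    "type_II": DrugArchetype("type_II", K_d_range=(5e-3, 5e-2),
                             f_range=(0.7, 1.4), g_range=(1e2, 1e3)),
}

# shared cellular context: autoinhibited-favored, sub-K_dim RAF abundance
DEFAULT_SHARED = {"K_A": 10.0, "K_dim": 0.1, "raf_total": 0.04}

# seven decade-spaced inhibitor concentrations, uM. The window (10 pM .. 10
# uM) brackets every archetype's response features: the low-dose rise of a
# potentiated binder sits near f*K_d (>= 2e-5 uM for the ranges above) and
# the inhibitory tail near K_d, so each drug's curve is informative about
# its own parameters.
DEFAULT_DOSES_UM = tuple(np.logspace(-5.0, 1.0, 7))


@dataclass(frozen=True)
class SyntheticPanel:
    """A generated panel plus its ground truth and noise bookkeeping."""

    drugs: tuple[str, ...]
    archetypes: tuple[str, ...]
    ground_truth: Optional[tuple[ModelParams, ...]]
    shared: dict
    dose_grids: np.ndarray  # (n_drugs, n_doses), uM
    noiseless: Optional[np.ndarray] = None  # max-normalized, noise-free
    noisy: Optional[np.ndarray] = None  # max-normalized after noise
    noise_cv: Optional[float] = None
    seed: Optional[int] = None

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def to_fit_problem(self, layout_kwargs: dict | None = None) -> FitProblem:
        if self.noisy is None:
            raise ValueError("panel has no simulated responses yet")
        layout = ParameterLayout(drugs=self.drugs, **(layout_kwargs or {}))
        return FitProblem(self.noisy, self.dose_grids, layout)


def _normalize_mix(n_drugs: int, archetype_mix) -> list[str]:
    if isinstance(archetype_mix, Mapping):
        labels = [lab for lab, k in archetype_mix.items() for _ in range(int(k))]
    else:
        labels = list(archetype_mix)
    if not labels:
        raise ValueError("empty archetype mix")
    if len(labels) != n_drugs:
        raise ValueError(f"archetype mix covers {len(labels)} drugs, need {n_drugs}")
    for lab in labels:
        if lab not in ARCHETYPES:
            raise ValueError(f"unknown archetype {lab!r}")
    return labels


def make_panel(
    n_drugs: int = 9,
    archetype_mix: Mapping[str, int] | Sequence[str] | None = None,
    shared: Mapping[str, float] | None = None,
    seed: int = 0,
    doses_uM: Sequence[float] = DEFAULT_DOSES_UM,
) -> SyntheticPanel:
    """Draw per-drug ground-truth parameters for a panel.

    ``archetype_mix`` maps archetype label to drug count (default an even
    3/3/3 split); per-drug (K_d, f, g) are log-uniform within the archetype
    ranges and the shared cellular parameters default to K_A = 10,
    K_dim = 0.1 uM, raf_total = 0.04 uM.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    if archetype_mix is None:
        base, extra = divmod(n_drugs, 3)
        archetype_mix = {
            lab: base + (1 if i < extra else 0)
            for i, lab in enumerate(ARCHETYPES)
        }
    labels = _normalize_mix(n_drugs, archetype_mix)
    sh = dict(DEFAULT_SHARED)
    sh.update(shared or {})
    rng = np.random.default_rng(seed)
    drugs, truths = [], []
    counter: dict[str, int] = {}
    for lab in labels:
        counter[lab] = counter.get(lab, 0) + 1
        drugs.append(f"{lab}_{counter[lab]}")
        draw = ARCHETYPES[lab].sample(rng)
        truths.append(
            ModelParams(
                K_A=sh["K_A"], K_dim=sh["K_dim"], K_d=draw["K_d"],
                f=draw["f"], g=draw["g"], raf_total=sh["raf_total"],
                variant=Variant.UNIFIED,
            )
        )
    grids = np.tile(np.asarray(doses_uM, dtype=float), (n_drugs, 1))
    return SyntheticPanel(
        drugs=tuple(drugs),
        archetypes=tuple(labels),
        ground_truth=tuple(truths),
        shared=sh,
        dose_grids=grids,
        seed=seed,
    )


def noiseless_matrix(panel: SyntheticPanel, normalized: bool = True) -> np.ndarray:
    """Exact model responses for the panel's ground truth."""
    from .closed_forms import active_raf_fraction

    if panel.ground_truth is None:
        raise ValueError("panel has no ground truth")
    raw = np.stack(
        [
            np.atleast_1d(active_raf_fraction(p, panel.dose_grids[i]))
            for i, p in enumerate(panel.ground_truth)
        ]
    )
    if not normalized:
        return raw
    return raw / raw.max(axis=1, keepdims=True)


def noise_multipliers(
    noise_cv: float, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with the stated CV.

    ``sigma^2 = log(1 + cv^2)`` and mean ``-sigma^2/2`` give
    ``E[m] = 1`` and ``SD[m]/E[m] = cv`` exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if noise_cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def simulate_responses(
    panel: SyntheticPanel, noise_cv: float = 0.05, seed: int = 0
) -> SyntheticPanel:
    """Attach noiseless and noisy max-normalized matrices to a panel.

    Noise is mean-one multiplicative log-normal with coefficient of
    variation ``noise_cv``; per-drug max-normalization is applied after
    noise (``noise_cv = 0`` reproduces the noiseless matrix exactly).
    """
    raw = noiseless_matrix(panel, normalized=False)
    rng = np.random.default_rng(seed)
    noisy = raw * noise_multipliers(noise_cv, raw.shape, rng)
    noisy_norm = noisy / noisy.max(axis=1, keepdims=True)
    clean_norm = raw / raw.max(axis=1, keepdims=True)
    return replace(
        panel, noiseless=clean_norm, noisy=noisy_norm, noise_cv=noise_cv, seed=seed
    )


def write_panel(panel: SyntheticPanel, csv_path: str | Path) -> None:
    """CSV (drug, dose_uM, response_normalized) + JSON ground-truth sidecar."""
    if panel.noisy is None:
        raise ValueError("simulate responses before writing")
    csv_path = Path(csv_path)
    rows = []
    for i, drug in enumerate(panel.drugs):
        for j in range(panel.dose_grids.shape[1]):
            rows.append(
                {
                    "drug": drug,
                    "dose_uM": panel.dose_grids[i, j],
                    "response_normalized": panel.noisy[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "drugs": list(panel.drugs),
        "archetypes": list(panel.archetypes),
        "shared": panel.shared,
        "noise_cv": panel.noise_cv,
        "seed": panel.seed,
        "dose_grids": panel.dose_grids.tolist(),
        "ground_truth": [p.to_dict() for p in panel.ground_truth]
        if panel.ground_truth
        else None,
        "noiseless": panel.noiseless.tolist() if panel.noiseless is not None else None,
        "noisy": panel.noisy.tolist(),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_panel(csv_path: str | Path) -> SyntheticPanel:
    """Round-trip loader; without the JSON sidecar the panel carries data
    but no ground truth."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, comment="#")
    required = {"drug", "dose_uM", "response_normalized"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{csv_path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    sidecar_path = csv_path.with_suffix(".json")
    drugs = tuple(dict.fromkeys(df["drug"]))
    counts = df.groupby("drug").size()
    if counts.nunique() != 1:
        raise ValueError(f"{csv_path}: unbalanced dose counts across drugs")
    n = int(counts.iloc[0])
    grids = np.empty((len(drugs), n))
    noisy = np.empty_like(grids)
    for i, drug in enumerate(drugs):
        sub = df[df["drug"] == drug].sort_values("dose_uM")
        grids[i] = sub["dose_uM"].to_numpy()
        noisy[i] = sub["response_normalized"].to_numpy()

    if not sidecar_path.exists():
        return SyntheticPanel(
            drugs=drugs,
            archetypes=tuple("unknown" for _ in drugs),
            ground_truth=None,
            shared={},
            dose_grids=grids,
            noisy=noisy,
        )
    meta = json.loads(sidecar_path.read_text())
    return SyntheticPanel(
        drugs=tuple(meta["drugs"]),
        archetypes=tuple(meta["archetypes"]),
        ground_truth=tuple(ModelParams.from_dict(d) for d in meta["ground_truth"])
        if meta.get("ground_truth")
        else None,
        shared=meta["shared"],
        dose_grids=np.asarray(meta["dose_grids"]),
        noiseless=np.asarray(meta["noiseless"]) if meta.get("noiseless") else None,
        noisy=np.asarray(meta["noisy"]),
        noise_cv=meta.get("noise_cv"),
        seed=meta.get("seed"),
    )
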