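"""Parameter space partitioning (PSP).

The model's parameter space is gridded (equally spaced inclusive
endpoints per parameter), one 100-trial subject is simulated per
parameter set, each run is classified into a choice pattern, and the
per-label proportions estimate how the model's parameter space
partitions into behavioral regions.

Grid points are cell-centered: each parameter axis takes the midpoints
of ``n_points`` equal subintervals of its range.  Several parameter
ranges are open intervals, and PSP proportions estimate the *volume* of
behavioral regions, for which the midpoint rule is the natural
quadrature; endpoint grids put 1/n of each axis's weight on degenerate
boundary atoms (for example a zero punishment learning rate), which
distorts small-region proportions at desk-scale resolution.

Unbounded parameters (ORL ``beta_F``/``beta_P``, VSE ``phi``) must be
truncated to finite bounds for gridding; the default is [-10, 10] on
the scaled-outcome convention, wide enough that the frequency/
perseverance/exploration terms can dominate the learned values over
most of the gridded range.  Headline proportions depend on this choice;
sensitivity is surfaced by re-running with alternative bounds via
``GridSpec(truncation=...)``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import DEFAULT_OUTCOME_SCALE, simulate_batch
from .patterns import BROAD_LABELS, RESTRICTED_LABELS, classify_counts_batch

#: per-model grid bounds in parameter order; None marks unbounded
#: parameters that require truncation bounds.
GRID_BOUNDS = {
    "ORL": {
        "a_rew": (0.0, 1.0),
        "a_pun": (0.0, 1.0),
        "k_prime": (0.0, 5.0),
        "beta_f": None,
        "beta_p": None,
    },
    "VSE": {
        "theta": (0.0, 1.0),
        "delta": (0.0, 1.0),
        "alpha": (0.0, 1.0),
        "phi": None,
        "beta": (0.0, 5.0),
    },
}

DEFAULT_TRUNCATION = (-10.0, 10.0)


@dataclass
class GridSpec:
    """Equally spaced grid over a model's parameter space."""

    model: str
    n_points: int = 10
    truncation: dict = field(default_factory=dict)

    def __post_init__(self):
        self.model = self.model.upper()
        from .legacy import LEGACY_GRID_BOUNDS

        bounds_table = {**GRID_BOUNDS, **LEGACY_GRID_BOUNDS}
        if self.model not in bounds_table:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        self.bounds = {}
        for name, b in bounds_table[self.model].items():
            if name in self.truncation:
                b = tuple(self.truncation[name])
            if b is None:
                b = DEFAULT_TRUNCATION
            lo, hi = b
            if not lo < hi:
                raise ValueError(f"invalid bounds for {name}: {b}")
            self.bounds[name] = (float(lo), float(hi))

    @property
    def param_names(self) -> list[str]:
        return list(self.bounds)

    @property
    def n_params(self) -> int:
        return len(self.bounds)

    @property
    def n_sets(self) -> int:
        return self.n_points ** self.n_params

    def axis(self, name: str) -> np.ndarray:
        """Cell-centered grid values for one parameter."""
        lo, hi = self.bounds[name]
        i = np.arange(self.n_points)
        return lo + (i + 0.5) * (hi - lo) / self.n_points

    def decode(self, flat_indices: np.ndarray) -> np.ndarray:
        """Parameter vectors for flat lexicographic set indices, (n, P)."""
        flat_indices = np.asarray(flat_indices, dtype=np.int64)
        out = np.empty((len(flat_indices), self.n_params))
        rem = flat_indices
        for k in range(self.n_params - 1, -1, -1):
            ax = self.axis(self.param_names[k])
            out[:, k] = ax[rem % self.n_points]
            rem = rem // self.n_points
        return out


def make_grid(spec: GridSpec):
    """Stream parameter vectors in lexicographic order (last axis fastest)."""
    axes = [spec.axis(n) for n in spec.param_names]
    for combo in itertools.product(*axes):
        yield np.array(combo)


@dataclass
class PSPResult:
    model: str
    broad: dict  # label -> proportion (sums to 1)
    restricted_raw: dict  # label -> fraction of all runs
    restricted_renorm: dict  # renormalized over qualifying runs
    n_runs: int
    n_points: int
    bounds: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "broad": self.broad,
            "restricted_raw": self.restricted_raw,
            "restricted_renorm": self.restricted_renorm,
            "n_runs": self.n_runs,
            "n_points": self.n_points,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PSPResult":
        return cls(
            d["model"], d["broad"], d["restricted_raw"],
            d["restricted_renorm"], d["n_runs"], d["n_points"],
            {k: tuple(v) for k, v in d["bounds"].items()}, d["seed"],
        )


def run_psp(
    model: str,
    spec: GridSpec | None = None,
    seed: int = 0,
    n_trials: int = 100,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    loss_policy: str = "shuffled_block",
    chunk_size: int = 20000,
    n_points: int = 10,
    set_indices: np.ndarray | None = None,
) -> PSPResult:
    """Grid-search PSP: one simulated subject per parameter set.

    Aggregation is commutative counting over per-set labels whose
    randomness is keyed by (seed, set index), so the result is identical
    for any ``chunk_size`` or worker partitioning.  ``set_indices``
    restricts the run to a subset of the grid (e.g. random half-grids).
    """
    if spec is None:
        spec = GridSpec(model, n_points=n_points)
    model = spec.model
    from .legacy import LEGACY_MODELS, simulate_batch_legacy

    indices = (
        np.arange(spec.n_sets, dtype=np.int64)
        if set_indices is None
        else np.asarray(set_indices, dtype=np.int64)
    )
    broad_counts = np.zeros(5, dtype=np.int64)
    restricted_counts = np.zeros(3, dtype=np.int64)
    for start in range(0, len(indices), chunk_size):
        idx = indices[start : start + chunk_size]
        params = spec.decode(idx)
        if model in LEGACY_MODELS:
            choices, _, _ = simulate_batch_legacy(
                model, params, n_trials, seed, loss_policy,
                outcome_scale, agent_offset=0, agent_ids=idx,
            )
        else:
            choices, _, _ = simulate_batch(
                model, params, n_trials, seed, loss_policy,
                outcome_scale, agent_ids=idx,
            )
        counts = np.stack(
            [(choices == d).sum(axis=1) for d in range(4)], axis=1
        )
        broad, restricted = classify_counts_batch(counts)
        broad_counts += np.bincount(broad, minlength=5)
        restricted_counts += np.bincount(
            restricted[restricted >= 0], minlength=3
        )
    n = len(indices)
    qual = restricted_counts.sum()
    return PSPResult(
        model=model,
        broad={l: broad_counts[i] / n for i, l in enumerate(BROAD_LABELS)},
        restricted_raw={
            l: restricted_counts[i] / n for i, l in enumerate(RESTRICTED_LABELS)
        },
        restricted_renorm={
            l: (restricted_counts[i] / qual if qual else float("nan"))
            for i, l in enumerate(RESTRICTED_LABELS)
        },
        n_runs=n,
        n_points=spec.n_points,
        bounds=spec.bounds,
        seed=seed,
    )


def compare_parameter_spaces(results, definition: str = "broad") -> pd.DataFrame:
    """Models-by-labels proportion matrix from one or more PSP results."""
    results = list(results)
    if not results:
        raise ValueError("no PSP results to compare")
    field_map = {
        "broad": "broad",
        "restricted": "restricted_renorm",
        "restricted_raw": "restricted_raw",
    }
    if definition not in field_map:
        raise ValueError(f"unknown definition {definition!r}")
    labels = BROAD_LABELS if definition == "broad" else RESTRICTED_LABELS
    data = {
        r.model: [getattr(r, field_map[definition])[l] for l in labels]
        for r in results
    }
    return pd.DataFrame(data, index=list(labels))
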