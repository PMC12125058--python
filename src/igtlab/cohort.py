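"""Synthetic cohorts with controlled choice-pattern composition.

A cohort mixes subjects generated from ORL and VSE (default 50/50).
Parameters are drawn either uniformly over the models' grid ranges or
from group-level normals on the unconstrained scale (the same transform
used by the fitting module).  Subjects are accepted by rejection
sampling against restricted-pattern include/exclude filters — e.g. a
"GOB" cohort keeps only restricted Good-Over-Bad and
Infrequent-Over-Frequent subjects, so it contains no Bad-Over-Good
subject by construction.  Generation metadata (per-subject model, true
parameters, seed, labels) suffices to replay every subject exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import derive_seed, u01
from .fitting import constrain
from .models import DEFAULT_OUTCOME_SCALE, TrialSequence, simulate_batch
from .patterns import (
    RESTRICTED_LABELS,
    classify_broad,
    classify_restricted,
    count_choices,
)
from .psp import DEFAULT_TRUNCATION, GRID_BOUNDS
from .task import DECKS

#: documented default group-level means/SDs (unconstrained scale) for
#: hierarchical parameter sampling; chosen to give moderate learning,
#: mild perseverance/frequency weighting and mid-range consistency.
DEFAULT_GROUP_MEANS = {
    "ORL": np.array([-0.4, -0.9, -0.8, 1.2, 0.7]),
    "VSE": np.array([0.0, 0.8, -0.3, 0.6, -0.5]),
}
#: group SDs follow each model's own hierarchical prior scale (ORL's
#: hyper-SD prior is half-normal(0.2); VSE's half-normal(3.0) is weak,
#: so a moderate heterogeneity of 0.4 is used there)
DEFAULT_GROUP_SDS = {
    "ORL": np.full(5, 0.2),
    "VSE": np.full(5, 0.4),
}


@dataclass
class CohortSpec:
    n_subjects: int = 20
    model_mix: dict = field(default_factory=lambda: {"ORL": 0.5, "VSE": 0.5})
    sampler: str = "uniform"  # 'uniform' over grid ranges | 'hierarchical'
    group_means: dict = field(default_factory=dict)  # model -> (5,) mu
    group_sds: dict = field(default_factory=dict)
    include_patterns: tuple = ()  # restricted labels a subject must have
    exclude_patterns: tuple = ()
    max_attempts: int = 10000
    n_trials: int = 100
    outcome_scale: float = DEFAULT_OUTCOME_SCALE
    seed: int = 0

    def __post_init__(self):
        total = sum(self.model_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("model_mix fractions must sum to 1")
        bad = set(self.include_patterns) & set(self.exclude_patterns)
        if bad:
            raise ValueError(f"patterns both included and excluded: {bad}")
        for lbl in (*self.include_patterns, *self.exclude_patterns):
            if lbl not in RESTRICTED_LABELS:
                raise ValueError(f"unknown restricted label {lbl!r}")


@dataclass
class Cohort:
    subjects: list  # of TrialSequence
    meta: pd.DataFrame  # per-subject model, params, label, seed

    def __len__(self) -> int:
        return len(self.subjects)


class GenerationError(RuntimeError):
    pass


def _sample_params(spec: CohortSpec, model: str, attempt_seed: int) -> np.ndarray:
    names = list(GRID_BOUNDS[model])
    u = u01(attempt_seed, np.arange(5), np.full(5, 7))
    if spec.sampler == "uniform":
        lo = np.array([
            (GRID_BOUNDS[model][n] or DEFAULT_TRUNCATION)[0] for n in names
        ])
        hi = np.array([
            (GRID_BOUNDS[model][n] or DEFAULT_TRUNCATION)[1] for n in names
        ])
        return lo + u * (hi - lo)
    if spec.sampler == "hierarchical":
        from scipy.special import ndtri

        mu = np.asarray(spec.group_means.get(model, DEFAULT_GROUP_MEANS[model]))
        sd = np.asarray(spec.group_sds.get(model, DEFAULT_GROUP_SDS[model]))
        z = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
        return constrain(model, mu + sd * z)
    raise ValueError(f"unknown sampler {spec.sampler!r}")


def _accept(label: str | None, spec: CohortSpec) -> bool:
    if label is not None and label in spec.exclude_patterns:
        return False
    if spec.include_patterns:
        return label in spec.include_patterns
    return True


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Rejection-sample subjects until ``n_subjects`` are accepted."""
    quotas = {
        m: int(round(f * spec.n_subjects)) for m, f in spec.model_mix.items()
    }
    # rounding drift goes to the first listed model
    drift = spec.n_subjects - sum(quotas.values())
    if drift and quotas:
        quotas[next(iter(quotas))] += drift
    subjects: list[TrialSequence] = []
    meta_rows = []
    for model, quota in quotas.items():
        model = model.upper()
        accepted = 0
        for attempt in range(spec.max_attempts):
            if accepted >= quota:
                break
            model_code = 1 if model == "ORL" else 2
            sub_seed = derive_seed(spec.seed, model_code, attempt)
            params = _sample_params(spec, model, sub_seed)
            choices, gains, losses = simulate_batch(
                model, params[None, :], spec.n_trials, sub_seed,
                outcome_scale=spec.outcome_scale,
            )
            counts = count_choices(choices[0])
            label = (
                classify_restricted(counts)
                if counts.n_trials == 100
                else None
            )
            if not _accept(label, spec):
                continue
            sid = f"{model.lower()}_{len(subjects):03d}"
            subjects.append(
                TrialSequence(choices[0], gains[0], losses[0], sid)
            )
            meta_rows.append(
                {
                    "subjID": sid,
                    "model": model,
                    "seed": sub_seed,
                    "restricted": label if label is not None else "none",
                    "broad": classify_broad(counts),
                    **{f"param_{i}": params[i] for i in range(5)},
                }
            )
            accepted += 1
        if accepted < quota:
            raise GenerationError(
                f"max_attempts={spec.max_attempts} exhausted for {model}: "
                f"accepted {accepted}/{quota} under include="
                f"{spec.include_patterns} exclude={spec.exclude_patterns}"
            )
    return Cohort(subjects, pd.DataFrame(meta_rows))


def gob_cohort_spec(seed: int = 0, n_subjects: int = 20) -> CohortSpec:
    """20 subjects, half ORL / half VSE, no restricted Bad-Over-Good:
    only GOB and IOF restricted patterns are admitted."""
    return CohortSpec(
        n_subjects=n_subjects,
        include_patterns=("GOB", "IOF"),
        exclude_patterns=("BOG",),
        seed=seed,
    )


def bog_cohort_spec(seed: int = 0, n_subjects: int = 20) -> CohortSpec:
    """The mirror cohort: no restricted Good-Over-Bad."""
    return CohortSpec(
        n_subjects=n_subjects,
        include_patterns=("BOG", "IOF"),
        exclude_patterns=("GOB",),
        seed=seed,
    )


def hierarchical_cohort(
    model: str,
    n_subjects: int = 20,
    seed: int = 0,
    group_means: np.ndarray | None = None,
    group_sds: np.ndarray | None = None,
    n_trials: int = 100,
) -> Cohort:
    """Unfiltered cohort from one model's group-level normals
    (parameter-recovery and model-comparison test bed)."""
    model = model.upper()
    spec = CohortSpec(
        n_subjects=n_subjects,
        model_mix={model: 1.0},
        sampler="hierarchical",
        group_means={} if group_means is None else {model: group_means},
        group_sds={} if group_sds is None else {model: group_sds},
        n_trials=n_trials,
        seed=seed,
    )
    return generate_cohort(spec)


# ---------------------------------------------------------------------------
# I/O: long CSV and wide many-labs layouts


def write_cohort(cohort: Cohort, path, format: str = "long_csv") -> None:
    if format == "long_csv":
        pd.concat([s.to_frame() for s in cohort.subjects]).to_csv(
            path, index=False
        )
    elif format == "wide_manylabs":
        n = cohort.subjects[0].n_trials if cohort.subjects else 0
        cols = {}
        cols["subjID"] = [s.subject_id for s in cohort.subjects]
        for t in range(n):
            cols[f"choice_{t + 1}"] = [
                s.choices[t] + 1 for s in cohort.subjects
            ]
        for t in range(n):
            cols[f"wins_{t + 1}"] = [s.gains[t] for s in cohort.subjects]
        for t in range(n):
            cols[f"losses_{t + 1}"] = [-s.losses[t] for s in cohort.subjects]
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cohort(path, format: str = "auto") -> Cohort:
    """Read a cohort; losses are accepted signed or as magnitudes."""
    df = pd.read_csv(path)
    if format == "auto":
        format = "long_csv" if "deck" in df.columns else "wide_manylabs"
    subjects = []
    if format == "long_csv":
        required = {"subjID", "trial", "deck", "gain", "loss"}
        if not required <= set(df.columns):
            raise ValueError(
                f"long CSV must have columns {sorted(required)}"
            )
        if (df["gain"] < 0).any():
            bad = df.index[df["gain"] < 0][0] + 2  # header + 1-based
            raise ValueError(f"negative gain at line {bad}")
        for sid, g in df.groupby("subjID", sort=False):
            g = g.sort_values("trial")
            try:
                choices = [DECKS.index(d) for d in g["deck"]]
            except ValueError:
                raise ValueError(
                    f"unknown deck symbol in subject {sid!r}"
                ) from None
            subjects.append(
                TrialSequence(
                    choices, g["gain"].to_numpy(),
                    np.abs(g["loss"].to_numpy()), str(sid),
                )
            )
    elif format == "wide_manylabs":
        choice_cols = [c for c in df.columns if c.startswith("choice_")]
        win_cols = [c for c in df.columns if c.startswith("wins_")]
        loss_cols = [c for c in df.columns if c.startswith("losses_")]
        if not (len(choice_cols) == len(win_cols) == len(loss_cols)):
            raise ValueError("wide layout needs matching choice/wins/losses blocks")
        for i, row in df.iterrows():
            gains = row[win_cols].to_numpy(dtype=float)
            if (gains < 0).any():
                raise ValueError(f"negative gain at line {i + 2}")
            subjects.append(
                TrialSequence(
                    row[choice_cols].to_numpy(dtype=int) - 1,
                    gains,
                    np.abs(row[loss_cols].to_numpy(dtype=float)),
                    str(row.get("subjID", f"subj_{i:03d}")),
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    meta = pd.DataFrame({"subjID": [s.subject_id for s in subjects]})
    return Cohort(subjects, meta)
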