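"""Domain types, disk I/O and preprocessing for tool-tissue force traces.

A trial is one execution of a microsurgical task recorded as a univariate
force sequence in newtons.  Preprocessing follows the order: clip negative
sensor readings to zero, standard-scale with statistics pooled over the
training trials, then (at training time only) crop or zero-pad to a fixed
window length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EXPERT = "Expert"
NOVICE = "Novice"
SKILL_LABELS = (EXPERT, NOVICE)

#: Maximum repetitions of the task per surgeon in the study protocol.
MAX_TRIALS_PER_SURGEON = 20


@dataclass(frozen=True)
class ForceTrace:
    """One trial's force sequence (newtons)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError(f"force trace must be 1-D, got shape {v.shape}")
        if v.size < 1:
            raise ValueError("force trace must contain at least one sample")
        object.__setattr__(self, "values", v)

    @property
    def T(self) -> int:
        return int(self.values.size)

    def require_finite(self) -> "ForceTrace":
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            raise ValueError(f"non-finite force sample at index {bad[0]}")
        return self


@dataclass(frozen=True)
class TrialRecord:
    """A force trace plus its metadata."""

    trace: ForceTrace
    surgeon_id: str
    skill: str
    trial_index: int

    def __post_init__(self):
        if self.skill not in SKILL_LABELS:
            raise ValueError(
                f"unknown skill label {self.skill!r}; expected one of {SKILL_LABELS}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def label(self) -> int:
        """Binary target: 1 for Expert, 0 for Novice."""
        return 1 if self.skill == EXPERT else 0


@dataclass(frozen=True)
class SurgeonInfo:
    surgeon_id: str
    skill: str
    n_trials: int


@dataclass
class Cohort:
    """A collection of trials with a per-surgeon roster."""

    records: list[TrialRecord]
    roster: list[SurgeonInfo] = field(default_factory=list)

    def __post_init__(self):
        seen: set[tuple[str, int]] = set()
        skills: dict[str, str] = {}
        counts: dict[str, int] = {}
        for r in self.records:
            key = (r.surgeon_id, r.trial_index)
            if key in seen:
                raise ValueError(f"duplicate (surgeon_id, trial_index): {key}")
            seen.add(key)
            if skills.setdefault(r.surgeon_id, r.skill) != r.skill:
                raise ValueError(f"surgeon {r.surgeon_id!r} has inconsistent skill labels")
            counts[r.surgeon_id] = counts.get(r.surgeon_id, 0) + 1
        for sid, n in counts.items():
            if n > MAX_TRIALS_PER_SURGEON:
                raise ValueError(
                    f"surgeon {sid!r} has {n} trials, exceeding the protocol "
                    f"maximum of {MAX_TRIALS_PER_SURGEON}")
        if not self.roster:
            self.roster = [SurgeonInfo(sid, skills[sid], counts[sid]) for sid in skills]
        else:
            roster_ids = {s.surgeon_id for s in self.roster}
            missing = set(skills) - roster_ids
            if missing:
                raise ValueError(f"records reference surgeons absent from roster: {missing}")

    @property
    def surgeon_ids(self) -> list[str]:
        return [s.surgeon_id for s in self.roster]

    def trials_of(self, surgeon_id: str) -> list[TrialRecord]:
        return [r for r in self.records if r.surgeon_id == surgeon_id]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ScalerState:
    """Pooled mean/std used for standard scaling (population convention)."""

    mean: float
    std: float

    def __post_init__(self):
        if not (self.std > 0):
            raise ValueError(f"scaler std must be > 0, got {self.std}")


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def clip_negatives(trace: ForceTrace) -> ForceTrace:
    """Replace negative force samples with zero (sensor instability artifact)."""
    trace.require_finite()
    return ForceTrace(np.maximum(trace.values, 0.0))


def fit_scaler(training_traces: list[ForceTrace]) -> ScalerState:
    """Fit pooled mean/std over all samples of all training traces."""
    if not training_traces:
        raise ValueError("need at least one training trace to fit a scaler")
    pooled = np.concatenate([t.values for t in training_traces])
    mean = float(pooled.mean())
    std = float(pooled.std())  # population convention (divide by N)
    if std == 0.0:
        raise ValueError("pooled training samples are constant; cannot standard-scale")
    return ScalerState(mean=mean, std=std)


def apply_scaler(trace: ForceTrace, scaler: ScalerState) -> ForceTrace:
    return ForceTrace((trace.values - scaler.mean) / scaler.std)


def crop_or_pad(trace: ForceTrace, target_len: int, rng: np.random.Generator) -> ForceTrace:
    """Random contiguous crop to `target_len`, or trailing zero-pad if shorter."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    T = trace.T
    if T > target_len:
        start = int(rng.integers(0, T - target_len + 1))
        return ForceTrace(trace.values[start:start + target_len].copy())
    if T < target_len:
        out = np.zeros(target_len, dtype=np.float64)
        out[:T] = trace.values
        return ForceTrace(out)
    return trace


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------
# Per-trial trace: two-column CSV with header "t,force_n".
# Cohort manifest: JSON array of {surgeon_id, skill, trial_index, trace_path},
# trace_path relative to the manifest's directory.

_MANIFEST_NAME = "manifest.json"


def _trace_to_csv(trace: ForceTrace, path: Path):
    with open(path, "w") as fh:
        fh.write("t,force_n\n")
        for t, v in enumerate(trace.values):
            fh.write(f"{t},{float(v)!r}\n")


def _trace_from_csv(path: Path) -> ForceTrace:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "t,force_n":
            raise ValueError(f"{path}: expected header 't,force_n', got {header!r}")
        values = [float(line.split(",")[1]) for line in fh if line.strip()]
    return ForceTrace(np.asarray(values))


def write_trials(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as manifest.json plus per-trial CSVs under `path`."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    traces_dir = root / "traces"
    traces_dir.mkdir(exist_ok=True)
    manifest = []
    for r in cohort.records:
        rel = f"traces/{r.surgeon_id}_trial{r.trial_index:03d}.csv"
        _trace_to_csv(r.trace, root / rel)
        manifest.append({
            "surgeon_id": r.surgeon_id,
            "skill": r.skill,
            "trial_index": r.trial_index,
            "trace_path": rel,
        })
    with open(root / _MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return root / _MANIFEST_NAME


def read_trials(path: str | Path) -> Cohort:
    """Read a cohort from a manifest file or a directory containing one."""
    p = Path(path)
    manifest_path = p / _MANIFEST_NAME if p.is_dir() else p
    if not manifest_path.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest_path}")
    with open(manifest_path) as fh:
        entries = json.load(fh)
    root = manifest_path.parent
    records = []
    for e in entries:
        missing = {"surgeon_id", "skill", "trial_index", "trace_path"} - set(e)
        if missing:
            raise ValueError(f"manifest entry missing fields: {sorted(missing)}")
        records.append(TrialRecord(
            trace=_trace_from_csv(root / e["trace_path"]),
            surgeon_id=str(e["surgeon_id"]),
            skill=e["skill"],
            trial_index=int(e["trial_index"]),
        ))
    return Cohort(records=records)
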