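"""Domain types for an sEMG scoliosis cohort, plus the on-disk format.

A cohort bundles three collections: time-invariant patient descriptors
(:class:`PatientStatic`), per-week clinical outcome labels
(:class:`OutcomePanel`), and raw multi-channel surface-EMG recordings
(:class:`EMGRecording`).  The study design samples each patient at weeks
0, 8, 16 and 24, with one ~20 s recording per exercise per visit.

The on-disk layout is deliberately plain text so fixtures are diffable:

    <dir>/manifest.json          counts, schema version, recording index
    <dir>/patients.csv           one row per patient
    <dir>/outcomes.csv           long format, one row per (patient, week)
    <dir>/signals/<name>.csv     time_s column + 8 channel columns (uV)
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1
MEASUREMENT_WEEKS = (0, 8, 16, 24)

#: Weeks at which Cobb angles are measured (baseline and end of programme).
COBB_WEEKS = (0, 24)


class MuscleChannel(enum.Enum):
    """The eight recorded muscles, in canonical channel order."""

    erector_spinae_L = 0
    erector_spinae_R = 1
    multifidus_L = 2
    multifidus_R = 3
    rectus_abdominis_L = 4
    rectus_abdominis_R = 5
    external_oblique_L = 6
    external_oblique_R = 7

    @property
    def side(self) -> str:
        return self.name[-1]

    @property
    def muscle_group(self) -> str:
        return self.name[:-2]


#: The four bilateral muscle pairs, keyed by muscle group.
MUSCLE_PAIRS = {
    "erector_spinae": (MuscleChannel.erector_spinae_L, MuscleChannel.erector_spinae_R),
    "multifidus": (MuscleChannel.multifidus_L, MuscleChannel.multifidus_R),
    "rectus_abdominis": (
        MuscleChannel.rectus_abdominis_L,
        MuscleChannel.rectus_abdominis_R,
    ),
    "external_oblique": (
        MuscleChannel.external_oblique_L,
        MuscleChannel.external_oblique_R,
    ),
}

#: Spinal region whose curve drives the convex/concave labelling of a pair.
#: The paraspinal electrodes sit at the lumbar level (L4-L5 per SENIAM), the
#: abdominal pairs are referred to the thoracic curve.
PAIR_REGION = {
    "erector_spinae": "lumbar",
    "multifidus": "lumbar",
    "rectus_abdominis": "thoracic",
    "external_oblique": "thoracic",
}

N_CHANNELS = len(MuscleChannel)
CHANNEL_NAMES = [m.name for m in MuscleChannel]


class ExerciseType(enum.Enum):
    """The four isometric Schroth exercise holds."""

    quadruped = 0
    bar_squat = 1
    unilateral_kneel = 2
    lateral_flexion_sit = 3


EXERCISES = list(ExerciseType)


@dataclass
class EMGRecording:
    """One exercise hold for one patient at one measurement week.

    ``signals`` is an [8 x T] array in microvolts, channel order fixed to
    the :class:`MuscleChannel` enumeration.
    """

    patient_id: str
    week: int
    exercise: ExerciseType
    sample_rate_hz: float
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class PatientStatic:
    """Time-invariant patient descriptors.

    ``convex_side`` maps each spinal region ("thoracic", "lumbar") to the
    side ("L"/"R") on which the curve bulges outward.
    """

    patient_id: str
    age: float
    sex: str  # "female" | "male"
    bmi: float
    risser: float
    curve_direction: str  # "left" | "right"
    convex_side: dict[str, str] = field(default_factory=dict)


@dataclass
class OutcomeMeasures:
    """Clinical labels at one measurement week.

    Cobb angles are only measured radiographically at weeks 0 and 24; at
    intermediate weeks they may be None (per protocol) or filled with
    latent values by the simulator's ground truth.
    """

    cobb_T: float | None = None
    cobb_L: float | None = None
    art_T: float | None = None
    art_L: float | None = None
    srs22: float | None = None
    bst: float | None = None

    def get(self, name: str) -> float | None:
        return getattr(self, name)


OUTCOME_NAMES = ("cobb_T", "cobb_L", "art_T", "art_L", "srs22", "bst")


@dataclass
class OutcomePanel:
    """Per-week outcome labels for one patient."""

    patient_id: str
    weeks: dict[int, OutcomeMeasures] = field(default_factory=dict)

    def value(self, week: int, name: str) -> float | None:
        if week not in self.weeks:
            return None
        return self.weeks[week].get(name)


@dataclass
class Cohort:
    """The full study dataset: statics, outcomes and EMG recordings."""

    statics: list[PatientStatic]
    outcomes: list[OutcomePanel]
    recordings: list[EMGRecording]

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.statics]

    def static_for(self, patient_id: str) -> PatientStatic:
        for s in self.statics:
            if s.patient_id == patient_id:
                return s
        raise KeyError(patient_id)

    def outcomes_for(self, patient_id: str) -> OutcomePanel:
        for o in self.outcomes:
            if o.patient_id == patient_id:
                return o
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only validation outcome; empty ``violations`` means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "cohort valid"
        return "\n".join(self.violations)


def _is_finite_number(x) -> bool:
    return isinstance(x, (int, float, np.floating, np.integer)) and math.isfinite(x)


def validate_cohort(cohort: Cohort, require_complete: bool = True) -> ValidationReport:
    """Check every type invariant and (optionally) design completeness.

    Total: never raises on malformed content, always reports.  A complete
    cohort has one recording per (patient, week, exercise), i.e. 16 per
    patient.
    """
    rep = ValidationReport()
    ids = [s.patient_id for s in cohort.statics]
    if len(set(ids)) != len(ids):
        rep.add("duplicate patient_id in statics")
    id_set = set(ids)

    for s in cohort.statics:
        p = s.patient_id
        if not _is_finite_number(s.age) or not (10 <= s.age <= 18):
            rep.add(f"{p}: age {s.age!r} outside [10, 18]")
        if s.sex not in ("female", "male"):
            rep.add(f"{p}: sex {s.sex!r} not in {{female, male}}")
        if not _is_finite_number(s.bmi) or s.bmi <= 0:
            rep.add(f"{p}: bmi {s.bmi!r} not positive")
        if not _is_finite_number(s.risser) or not (0 <= s.risser <= 5):
            rep.add(f"{p}: risser {s.risser!r} outside [0, 5]")
        if s.curve_direction not in ("left", "right"):
            rep.add(f"{p}: curve_direction {s.curve_direction!r} invalid")
        for region in ("thoracic", "lumbar"):
            if s.convex_side.get(region) not in ("L", "R"):
                rep.add(f"{p}: convex_side missing/invalid for {region}")

    out_ids = [o.patient_id for o in cohort.outcomes]
    if sorted(out_ids) != sorted(ids):
        rep.add("outcome panels do not match statics one-to-one")
    ranges = {
        "cobb_T": (0.0, 90.0),
        "cobb_L": (0.0, 90.0),
        "art_T": (0.0, math.inf),
        "art_L": (0.0, math.inf),
        "srs22": (1.0, 5.0),
        "bst": (0.0, 240.0),
    }
    for o in cohort.outcomes:
        p = o.patient_id
        for w in o.weeks:
            if w not in MEASUREMENT_WEEKS:
                rep.add(f"{p}: outcome week {w} not in {MEASUREMENT_WEEKS}")
        for w, m in o.weeks.items():
            for name, (lo, hi) in ranges.items():
                v = m.get(name)
                if v is None:
                    continue
                if not _is_finite_number(v) or not (lo <= v <= hi):
                    rep.add(f"{p} week {w}: {name}={v!r} outside [{lo}, {hi}]")
        for w in COBB_WEEKS:
            if w in o.weeks:
                for name in ("cobb_T", "cobb_L"):
                    if o.weeks[w].get(name) is None:
                        rep.add(f"{p} week {w}: mandatory {name} missing")

    seen = set()
    for r in cohort.recordings:
        key = (r.patient_id, r.week, r.exercise.name)
        tag = f"{r.patient_id} week {r.week} {r.exercise.name}"
        if key in seen:
            rep.add(f"{tag}: duplicate recording")
        seen.add(key)
        if r.patient_id not in id_set:
            rep.add(f"{tag}: patient_id absent from statics")
        if r.week not in MEASUREMENT_WEEKS:
            rep.add(f"{tag}: week not in {MEASUREMENT_WEEKS}")
        if not _is_finite_number(r.sample_rate_hz) or r.sample_rate_hz <= 800:
            rep.add(f"{tag}: sample_rate_hz {r.sample_rate_hz!r} must exceed 800 (2x400 Hz)")
        sig = r.signals
        if sig.ndim != 2 or sig.shape[0] != N_CHANNELS:
            rep.add(f"{tag}: signals shape {sig.shape} is not [8 x T]")
        elif sig.shape[1] < 1:
            rep.add(f"{tag}: empty signal")
        elif not np.all(np.isfinite(sig)):
            rep.add(f"{tag}: non-finite signal values")

    if require_complete:
        for p in ids:
            for w in MEASUREMENT_WEEKS:
                for ex in EXERCISES:
                    if (p, w, ex.name) not in seen:
                        rep.add(f"missing recording: ({p}, week {w}, {ex.name})")
    return rep


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------


def _recording_filename(r: EMGRecording) -> str:
    return f"{r.patient_id}_w{r.week:02d}_{r.exercise.name}.csv"


def save_cohort(cohort: Cohort, path: str | Path) -> dict:
    """Write a cohort directory; returns the manifest dict.

    Refuses to write an invalid cohort.  Signal values are written with
    enough digits for a bit-exact float32 round trip.
    """
    rep = validate_cohort(cohort)
    if not rep.ok:
        raise ValueError("refusing to save invalid cohort:\n" + str(rep))
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "signals").mkdir(exist_ok=True)

    pat_rows = []
    for s in cohort.statics:
        pat_rows.append(
            {
                "patient_id": s.patient_id,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "risser": s.risser,
                "curve_direction": s.curve_direction,
                "convex_thoracic": s.convex_side["thoracic"],
                "convex_lumbar": s.convex_side["lumbar"],
            }
        )
    pd.DataFrame(pat_rows).to_csv(path / "patients.csv", index=False, float_format="%.17g")

    out_rows = []
    for o in cohort.outcomes:
        for w in sorted(o.weeks):
            row = {"patient_id": o.patient_id, "week": w}
            for name in OUTCOME_NAMES:
                row[name] = o.weeks[w].get(name)
            out_rows.append(row)
    pd.DataFrame(out_rows).to_csv(path / "outcomes.csv", index=False, float_format="%.17g")

    index = []
    for r in cohort.recordings:
        fname = _recording_filename(r)
        t = np.arange(r.n_samples, dtype=np.float64) / r.sample_rate_hz
        header = ",".join(["time_s"] + CHANNEL_NAMES)
        data = np.column_stack([t] + [r.signals[i].astype(np.float64) for i in range(N_CHANNELS)])
        np.savetxt(path / "signals" / fname, data, fmt="%.9g", delimiter=",",
                   header=header, comments="")
        index.append(
            {
                "file": fname,
                "patient_id": r.patient_id,
                "week": r.week,
                "exercise": r.exercise.name,
                "sample_rate_hz": r.sample_rate_hz,
                "n_samples": int(r.n_samples),
            }
        )

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_patients": len(cohort.statics),
        "n_recordings": len(cohort.recordings),
        "channels": CHANNEL_NAMES,
        "recordings": index,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_cohort(path: str | Path, require_complete: bool = True) -> Cohort:
    """Read a cohort directory written by :func:`save_cohort`.

    Channel order is restored from the per-file headers regardless of the
    on-disk column order.  Raises on missing files, manifest mismatch or
    non-finite signal values; other invariant violations raise too (the
    loader validates).
    """
    path = Path(path)
    man_path = path / "manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"missing manifest: {man_path}")
    with open(man_path) as fh:
        manifest = json.load(fh)

    pats = pd.read_csv(path / "patients.csv", float_precision="round_trip")
    statics = [
        PatientStatic(
            patient_id=str(row.patient_id),
            age=float(row.age),
            sex=str(row.sex),
            bmi=float(row.bmi),
            risser=float(row.risser),
            curve_direction=str(row.curve_direction),
            convex_side={"thoracic": str(row.convex_thoracic), "lumbar": str(row.convex_lumbar)},
        )
        for row in pats.itertuples()
    ]

    outs = pd.read_csv(path / "outcomes.csv", float_precision="round_trip")
    panels: dict[str, OutcomePanel] = {}
    for row in outs.itertuples():
        pid = str(row.patient_id)
        panel = panels.setdefault(pid, OutcomePanel(patient_id=pid))
        vals = {}
        for name in OUTCOME_NAMES:
            v = getattr(row, name)
            vals[name] = None if pd.isna(v) else float(v)
        panel.weeks[int(row.week)] = OutcomeMeasures(**vals)

    if len(manifest["recordings"]) != int(manifest["n_recordings"]):
        raise ValueError("manifest recording index length mismatch")
    recordings = []
    for entry in manifest["recordings"]:
        fpath = path / "signals" / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest lists missing signal file: {entry['file']}")
        df = pd.read_csv(fpath)
        missing = [c for c in CHANNEL_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"{entry['file']}: missing channel columns {missing}")
        sig = df[CHANNEL_NAMES].to_numpy().T.astype(np.float32)
        if not np.all(np.isfinite(sig)):
            raise ValueError(f"{entry['file']}: non-finite signal values")
        recordings.append(
            EMGRecording(
                patient_id=str(entry["patient_id"]),
                week=int(entry["week"]),
                exercise=ExerciseType[entry["exercise"]],
                sample_rate_hz=float(entry["sample_rate_hz"]),
                signals=sig,
            )
        )

    cohort = Cohort(statics=statics, outcomes=list(panels.values()), recordings=recordings)
    rep = validate_cohort(cohort, require_complete=require_complete)
    if not rep.ok:
        raise ValueError("loaded cohort is invalid:\n" + str(rep))
    return cohort
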