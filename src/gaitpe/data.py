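"""Data model and CSV I/O for gait cohorts.

A cohort couples per-subject clinical metadata (condition, GMFCS stage,
walking speed, limb length, gait indices) with the subject's gait cycles.
Each cycle holds 201 angular samples — one full cycle, heel contact to next
heel contact of the same foot — for each of the 15 joint/plane channels.
Left and right cycles are separate cycles of the same subject.

Two plain CSV tables are the on-disk form:

* ``cycles.csv`` — long format, one row per angular sample:
  subject_id, side, cycle_id, joint, plane, sample_index, angle_deg.
* ``subjects.csv`` — one row per subject with condition, GMFCS, speeds,
  limb length and the GDI/GPS/MAP indices.

Angles are stored in degrees.  Permutation entropy is invariant to any
positive affine rescaling of a channel, so the unit never affects results
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .channels import CHANNELS, MAP_ITEMS, Channel, Joint, Plane

#: Number of angular samples per gait cycle (0..100% of the cycle).
N_SAMPLES = 201

GMFCS_LEVELS = ("none", "I", "II", "III", "IV")
CONDITIONS = ("control", "cp")

SUBJECT_COLUMNS = (
    "subject_id",
    "condition",
    "gmfcs",
    "walking_speed_m_s",
    "lower_limb_length_m",
    "gdi",
    "gps",
) + MAP_ITEMS

CYCLE_COLUMNS = (
    "subject_id",
    "side",
    "cycle_id",
    "joint",
    "plane",
    "sample_index",
    "angle_deg",
)


class CohortValidationError(ValueError):
    """Raised when a table or cohort violates the data-model invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "cohort validation failed:\n  " + "\n  ".join(self.violations)
        )


@dataclass
class GaitCycle:
    """One gait cycle: 15 channels x 201 angle samples plus identifiers."""

    subject_id: str
    side: str  # "left" | "right"
    cycle_id: str
    samples: dict[Channel, np.ndarray]

    def __post_init__(self) -> None:
        self.samples = {
            ch: np.asarray(v, dtype=float) for ch, v in self.samples.items()
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GaitCycle):
            return NotImplemented
        if (self.subject_id, self.side, self.cycle_id) != (
            other.subject_id,
            other.side,
            other.cycle_id,
        ):
            return False
        if set(self.samples) != set(other.samples):
            return False
        return all(
            np.array_equal(self.samples[ch], other.samples[ch])
            for ch in self.samples
        )


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical metadata for one subject.

    ``normalized_speed`` is walking speed divided by lower-limb length
    (units 1/s); it is derived, not stored on disk.
    """

    subject_id: str
    condition: str  # "control" | "cp"
    gmfcs: str  # "none" for controls, "I".."IV" for patients
    walking_speed: float  # m/s
    lower_limb_length: float  # m
    gdi: float
    gps: float
    map_items: Mapping[str, float] = field(default_factory=dict)

    @property
    def normalized_speed(self) -> float:
        return self.walking_speed / self.lower_limb_length

    @property
    def severity(self) -> int:
        """Ordinal severity: 0 for controls, 1..4 for GMFCS I..IV."""
        return 0 if self.gmfcs == "none" else GMFCS_LEVELS.index(self.gmfcs)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise CohortValidationError(
                [f"subject {self.subject_id}: unknown condition {self.condition!r}"]
            )
        if self.gmfcs not in GMFCS_LEVELS:
            raise CohortValidationError(
                [f"subject {self.subject_id}: unknown GMFCS level {self.gmfcs!r}"]
            )
        if (self.condition == "control") != (self.gmfcs == "none"):
            raise CohortValidationError(
                [
                    f"subject {self.subject_id}: condition {self.condition!r} "
                    f"inconsistent with GMFCS {self.gmfcs!r}"
                ]
            )


@dataclass
class Cohort:
    """A set of subjects together with all their gait cycles."""

    subjects: dict[str, SubjectRecord]
    cycles: list[GaitCycle]

    def validate(self) -> list[str]:
        """Return every invariant violation in the cohort (empty if valid)."""
        violations: list[str] = []
        owners: set[str] = set()
        for cyc in self.cycles:
            violations.extend(validate_cycle(cyc))
            if cyc.subject_id not in self.subjects:
                violations.append(
                    f"cycle {cyc.subject_id}/{cyc.side}/{cyc.cycle_id}: "
                    f"unknown subject_id {cyc.subject_id!r}"
                )
            owners.add(cyc.subject_id)
        for sid in self.subjects:
            if sid not in owners:
                violations.append(f"subject {sid}: owns no cycles")
        return violations

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def subject_frame(self) -> pd.DataFrame:
        """Subject metadata as a tidy DataFrame (one row per subject)."""
        rows = []
        for s in self.subjects.values():
            row = {
                "subject_id": s.subject_id,
                "condition": s.condition,
                "gmfcs": s.gmfcs,
                "walking_speed_m_s": s.walking_speed,
                "lower_limb_length_m": s.lower_limb_length,
                "normalized_speed": s.normalized_speed,
                "severity": s.severity,
                "gdi": s.gdi,
                "gps": s.gps,
            }
            for item in MAP_ITEMS:
                row[item] = s.map_items.get(item, math.nan)
            rows.append(row)
        if not rows:
            return pd.DataFrame(
                columns=list(SUBJECT_COLUMNS) + ["normalized_speed", "severity"]
            )
        return (
            pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.subjects != other.subjects:
            return False
        key = lambda c: (c.subject_id, c.side, c.cycle_id)
        return sorted(self.cycles, key=key) == sorted(other.cycles, key=key)


def validate_cycle(cycle: GaitCycle) -> list[str]:
    """Check one cycle against the data-model invariants.

    Violations are returned, never raised; each names the offending
    channel and the rule broken.
    """
    tag = f"cycle {cycle.subject_id}/{cycle.side}/{cycle.cycle_id}"
    violations: list[str] = []
    if cycle.side not in ("left", "right"):
        violations.append(f"{tag}: side must be left or right, got {cycle.side!r}")
    for ch in CHANNELS:
        if ch not in cycle.samples:
            violations.append(f"{tag}: missing channel {ch.label}")
    for ch, values in cycle.samples.items():
        if ch not in CHANNELS:
            violations.append(f"{tag}: unknown channel {ch!r}")
            continue
        if values.shape != (N_SAMPLES,):
            violations.append(
                f"{tag}: channel {ch.label} has {values.shape[0] if values.ndim == 1 else values.shape} "
                f"samples, expected {N_SAMPLES}"
            )
        elif not np.isfinite(values).all():
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            violations.append(
                f"{tag}: channel {ch.label} has non-finite angle at sample {bad}"
            )
    return violations


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def cycles_to_frame(cycles: Iterable[GaitCycle]) -> pd.DataFrame:
    """Long-format cycle table with deterministic row order."""
    order = {ch: i for i, ch in enumerate(CHANNELS)}
    recs = []
    for cyc in sorted(cycles, key=lambda c: (c.subject_id, c.cycle_id, c.side)):
        for ch in sorted(cyc.samples, key=lambda c: order.get(c, len(order))):
            vals = cyc.samples[ch]
            recs.append(
                pd.DataFrame(
                    {
                        "subject_id": cyc.subject_id,
                        "side": cyc.side,
                        "cycle_id": cyc.cycle_id,
                        "joint": ch.joint.value,
                        "plane": ch.plane.value,
                        "sample_index": np.arange(len(vals)),
                        "angle_deg": vals,
                    }
                )
            )
    if not recs:
        return pd.DataFrame(columns=list(CYCLE_COLUMNS))
    return pd.concat(recs, ignore_index=True)


def write_cohort(
    cohort: Cohort, cycle_table_path: str | Path, subject_table_path: str | Path
) -> None:
    """Write ``cycles.csv`` and ``subjects.csv``.

    Row and column order are deterministic, so two writes of the same
    cohort produce byte-identical files.  Floats are written with 17
    significant digits, so ``read_cohort`` restores the exact values.
    """
    cycles_to_frame(cohort.cycles).to_csv(
        cycle_table_path, index=False, float_format="%.17g"
    )
    subj = cohort.subject_frame()[list(SUBJECT_COLUMNS)]
    subj.to_csv(subject_table_path, index=False, float_format="%.17g")


def read_cohort(
    cycle_table_path: str | Path, subject_table_path: str | Path
) -> Cohort:
    """Read and validate a cohort from its two CSV tables.

    Raises :class:`CohortValidationError` naming every offending record if
    any invariant fails (wrong sample count, missing channel, non-finite
    angle, unresolved subject_id, malformed joint/plane).
    """
    subj_df = pd.read_csv(subject_table_path, float_precision="round_trip")
    cyc_df = pd.read_csv(cycle_table_path, float_precision="round_trip")

    violations: list[str] = []
    subjects: dict[str, SubjectRecord] = {}
    for _, row in subj_df.iterrows():
        try:
            rec = SubjectRecord(
                subject_id=str(row["subject_id"]),
                condition=str(row["condition"]),
                gmfcs=str(row["gmfcs"]),
                walking_speed=float(row["walking_speed_m_s"]),
                lower_limb_length=float(row["lower_limb_length_m"]),
                gdi=float(row["gdi"]),
                gps=float(row["gps"]),
                map_items={k: float(row[k]) for k in MAP_ITEMS if k in row},
            )
        except CohortValidationError as err:
            violations.extend(err.violations)
            continue
        except (KeyError, ValueError) as err:
            violations.append(f"subject row {row.get('subject_id', '?')}: {err}")
            continue
        subjects[rec.subject_id] = rec

    cycles: list[GaitCycle] = []
    if len(cyc_df):
        for (sid, side, cid), grp in cyc_df.groupby(
            ["subject_id", "side", "cycle_id"], sort=True
        ):
            sid, side, cid = str(sid), str(side), str(cid)
            samples: dict[Channel, np.ndarray] = {}
            for (joint, plane), chgrp in grp.groupby(["joint", "plane"], sort=False):
                try:
                    ch = Channel(Joint(str(joint)), Plane(str(plane)))
                except ValueError:
                    violations.append(
                        f"cycle {sid}/{side}/{cid}: unknown joint/plane "
                        f"{joint!r}/{plane!r}"
                    )
                    continue
                chgrp = chgrp.sort_values("sample_index")
                idx = chgrp["sample_index"].to_numpy()
                if not np.array_equal(idx, np.arange(len(idx))):
                    violations.append(
                        f"cycle {sid}/{side}/{cid}: channel {ch.label} has "
                        f"non-contiguous sample indices"
                    )
                samples[ch] = chgrp["angle_deg"].to_numpy(dtype=float)
            cycles.append(GaitCycle(sid, side, cid, samples))

    cohort = Cohort(subjects=subjects, cycles=cycles)
    violations.extend(cohort.validate())
    if violations:
        raise CohortValidationError(violations)
    return cohort
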