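"""Building antidepressant treatment trajectories from prescription records.

The unit of analysis is a patient's *first* antidepressant treatment
trajectory: consecutive prescriptions of one antidepressant class whose gaps
(next start minus previous end) are at most 30 days, merged into a single
episode.  Before merging, records with implausible doses — below half the
minimal or above five times the maximal therapeutic dose for that drug — are
discarded as data-entry faults.  Outcomes attached to a trajectory are its
duration in days and whether the class was *continued*, i.e. equals the last
antidepressant class the patient received during follow-up; pauses within
the same class are not switches.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AD_CLASSES: tuple[str, ...] = ("MAOI", "SSRI", "TetraCA", "TriCA", "nSSRI", "other")
CO_MED_CLASSES: tuple[str, ...] = ("antipsychotics", "benzodiazepine",
                                   "disulfiram", "lithium")

MERGE_GAP_DAYS = 30          # new script within 30 days of the old one merges
EFFECTIVE_DURATION_DAYS = 35  # >= 5 weeks counts as an effective duration


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_name: str
    dose: float          # mg/day
    start: int           # day index
    end: int             # day index, start <= end

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.patient_id}/{self.drug_name}: start {self.start} "
                f"after end {self.end}")
        if not self.dose > 0:
            raise ValueError(f"{self.patient_id}/{self.drug_name}: dose must be > 0")


@dataclass(frozen=True)
class DoseEntry:
    category: str
    min_dose: float
    max_dose: float


class DoseTable:
    """Drug name -> (class, minimal and maximal therapeutic dose in mg/day)."""

    def __init__(self, entries: Mapping[str, DoseEntry]):
        self._entries = dict(entries)
        for drug, e in self._entries.items():
            if not (0 < e.min_dose <= e.max_dose):
                raise ValueError(f"{drug}: need 0 < min_dose <= max_dose")
            if e.category not in AD_CLASSES + CO_MED_CLASSES:
                raise ValueError(f"{drug}: unknown category {e.category!r}")

    def __contains__(self, drug: str) -> bool:
        return drug in self._entries

    def __getitem__(self, drug: str) -> DoseEntry:
        return self._entries[drug]

    def category(self, drug: str) -> str:
        return self._entries[drug].category

    def drugs_in(self, category: str) -> tuple[str, ...]:
        return tuple(sorted(d for d, e in self._entries.items()
                            if e.category == category))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseTable":
        entries: dict[str, DoseEntry] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["drug_name"]] = DoseEntry(
                    row["category"], float(row["min_dose"]), float(row["max_dose"]))
        return cls(entries)

    @classmethod
    def default(cls) -> "DoseTable":
        """The packaged synthetic dose table (configurable stand-in for a
        national therapeutic-dose reference, which is not redistributable)."""
        return cls.from_csv(Path(__file__).parent / "data" /
                            "synthetic_dose_table.csv")


@dataclass
class TreatmentTrajectory:
    patient_id: str
    ad_class: str
    start: int
    end: int
    co_medication: dict[str, bool] = field(default_factory=dict)
    continued: bool | None = None
    final_class: str | None = None
    # patient-level attributes attached later
    sex_female: bool | None = None
    age: float | None = None
    gaf: float | None = None
    gaf_imputed: bool = False
    dx: dict[str, bool] = field(default_factory=dict)
    sentiment_means: dict[str, float] = field(default_factory=dict)

    @property
    def duration_days(self) -> int:
        # a same-day script has duration 0; the >= 35-day cut is applied to this
        return self.end - self.start


class UnknownDrugError(KeyError):
    def __init__(self, names: Sequence[str]):
        self.names = sorted(set(names))
        super().__init__(f"drugs missing from the dose table: {self.names}")


def filter_doses(records: Iterable[PrescriptionRecord],
                 dose_table: DoseTable) -> list[PrescriptionRecord]:
    """Drop records dosed below half the minimal or above five times the
    maximal therapeutic dose; the boundaries themselves survive.

    Order is preserved and surviving records are returned unchanged.
    """
    records = list(records)
    unknown = [r.drug_name for r in records if r.drug_name not in dose_table]
    if unknown:
        raise UnknownDrugError(unknown)
    out = []
    for r in records:
        e = dose_table[r.drug_name]
        if 0.5 * e.min_dose <= r.dose <= 5.0 * e.max_dose:
            out.append(r)
    return out


def assemble_trajectories(records: Iterable[PrescriptionRecord],
                          dose_table: DoseTable) -> list[TreatmentTrajectory]:
    """Merge per-patient, per-class prescription runs and keep each patient's
    first trajectory as the unit of analysis.

    A new same-class prescription starting within ``MERGE_GAP_DAYS`` of the
    running episode's end extends it.  Ties between two classes starting the
    same day are broken by class-name order.  Co-medication flags are set when
    a co-medication prescription overlaps the trajectory interval by at least
    one day.
    """
    by_patient: dict[str, list[PrescriptionRecord]] = {}
    for r in records:
        if r.drug_name not in dose_table:
            raise UnknownDrugError([r.drug_name])
        by_patient.setdefault(r.patient_id, []).append(r)

    trajectories: list[TreatmentTrajectory] = []
    for pid in sorted(by_patient):
        recs = by_patient[pid]
        episodes: list[TreatmentTrajectory] = []
        for ad_class in AD_CLASSES:
            cls_recs = sorted(
                (r for r in recs if dose_table.category(r.drug_name) == ad_class),
                key=lambda r: (r.start, r.end, r.drug_name))
            current: TreatmentTrajectory | None = None
            for r in cls_recs:
                if current is not None and r.start - current.end <= MERGE_GAP_DAYS:
                    current.end = max(current.end, r.end)
                else:
                    current = TreatmentTrajectory(pid, ad_class, r.start, r.end)
                    episodes.append(current)
        if not episodes:
            continue
        first = min(episodes, key=lambda t: (t.start, t.ad_class))
        comed_recs = [r for r in recs
                      if dose_table.category(r.drug_name) in CO_MED_CLASSES]
        first.co_medication = {
            c: any(dose_table.category(r.drug_name) == c
                   and min(r.end, first.end) - max(r.start, first.start) >= 1
                   for r in comed_recs)
            for c in CO_MED_CLASSES}
        trajectories.append(first)
    return trajectories


def derive_outcomes(trajectory: TreatmentTrajectory,
                    all_patient_records: Iterable[PrescriptionRecord],
                    dose_table: DoseTable) -> TreatmentTrajectory:
    """Set ``continued`` and ``final_class`` from the patient's full follow-up.

    ``continued`` is true when the trajectory's class equals the class of the
    patient's final antidepressant prescription; later prescriptions of the
    same class after a pause therefore do not count as switches.
    """
    recs = [r for r in all_patient_records
            if r.patient_id == trajectory.patient_id
            and dose_table.category(r.drug_name) in AD_CLASSES]
    if not recs:
        raise ValueError(
            f"patient {trajectory.patient_id} has no antidepressant records")
    last_start = max(r.start for r in recs)
    final_classes = sorted({dose_table.category(r.drug_name)
                            for r in recs if r.start == last_start})
    trajectory.continued = trajectory.ad_class in final_classes
    trajectory.final_class = (trajectory.ad_class if trajectory.continued
                              else final_classes[0])
    return trajectory


def switch_flow_table(trajectories: Sequence[TreatmentTrajectory],
                      records: Iterable[PrescriptionRecord],
                      dose_table: DoseTable):
    """Counts of (initial class x final class) among non-continued
    trajectories; the diagonal is allowed but empty under the final-class
    definition of continuation."""
    import pandas as pd

    records = list(records)
    table = pd.DataFrame(0, index=list(AD_CLASSES), columns=list(AD_CLASSES))
    for t in trajectories:
        if t.continued is None:
            derive_outcomes(t, [r for r in records
                                if r.patient_id == t.patient_id], dose_table)
        if not t.continued:
            table.loc[t.ad_class, t.final_class] += 1
    table.index.name = "initial"
    table.columns.name = "final"
    return table


def attach_patient_data(trajectories: Sequence[TreatmentTrajectory],
                        patients, gaf) -> list[TreatmentTrajectory]:
    """Copy demographics, DSM flags and (possibly missing) GAF scores onto
    trajectories from per-patient tables indexed by ``patient_id``."""
    pat = patients.set_index("patient_id") if "patient_id" in patients else patients
    gaf_map = dict(zip(gaf["patient_id"], gaf["gaf"]))
    dx_cols = [c for c in pat.columns if c.startswith("dx_")]
    out = []
    for t in trajectories:
        row = pat.loc[t.patient_id]
        t.sex_female = bool(row["sex_female"])
        t.age = float(row["age"])
        g = gaf_map.get(t.patient_id, float("nan"))
        t.gaf = None if (g is None or (isinstance(g, float) and math.isnan(g))) else float(g)
        t.dx = {c: bool(row[c]) for c in dx_cols}
        out.append(t)
    return out


def read_prescriptions_csv(path: str | Path) -> list[PrescriptionRecord]:
    with open(path, newline="") as fh:
        return [PrescriptionRecord(row["patient_id"], row["drug_name"],
                                   float(row["dose"]), int(row["start"]),
                                   int(row["end"]))
                for row in csv.DictReader(fh)]


def write_prescriptions_csv(records: Iterable[PrescriptionRecord],
                            path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "drug_name", "dose", "start", "end"])
        for r in records:
            w.writerow([r.patient_id, r.drug_name, r.dose, r.start, r.end])
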