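"""Data model and table I/O for ADC test-retest repeatability studies.

The core objects are per-session ROI summaries (:class:`ROIMeasurement`),
matched test/retest pairs (:class:`TestRetestPair`), and per-pair
repeatability records (:class:`RepeatabilityRecord`).  ADC values are kept
in units of 10^-5 mm^2/s throughout, the convention used for all printed
liver-DWI numbers this package works with; helpers to convert to SI
(mm^2/s) are provided.

ROI tables are delimiter-separated text with a header row and columns
``patient_id, roi_kind, session, n_voxels, mean_adc, adc_sd, motion_flag``.
A small per-patient summary of the study cohort (average voxel count,
volume change, average mean ADC, ADC change, lesion and motion notes) is
packaged as a CSV fixture and exposed via :func:`load_table2_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ROI_KINDS = ("whole_3d", "slice_largest", "slice_solid", "parenchyma")
SESSIONS = ("test", "retest")

ADC_UNIT_TO_SI = 1e-5  # 1 table unit = 1e-5 mm^2/s

ROI_TABLE_COLUMNS = (
    "patient_id",
    "roi_kind",
    "session",
    "n_voxels",
    "mean_adc",
    "adc_sd",
    "motion_flag",
)


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class RowValidationError(ValueError):
    """A table row violates a domain invariant; carries the row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class AmbiguityError(ValueError):
    """Duplicate (patient, roi_kind, session) keys make pairing ambiguous."""


class InsufficientDataError(ValueError):
    """Too few records for the requested computation."""


def adc_to_si(value: float) -> float:
    """Convert an ADC value in 10^-5 mm^2/s to mm^2/s."""
    return value * ADC_UNIT_TO_SI


def adc_from_si(value: float) -> float:
    """Convert an ADC value in mm^2/s to 10^-5 mm^2/s."""
    return value / ADC_UNIT_TO_SI


@dataclass(frozen=True)
class ROIMeasurement:
    """One session's summary of an ROI's ADC histogram.

    Parameters
    ----------
    patient_id : str
        Opaque subject label.
    roi_kind : str
        One of ``whole_3d``, ``slice_largest``, ``slice_solid``,
        ``parenchyma``.
    session : str
        ``test`` or ``retest``.
    n_voxels : int
        Number of voxels in the ROI (>= 1).
    mean_adc : float
        Mean ADC over the ROI, in 10^-5 mm^2/s (> 0).
    adc_sd : float
        Standard deviation of the ROI's ADC histogram, same units (>= 0).
    motion_flag : bool
        True when visible motion artefact was recorded for this session.
    """

    patient_id: str
    roi_kind: str
    session: str
    n_voxels: int
    mean_adc: float
    adc_sd: float
    motion_flag: bool = False

    def __post_init__(self) -> None:
        if self.roi_kind not in ROI_KINDS:
            raise ValueError(f"unknown roi_kind {self.roi_kind!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        if int(self.n_voxels) < 1:
            raise ValueError(f"n_voxels must be >= 1, got {self.n_voxels}")
        if not self.mean_adc > 0:
            raise ValueError(f"mean_adc must be > 0, got {self.mean_adc}")
        if self.adc_sd < 0:
            raise ValueError(f"adc_sd must be >= 0, got {self.adc_sd}")

    @property
    def sem(self) -> float:
        """Standard error of the ROI mean: histogram SD / sqrt(N)."""
        return self.adc_sd / float(self.n_voxels) ** 0.5


@dataclass(frozen=True)
class TestRetestPair:
    """Matched test/retest measurements of the same ROI.

    ``sem_1``/``sem_2`` are the per-session standard errors of the ROI
    mean, w_j / sqrt(N_j).
    """

    __test__ = False  # "Test" prefix is domain vocabulary, not a test class

    roi_1: ROIMeasurement
    roi_2: ROIMeasurement

    def __post_init__(self) -> None:
        if self.roi_1.patient_id != self.roi_2.patient_id:
            raise ValueError("pair spans different patients")
        if self.roi_1.roi_kind != self.roi_2.roi_kind:
            raise ValueError("pair spans different ROI kinds")
        if self.roi_1.session == self.roi_2.session:
            raise ValueError("pair needs distinct sessions")

    @property
    def patient_id(self) -> str:
        return self.roi_1.patient_id

    @property
    def roi_kind(self) -> str:
        return self.roi_1.roi_kind

    @property
    def sem_1(self) -> float:
        return self.roi_1.sem

    @property
    def sem_2(self) -> float:
        return self.roi_2.sem

    @property
    def motion(self) -> bool:
        """True if either session is motion-flagged."""
        return self.roi_1.motion_flag or self.roi_2.motion_flag


@dataclass(frozen=True)
class RepeatabilityRecord:
    """Per-pair repeatability with (optionally) its modelled uncertainty.

    ``r12`` is the symmetric percentage ADC change between sessions,
    ``delta_vol_pct`` the analogous volume change, ``epsilon_r12`` the
    model-predicted uncertainty of ``r12`` (percent) and ``z`` the
    standardised residual r12 / epsilon_r12.
    """

    pair: TestRetestPair
    r12: float
    delta_vol_pct: float
    epsilon_r12: float | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.r12):
            raise ValueError("r12 must be finite")
        if self.z is not None and not (self.epsilon_r12 or 0) > 0:
            raise ValueError("z populated but epsilon_r12 not positive")

    @property
    def motion(self) -> bool:
        return self.pair.motion

    def with_uncertainty(self, epsilon: float) -> "RepeatabilityRecord":
        if not epsilon > 0:
            raise ValueError("epsilon_r12 must be > 0")
        return replace(self, epsilon_r12=epsilon, z=self.r12 / epsilon)


@dataclass
class ParseReport:
    """Row accounting for a table read."""

    n_read: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class ROITable:
    """Parsed ROI table: measurements in file order plus a parse report."""

    measurements: list[ROIMeasurement]
    report: ParseReport

    def __iter__(self):
        return iter(self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)


_TRUE = {"1", "true", "yes", "motion"}
_FALSE = {"0", "false", "no", "", "nan", "none"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a flag")


def read_roi_table(path: str | Path, *, delimiter: str | None = None,
                   strict: bool = True) -> ROITable:
    """Read a delimiter-separated ROI summary table.

    With ``strict=True`` (default) any invalid row raises
    :class:`RowValidationError` naming the offending row; with
    ``strict=False`` invalid rows are collected in the parse report and
    valid rows are returned in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, engine="python",
                     dtype=str, skipinitialspace=True)
    missing = [c for c in ROI_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    measurements: list[ROIMeasurement] = []
    report = ParseReport()
    for i, row in df.iterrows():
        report.n_read += 1
        try:
            m = ROIMeasurement(
                patient_id=str(row["patient_id"]).strip(),
                roi_kind=str(row["roi_kind"]).strip(),
                session=str(row["session"]).strip(),
                n_voxels=int(float(row["n_voxels"])),
                mean_adc=float(row["mean_adc"]),
                adc_sd=float(row["adc_sd"]),
                motion_flag=_parse_bool(row["motion_flag"]),
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise RowValidationError(int(i), str(exc)) from exc
            report.rejected.append((int(i), str(exc)))
            continue
        measurements.append(m)
    return ROITable(measurements, report)


def write_roi_table(measurements: Iterable[ROIMeasurement],
                    path: str | Path, *, delimiter: str = ",") -> None:
    """Write measurements to a delimited text table (lossless round-trip)."""
    rows = [
        {
            "patient_id": m.patient_id,
            "roi_kind": m.roi_kind,
            "session": m.session,
            "n_voxels": m.n_voxels,
            "mean_adc": repr(float(m.mean_adc)),
            "adc_sd": repr(float(m.adc_sd)),
            "motion_flag": int(m.motion_flag),
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=list(ROI_TABLE_COLUMNS)).to_csv(
        path, sep=delimiter, index=False)


@dataclass
class PairingResult:
    """Pairs formed by :func:`pair_sessions` plus unpaired leftovers."""

    pairs: list[TestRetestPair]
    unpaired: list[ROIMeasurement]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def pair_sessions(measurements: Iterable[ROIMeasurement]) -> PairingResult:
    """Match test/retest sessions into pairs per (patient, roi_kind).

    Unpaired measurements are reported, never silently dropped.  Duplicate
    (patient, roi_kind, session) keys raise :class:`AmbiguityError`.
    """
    by_key: dict[tuple[str, str], dict[str, ROIMeasurement]] = {}
    order: list[tuple[str, str]] = []
    for m in measurements:
        key = (m.patient_id, m.roi_kind)
        slot = by_key.setdefault(key, {})
        if key not in order:
            order.append(key)
        if m.session in slot:
            raise AmbiguityError(
                f"duplicate measurement for patient={m.patient_id!r} "
                f"roi_kind={m.roi_kind!r} session={m.session!r}")
        slot[m.session] = m
    pairs, unpaired = [], []
    for key in order:
        slot = by_key[key]
        if "test" in slot and "retest" in slot:
            pairs.append(TestRetestPair(slot["test"], slot["retest"]))
        else:
            unpaired.extend(slot.values())
    return PairingResult(pairs, unpaired)


# ---------------------------------------------------------------------------
# Packaged per-patient cohort summary (20 colorectal liver metastases,
# whole-tumour 3D ROIs; averages of the two baselines plus the printed
# percentage changes).

@dataclass(frozen=True)
class Table2Row:
    patient_id: str
    avg_voxels: int
    delta_vol_pct: float
    avg_mean_adc: float
    delta_adc_pct: float
    lesion_note: str
    motion_flag: bool


@dataclass
class Table2Fixture:
    """Per-patient 3D whole-tumour summary of the 20-patient cohort.

    Stores session *averages* and printed percentage deltas only — the
    per-session values and histogram widths were not published — so this
    fixture supports group statistics, not per-ROI model fitting.
    """

    rows: list[Table2Row]

    def __post_init__(self) -> None:
        if len(self.rows) != 20:
            raise ValueError(f"expected 20 rows, got {len(self.rows)}")
        n_motion = sum(r.motion_flag for r in self.rows)
        if n_motion != 5:
            raise ValueError(f"expected 5 motion-flagged rows, got {n_motion}")
        for r in self.rows:
            if not 76 <= r.avg_mean_adc <= 198:
                raise ValueError(
                    f"avg_mean_adc {r.avg_mean_adc} outside [76, 198]")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged cohort summary table."""
    with resources.files("adcrepeat.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    rows = [
        Table2Row(
            patient_id=r["patient_id"],
            avg_voxels=int(r["avg_voxels"]),
            delta_vol_pct=float(r["delta_vol_pct"]),
            avg_mean_adc=float(r["avg_mean_adc"]),
            delta_adc_pct=float(r["delta_adc_pct"]),
            lesion_note=r["lesion_note"],
            motion_flag=_parse_bool(r["motion_flag"]),
        )
        for _, r in df.iterrows()
    ]
    return Table2Fixture(rows)


def write_records_csv(records: Sequence[RepeatabilityRecord],
                      path: str | Path) -> None:
    """One row per repeatability record (pair fields flattened)."""
    rows = []
    for rec in records:
        p = rec.pair
        rows.append({
            "patient_id": p.patient_id,
            "roi_kind": p.roi_kind,
            "n_voxels_1": p.roi_1.n_voxels,
            "n_voxels_2": p.roi_2.n_voxels,
            "mean_adc_1": repr(float(p.roi_1.mean_adc)),
            "mean_adc_2": repr(float(p.roi_2.mean_adc)),
            "adc_sd_1": repr(float(p.roi_1.adc_sd)),
            "adc_sd_2": repr(float(p.roi_2.adc_sd)),
            "r12": repr(float(rec.r12)),
            "delta_vol_pct": repr(float(rec.delta_vol_pct)),
            "epsilon_r12": "" if rec.epsilon_r12 is None else repr(float(rec.epsilon_r12)),
            "z": "" if rec.z is None else repr(float(rec.z)),
            "motion": int(rec.motion),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[RepeatabilityRecord]:
    """Inverse of :func:`write_records_csv`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, r in df.iterrows():
        motion = _parse_bool(r["motion"])
        m1 = ROIMeasurement(r["patient_id"], r["roi_kind"], "test",
                            int(r["n_voxels_1"]), float(r["mean_adc_1"]),
                            float(r["adc_sd_1"]), motion)
        m2 = ROIMeasurement(r["patient_id"], r["roi_kind"], "retest",
                            int(r["n_voxels_2"]), float(r["mean_adc_2"]),
                            float(r["adc_sd_2"]), False)
        rec = RepeatabilityRecord(
            TestRetestPair(m1, m2),
            r12=float(r["r12"]),
            delta_vol_pct=float(r["delta_vol_pct"]),
        )
        eps = r.get("epsilon_r12", "")
        if eps not in ("", None):
            rec = rec.with_uncertainty(float(eps))
        records.append(rec)
    return records


def write_params_json(obj, path: str | Path, **extra) -> None:
    """Serialise fitted parameters (or any mapping-like) with metadata."""
    if hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    else:
        payload = dict(obj)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
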