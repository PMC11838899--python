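"""Dataset containers and long-format CSV I/O.

The unit of analysis is the content of one "2Dmito" plot: per-fibre protein
abundances for one patient and a handful of healthy control subjects, with a
mitochondrial-mass channel (x, e.g. VDAC) paired against one OXPHOS channel
(y, e.g. NDUFB8).  Input tables are tidy/long CSV with columns
``fibre_id, subject_id, subject_type, channel, value``; a fibre contributes
one row per channel.  Pairing is by exact ``(subject_id, fibre_id)`` match;
fibres missing either channel are dropped and counted, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("fibre_id", "subject_id", "subject_type", "channel", "value")

CONTROL = "control"
PATIENT = "patient"


class DataFormatError(ValueError):
    """The input table does not have the expected long-format shape."""


class DatasetStructureError(ValueError):
    """The table parses but cannot form a valid control(s)-plus-patient dataset."""


@dataclass
class SubjectBlock:
    """Paired (x, y) arrays for one subject, aligned by fibre."""

    subject_id: str
    subject_type: str  # "control" or "patient"
    fibre_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.fibre_ids = np.asarray(self.fibre_ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.fibre_ids) == len(self.x) == len(self.y)):
            raise DatasetStructureError(
                f"subject {self.subject_id!r}: unequal fibre_id/x/y lengths"
            )
        if self.subject_type not in (CONTROL, PATIENT):
            raise DatasetStructureError(
                f"subject {self.subject_id!r}: unknown subject_type {self.subject_type!r}"
            )

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class LoadReport:
    """Bookkeeping for rows dropped while assembling a dataset."""

    n_fibres: dict = field(default_factory=dict)
    n_dropped_unpaired: int = 0
    n_dropped_nonpositive: int = 0

    def to_dict(self) -> dict:
        return {
            "n_fibres": dict(self.n_fibres),
            "n_dropped_unpaired": int(self.n_dropped_unpaired),
            "n_dropped_nonpositive": int(self.n_dropped_nonpositive),
        }


@dataclass
class MitoDataset:
    """One 2Dmito plot: k-1 control subjects plus exactly one patient (last).

    ``x`` holds the mass-channel values and ``y`` the OXPHOS-channel values,
    either raw intensities (``logged=False``) or natural logs (``logged=True``).
    Subject order is stable: controls in input order, patient last, matching
    the model convention that subjects 1..k-1 are controls and k the patient.
    """

    mass_channel: str
    oxphos_channel: str
    subjects: list  # list[SubjectBlock], patient last
    logged: bool = False

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise DatasetStructureError("need at least one control and one patient")
        n_pat = sum(s.subject_type == PATIENT for s in self.subjects)
        if n_pat != 1:
            raise DatasetStructureError(f"expected exactly one patient, found {n_pat}")
        if self.subjects[-1].subject_type != PATIENT:
            raise DatasetStructureError("patient must be the last subject block")

    @property
    def k(self) -> int:
        return len(self.subjects)

    @property
    def controls(self) -> list:
        return self.subjects[:-1]

    @property
    def patient(self) -> SubjectBlock:
        return self.subjects[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (fibre, channel)."""
        rows = []
        for s in self.subjects:
            for fid, xv, yv in zip(s.fibre_ids, s.x, s.y):
                rows.append((fid, s.subject_id, s.subject_type, self.mass_channel, xv))
                rows.append((fid, s.subject_id, s.subject_type, self.oxphos_channel, yv))
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def save(self, path) -> None:
        """Write the long-format CSV.  Values round-trip bitwise via repr."""
        self.to_frame().to_csv(path, index=False)


def load_dataset(path, mass_channel: str, oxphos_channel: str, patient_id: str,
                 control_ids=None):
    """Read a long-format CSV into a raw-valued :class:`MitoDataset`.

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``fibre_id, subject_id, subject_type, channel, value``.
    mass_channel, oxphos_channel : str
        Channel names to pair as (x, y).
    patient_id : str
        Subject to place last as the patient; its ``subject_type`` rows are
        not trusted to be consistent — membership is by id.
    control_ids : sequence of str, optional
        Restrict controls to these subjects (default: all control-typed
        subjects in the file).

    Returns
    -------
    (MitoDataset, LoadReport)
    """
    df = pd.read_csv(path, dtype={"fibre_id": str, "subject_id": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing required columns: {missing}")

    subject_ids = df["subject_id"].unique().tolist()
    if patient_id not in subject_ids:
        raise LookupError(f"patient_id {patient_id!r} not present in table")
    if control_ids is None:
        control_ids = [
            s for s in subject_ids
            if s != patient_id
            and (df.loc[df.subject_id == s, "subject_type"] == CONTROL).any()
        ]
    else:
        control_ids = [str(c) for c in control_ids]
        absent = [c for c in control_ids if c not in subject_ids]
        if absent:
            raise LookupError(f"control subjects not present in table: {absent}")
    if len(control_ids) == 0:
        raise DatasetStructureError("no control subjects found")

    report = LoadReport()
    blocks = []
    for sid in list(control_ids) + [patient_id]:
        stype = CONTROL if sid != patient_id else PATIENT
        sub = df[df.subject_id == sid]
        wide = (
            sub[sub.channel.isin([mass_channel, oxphos_channel])]
            .pivot_table(index="fibre_id", columns="channel", values="value",
                         aggfunc="first", sort=False)
        )
        for ch in (mass_channel, oxphos_channel):
            if ch not in wide.columns:
                wide[ch] = np.nan
        paired = wide.dropna(subset=[mass_channel, oxphos_channel])
        report.n_dropped_unpaired += len(wide) - len(paired)
        if len(paired) == 0:
            raise DatasetStructureError(
                f"subject {sid!r} has no fibres with both channels"
            )
        report.n_fibres[sid] = len(paired)
        blocks.append(SubjectBlock(
            subject_id=sid,
            subject_type=stype,
            fibre_ids=paired.index.to_numpy(),
            x=paired[mass_channel].to_numpy(),
            y=paired[oxphos_channel].to_numpy(),
        ))
    return MitoDataset(mass_channel, oxphos_channel, blocks, logged=False), report


def log_transform(dataset: MitoDataset):
    """Natural-log transform of both channels.

    Fibres with any non-positive value are excluded (log would be non-finite)
    and counted in the returned report; intensities are never offset by a
    pseudo-count, which would distort the low-intensity tail.
    """
    report = LoadReport()
    blocks = []
    for s in dataset.subjects:
        keep = (s.x > 0) & (s.y > 0) & np.isfinite(s.x) & np.isfinite(s.y)
        report.n_dropped_nonpositive += int((~keep).sum())
        if not keep.any():
            raise DatasetStructureError(
                f"subject {s.subject_id!r}: all fibres excluded by positivity filter"
            )
        report.n_fibres[s.subject_id] = int(keep.sum())
        blocks.append(SubjectBlock(
            s.subject_id, s.subject_type,
            s.fibre_ids[keep], np.log(s.x[keep]), np.log(s.y[keep]),
        ))
    return (
        MitoDataset(dataset.mass_channel, dataset.oxphos_channel, blocks, logged=True),
        report,
    )


def exp_transform(dataset: MitoDataset) -> MitoDataset:
    """Inverse of :func:`log_transform` (back to raw intensity scale)."""
    blocks = [
        SubjectBlock(s.subject_id, s.subject_type, s.fibre_ids,
                     np.exp(s.x), np.exp(s.y))
        for s in dataset.subjects
    ]
    return MitoDataset(dataset.mass_channel, dataset.oxphos_channel, blocks,
                       logged=False)


@dataclass
class ValidationReport:
    subject_stats: list
    warnings: list

    @property
    def ok(self) -> bool:
        return not self.warnings

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"subjects": self.subject_stats, "warnings": self.warnings}, **kwargs
        )


def validate(dataset: MitoDataset) -> ValidationReport:
    """Report-only sanity checks; never mutates or raises."""
    stats, warnings = [], []
    for s in dataset.subjects:
        nan_x, nan_y = int(np.isnan(s.x).sum()), int(np.isnan(s.y).sum())
        finite_x = s.x[np.isfinite(s.x)]
        finite_y = s.y[np.isfinite(s.y)]
        stats.append({
            "subject_id": str(s.subject_id),
            "subject_type": s.subject_type,
            "n": int(s.n),
            "x_min": float(finite_x.min()) if finite_x.size else None,
            "x_max": float(finite_x.max()) if finite_x.size else None,
            "y_min": float(finite_y.min()) if finite_y.size else None,
            "y_max": float(finite_y.max()) if finite_y.size else None,
            "nan_count": nan_x + nan_y,
        })
        if nan_x or nan_y:
            bad = s.fibre_ids[np.isnan(s.x) | np.isnan(s.y)]
            for fid in bad:
                warnings.append(
                    f"subject {s.subject_id!r}: NaN value in fibre {fid!r}"
                )
        ids, counts = np.unique(s.fibre_ids, return_counts=True)
        for fid in ids[counts > 1]:
            warnings.append(
                f"subject {s.subject_id!r}: duplicate fibre_id {fid!r}"
            )
    return ValidationReport(stats, warnings)
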