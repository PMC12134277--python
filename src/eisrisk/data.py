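"""Data model, label semantics and file I/O for EIS cohorts.

An :class:`EISReading` is the atomic analysis unit: one 14-frequency complex
impedance spectrum (28 features: 14 real parts then 14 reactive parts, both
in ascending frequency order) with subject, anatomical-site, WHO-grade and
binary risk-label metadata.  Readings nest within subjects; a subject
carries exactly one WHO grade.

Interchange format is CSV with a small machine-readable metadata header of
``# key=value`` lines (f_min, n_steps, seed), then columns::

    reading_id, subject_id, site, who_grade, binary_label,
    re_00..re_13, im_00..im_13

The reactive columns store the non-negative convention Z = Z_Re - j*Z_Im.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from ._exceptions import FormatError, InvalidArgumentError

if TYPE_CHECKING:  # pragma: no cover
    from .synth import FrequencyGrid

WHO_GRADES = (
    "healthy",
    "non_dysplastic",
    "mild",
    "moderate",
    "severe",
    "cancer",
    "treated",
)

#: WHO grades mapped deterministically to the binary risk scale; moderate
#: dysplasia is the only probabilistic grade (histopathological binary
#: grading is an independent assessment, and the study's own site-pooled
#: counts split moderate cases across both groups).
_LOW_RISK_GRADES = frozenset({"healthy", "non_dysplastic", "mild"})
_HIGH_RISK_GRADES = frozenset({"severe", "cancer", "treated"})

N_FREQUENCIES = 14
N_FEATURES = 2 * N_FREQUENCIES


@dataclass(frozen=True)
class EISReading:
    """One impedance spectrum with its metadata."""

    reading_id: str
    subject_id: str
    site: str
    z_re: tuple[float, ...]
    z_im: tuple[float, ...]
    who_grade: str
    binary_label: str = ""

    def __post_init__(self) -> None:
        if len(self.z_re) != N_FREQUENCIES or len(self.z_im) != N_FREQUENCIES:
            raise FormatError(
                f"reading {self.reading_id!r}: expected {N_FREQUENCIES} real and "
                f"{N_FREQUENCIES} imaginary values, got {len(self.z_re)}/{len(self.z_im)}"
            )
        if self.who_grade not in WHO_GRADES:
            raise InvalidArgumentError(
                f"reading {self.reading_id!r}: unknown WHO grade {self.who_grade!r}"
            )
        if any(not np.isfinite(v) for v in self.z_re + self.z_im):
            raise FormatError(f"reading {self.reading_id!r}: non-finite impedance value")


def to_feature_vector(reading: EISReading) -> np.ndarray:
    """28-element feature vector: real parts then reactive parts, ascending frequency."""
    return np.asarray(reading.z_re + reading.z_im, dtype=float)


def assign_binary_label(
    who_grade: str,
    u: float = 0.0,
    moderate_to_highrisk_fraction: float = 2.0 / 3.0,
) -> str:
    """Map a WHO grade to the binary risk scale.

    healthy / non-dysplastic / mild -> low_risk; severe / cancer (and the
    porcine acid-treated class) -> high_risk; moderate -> high_risk iff the
    uniform draw ``u`` falls below ``moderate_to_highrisk_fraction``.
    """
    if who_grade in _LOW_RISK_GRADES:
        return "low_risk"
    if who_grade in _HIGH_RISK_GRADES:
        return "high_risk"
    if who_grade == "moderate":
        return "high_risk" if u < moderate_to_highrisk_fraction else "low_risk"
    raise InvalidArgumentError(f"unknown WHO grade {who_grade!r}")


@dataclass
class EISDataset:
    """A cohort of readings sharing one frequency grid."""

    readings: list[EISReading]
    grid: "FrequencyGrid"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grades: dict[str, str] = {}
        for r in self.readings:
            prev = grades.setdefault(r.subject_id, r.who_grade)
            if prev != r.who_grade:
                raise FormatError(
                    f"subject {r.subject_id!r} carries two WHO grades "
                    f"({prev!r} and {r.who_grade!r})"
                )

    def __len__(self) -> int:
        return len(self.readings)

    def feature_matrix(self) -> np.ndarray:
        """(n_readings, 28) feature matrix in reading order."""
        if not self.readings:
            return np.empty((0, N_FEATURES))
        return np.stack([to_feature_vector(r) for r in self.readings])

    def subject_ids(self) -> np.ndarray:
        return np.array([r.subject_id for r in self.readings])

    def who_grades(self) -> np.ndarray:
        return np.array([r.who_grade for r in self.readings])

    def binary_labels(self) -> np.ndarray:
        return np.array([r.binary_label for r in self.readings])

    def task_labels(self, task: int) -> np.ndarray:
        """Per-reading class labels for one of the three diagnostic tasks.

        Task 1 (porcine) and Task 3 (human composite) are binary
        low_risk/high_risk; in Task 3 the healthy readings join the
        composite low-risk class.  Task 2 keeps healthy readings as a
        separate ``normal`` class alongside lesional low_risk/high_risk.
        """
        if task not in (1, 2, 3):
            raise InvalidArgumentError(f"task must be 1, 2 or 3, got {task}")
        grades = self.who_grades()
        binary = self.binary_labels()
        if task == 2:
            return np.where(grades == "healthy", "normal", binary)
        return binary

    def class_counts(self) -> dict[str, tuple[int, int]]:
        """Per-WHO-grade (n_subjects, n_readings) counts."""
        out: dict[str, tuple[int, int]] = {}
        for grade in sorted(set(r.who_grade for r in self.readings)):
            subs = {r.subject_id for r in self.readings if r.who_grade == grade}
            n_read = sum(1 for r in self.readings if r.who_grade == grade)
            out[grade] = (len(subs), n_read)
        return out

    def subset(self, indices: Iterable[int]) -> "EISDataset":
        return EISDataset(
            readings=[self.readings[i] for i in indices],
            grid=self.grid,
            provenance=dict(self.provenance),
        )


_META_COLS = ["reading_id", "subject_id", "site", "who_grade", "binary_label"]
_RE_COLS = [f"re_{k:02d}" for k in range(N_FREQUENCIES)]
_IM_COLS = [f"im_{k:02d}" for k in range(N_FREQUENCIES)]
_ALL_COLS = _META_COLS + _RE_COLS + _IM_COLS


def write_dataset(ds: EISDataset, path: str | Path) -> None:
    """Write a dataset to CSV with the '#'-prefixed metadata header.

    Numeric cells use ``repr`` precision so a write/read round-trip is
    bit-exact.
    """
    path = Path(path)
    rows = []
    for r in ds.readings:
        row = [r.reading_id, r.subject_id, r.site, r.who_grade, r.binary_label]
        row += [repr(float(v)) for v in r.z_re] + [repr(float(v)) for v in r.z_im]
        rows.append(row)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# f_min={ds.grid.f_min}\n")
        fh.write(f"# n_steps={ds.grid.n_steps}\n")
        for key, value in sorted(ds.provenance.items()):
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(_ALL_COLS) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


def read_dataset(path: str | Path) -> EISDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`FormatError` naming the offending row/column on missing
    columns, non-numeric impedance cells, or a subject carrying two grades.
    """
    from .synth import build_frequency_grid  # deferred: synth imports data

    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), dtype=str)
    missing = [c for c in _ALL_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in _ALL_COLS]
    if extra:
        raise FormatError(f"{path}: unexpected columns {extra}")

    readings = []
    for idx, row in df.iterrows():
        try:
            z_re = tuple(float(row[c]) for c in _RE_COLS)
            z_im = tuple(float(row[c]) for c in _IM_COLS)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric impedance cell in row {idx}") from exc
        readings.append(
            EISReading(
                reading_id=str(row["reading_id"]),
                subject_id=str(row["subject_id"]),
                site=str(row["site"]),
                z_re=z_re,
                z_im=z_im,
                who_grade=str(row["who_grade"]),
                binary_label="" if pd.isna(row["binary_label"]) else str(row["binary_label"]),
            )
        )
    grid = build_frequency_grid(
        f_min=float(meta.get("f_min", 76.0)), n_steps=int(meta.get("n_steps", 14))
    )
    provenance = {k: v for k, v in meta.items() if k not in ("f_min", "n_steps")}
    provenance["path"] = str(path)
    return EISDataset(readings=readings, grid=grid, provenance=provenance)
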