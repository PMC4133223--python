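"""Worst-eye normalized-error evaluation protocol.

Detections are scored per image against ground-truth eye centers with

    e = max(d_left, d_right) / d

where d_left / d_right are the Euclidean distances between estimated and true
centers and d is the true interocular distance.  Landmark thresholds:
e <= 0.25 roughly spans the eye corners, e <= 0.10 the iris, e <= 0.05 the
pupil.  Accuracy curves report the fraction of images with e <= t over a
threshold grid (inclusive comparison).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("pupilloc")

LANDMARK_THRESHOLDS = (0.05, 0.10, 0.25)


@dataclass(frozen=True)
class EyeGroundTruth:
    image_id: str
    left: tuple[float, float]
    right: tuple[float, float]

    def __post_init__(self) -> None:
        if self.interocular == 0.0:
            raise ValueError(f"{self.image_id}: left and right eye centers coincide")

    @property
    def interocular(self) -> float:
        return math.dist(self.left, self.right)


@dataclass(frozen=True)
class EvalRecord:
    image_id: str
    d_left: float
    d_right: float
    interocular: float
    e: float


def normalized_error(est_left: tuple[float, float], est_right: tuple[float, float],
                     truth: EyeGroundTruth) -> EvalRecord:
    """Worst-eye error of one image's pair of estimates."""
    d = truth.interocular
    if d == 0.0:
        raise ValueError("ground truth has zero interocular distance")
    dl = math.dist(est_left, truth.left)
    dr = math.dist(est_right, truth.right)
    return EvalRecord(image_id=truth.image_id, d_left=dl, d_right=dr,
                      interocular=d, e=max(dl, dr) / d)


@dataclass(frozen=True)
class AccuracyCurve:
    thresholds: np.ndarray
    fractions: np.ndarray

    def at(self, t: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - t)))
        if not math.isclose(self.thresholds[idx], t, abs_tol=1e-12):
            raise KeyError(f"threshold {t} not on the curve grid")
        return float(self.fractions[idx])


def default_thresholds() -> np.ndarray:
    """0 to 0.30 in steps of 0.01 (contains the 0.05/0.10/0.25 landmarks)."""
    return np.round(np.arange(0, 31) * 0.01, 10)


def accuracy_curve(records: list[EvalRecord],
                   thresholds: np.ndarray | None = None) -> AccuracyCurve:
    """Fraction of images with e <= t for each threshold t."""
    if not records:
        raise ValueError("cannot build an accuracy curve from zero records")
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=np.float64)
    errors = np.array([r.e for r in records])
    fractions = np.array([(errors <= t).mean() for t in thresholds])
    return AccuracyCurve(thresholds=thresholds, fractions=fractions)


def _parse_float(tok: str, where: str) -> float:
    try:
        return float(tok)
    except ValueError as exc:
        raise ValueError(f"{where}: not a number: {tok!r}") from exc


def read_ground_truth(path: str | Path, dialect: str = "csv") -> list[EyeGroundTruth]:
    """Read ground-truth eye centers.

    ``csv``: one ``image_id,lx,ly,rx,ry`` row per image (optional header).
    ``sidecar``: a per-image file, comment lines starting with ``#``, then one
    ``LX LY RX RY`` line; the image id is the file stem.
    """
    path = Path(path)
    truths: list[EyeGroundTruth] = []
    if dialect == "csv":
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or (lineno == 1 and row[0].strip().lower() == "image_id"):
                    continue
                if len(row) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 CSV fields, got {len(row)}")
                where = f"{path}:{lineno}"
                vals = [_parse_float(tok, where) for tok in row[1:]]
                truths.append(EyeGroundTruth(image_id=row[0].strip(),
                                             left=(vals[0], vals[1]),
                                             right=(vals[2], vals[3])))
    elif dialect == "sidecar":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'LX LY RX RY'")
            where = f"{path}:{lineno}"
            vals = [_parse_float(tok, where) for tok in parts]
            truths.append(EyeGroundTruth(image_id=path.stem,
                                         left=(vals[0], vals[1]),
                                         right=(vals[2], vals[3])))
            break  # one record per sidecar file
    else:
        raise ValueError(f"unknown ground-truth dialect: {dialect!r}")
    if not truths:
        logger.warning("no ground-truth records found in %s", path)
    return truths


def write_records_csv(records: list[EvalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "d_left", "d_right", "interocular", "e"])
        for r in records:
            writer.writerow([r.image_id, f"{r.d_left:.6f}", f"{r.d_right:.6f}",
                             f"{r.interocular:.6f}", f"{r.e:.6f}"])


def write_curve_csv(curve: AccuracyCurve, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "fraction"])
        for t, f in zip(curve.thresholds, curve.fractions):
            writer.writerow([f"{t:.2f}", f"{f:.6f}"])
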