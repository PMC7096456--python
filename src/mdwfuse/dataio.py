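"""Reading and writing of spectra tables, reference concentrations and fitted models.

File dialect is deliberately plain: comma-separated UTF-8 text with ``.`` as
decimal separator. Floating-point values are written at full ``repr``
precision (17 significant digits) so that write/read round-trips are exact.
Fitted calibrations are serialized as versioned JSON; the calibration score
matrix is part of the payload because Mahalanobis distances are computed in
score space and therefore need it at prediction time.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MODEL_FORMAT_TAG = "mdwfuse-pls-model"
MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class SpectraTable:
    """Sample-by-wavenumber absorbance matrix for one sensor.

    Wavenumbers are normalized to ascending order on construction; a table
    built from a descending axis is flipped (values preserved).
    """

    sample_ids: list[str]
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sensor_name: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} absorbance rows but {len(self.sample_ids)} sample ids"
            )
        if p != self.wavenumbers.size:
            raise ValueError(
                f"{p} absorbance columns but {self.wavenumbers.size} wavenumbers"
            )
        if self.wavenumbers.size < 2:
            raise ValueError("need at least 2 wavenumbers")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        diffs = np.diff(self.wavenumbers)
        if np.all(diffs < 0):  # descending on input -> normalize
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()
        elif not np.all(diffs > 0):
            raise ValueError("wavenumbers must be strictly monotone")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, sample_ids: list[str]) -> "SpectraTable":
        """Row subset in the given id order; unknown ids raise."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample ids not in table: {missing}")
        rows = [index[s] for s in sample_ids]
        return SpectraTable(
            sample_ids=list(sample_ids),
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[rows].copy(),
            sensor_name=self.sensor_name,
        )


@dataclass
class ReferenceValues:
    """Reference analyte concentrations (% w/w), one per sample."""

    sample_ids: list[str]
    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim != 1:
            raise ValueError("concentration must be a vector")
        if self.concentration.size != len(self.sample_ids):
            raise ValueError("sample_ids and concentration lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in reference values")
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("non-finite concentration")
        if np.any(self.concentration < 0):
            raise ValueError("negative concentration")

    def subset(self, sample_ids: list[str]) -> "ReferenceValues":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample ids not in reference: {missing}")
        rows = [index[s] for s in sample_ids]
        return ReferenceValues(list(sample_ids), self.concentration[rows])


def _parse_float(token: str, where: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"non-numeric value {token!r} at {where}") from None
    if not math.isfinite(value):
        raise ParseError(f"non-finite value {token!r} at {where}")
    return value


def read_spectra_table(path: str | Path, sensor_name: str = "") -> SpectraTable:
    """Read a spectra CSV: header row = wavenumbers, first column = sample ids.

    The top-left corner cell is a label and is ignored. Either wavenumber
    direction is accepted; columns are normalized to ascending order.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one sample row")
    header = rows[0]
    if len(header) < 3:
        raise ParseError(f"{path}: need at least 2 wavenumber columns")
    wavenumbers = [
        _parse_float(tok, f"header column {j + 2}") for j, tok in enumerate(header[1:])
    ]
    sample_ids: list[str] = []
    matrix: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: row {i} has {len(row)} fields, expected {len(header)}"
            )
        sid = row[0].strip()
        if not sid:
            raise ParseError(f"{path}: empty sample id at row {i}")
        sample_ids.append(sid)
        matrix.append(
            [
                _parse_float(tok, f"row {i} (sample {sid!r}), column {j + 2}")
                for j, tok in enumerate(row[1:])
            ]
        )
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    try:
        return SpectraTable(sample_ids, np.array(wavenumbers), np.array(matrix), sensor_name)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_spectra_table(table: SpectraTable, path: str | Path) -> None:
    """Write a spectra CSV at full repr precision (exact round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id"] + [repr(float(w)) for w in table.wavenumbers])
        for sid, row in zip(table.sample_ids, table.absorbance):
            writer.writerow([sid] + [repr(float(v)) for v in row])


def read_reference(path: str | Path) -> ReferenceValues:
    """Read a two-column (sample id, concentration) CSV.

    A first line whose concentration field does not parse as a number is
    treated as a header and skipped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise ParseError(f"{path}: empty reference file")
    start = 0
    if len(rows[0]) >= 2:
        try:
            float(rows[0][1])
        except ValueError:
            start = 1  # header line
    sample_ids: list[str] = []
    values: list[float] = []
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 2:
            raise ParseError(f"{path}: row {i} needs 2 fields (id, concentration)")
        value = _parse_float(row[1], f"row {i} (sample {row[0]!r})")
        if value < 0:
            raise ParseError(f"{path}: negative concentration {value} at row {i}")
        sample_ids.append(row[0].strip())
        values.append(value)
    if not sample_ids:
        raise ParseError(f"{path}: no data rows")
    try:
        return ReferenceValues(sample_ids, np.array(values))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_reference(ref: ReferenceValues, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "concentration"])
        for sid, v in zip(ref.sample_ids, ref.concentration):
            writer.writerow([sid, repr(float(v))])


def align_reference(table: SpectraTable, ref: ReferenceValues) -> np.ndarray:
    """Concentrations reordered to the table's sample order, matched by id.

    Mismatched id sets raise with the symmetric difference listed.
    """
    t_ids, r_ids = set(table.sample_ids), set(ref.sample_ids)
    if t_ids != r_ids:
        only_t = sorted(t_ids - r_ids)
        only_r = sorted(r_ids - t_ids)
        raise ValueError(
            "sample id mismatch between spectra and reference: "
            f"only in spectra {only_t}, only in reference {only_r}"
        )
    lookup = dict(zip(ref.sample_ids, ref.concentration))
    return np.array([lookup[s] for s in table.sample_ids], dtype=float)


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted PLS calibration to versioned JSON.

    Stores everything prediction and score projection need (scaler vectors,
    rotations, coefficients, the calibration score matrix); load(save(m))
    reproduces predictions bit-identically because JSON floats round-trip.
    """
    payload = {
        "format": MODEL_FORMAT_TAG,
        "version": MODEL_FORMAT_VERSION,
        "sensor_name": model.sensor_name,
        "n_lv": int(model.n_lv),
        "y_center": float(model.y_center),
        "scaler_means": model.scaler.column_means.tolist(),
        "scaler_sds": model.scaler.column_sds.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "x_rotations": model.x_rotations.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "cal_scores": model.cal_scores.tolist(),
        "rmsecv_curve": None
        if model.rmsecv_curve is None
        else model.rmsecv_curve.tolist(),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path):
    from .preprocess import Scaler
    from .plsmodel import PLSCalibration

    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ParseError(f"{path}: not a valid model file ({exc})") from None
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT_TAG:
        raise ParseError(f"{path}: not a {MODEL_FORMAT_TAG} file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ParseError(
            f"{path}: model format version {payload.get('version')} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    curve = payload["rmsecv_curve"]
    return PLSCalibration(
        scaler=Scaler(
            column_means=np.array(payload["scaler_means"], dtype=float),
            column_sds=np.array(payload["scaler_sds"], dtype=float),
        ),
        x_mean=np.array(payload["x_mean"], dtype=float),
        x_weights=np.array(payload["x_weights"], dtype=float),
        x_loadings=np.array(payload["x_loadings"], dtype=float),
        x_rotations=np.array(payload["x_rotations"], dtype=float),
        y_loadings=np.array(payload["y_loadings"], dtype=float),
        coefficients=np.array(payload["coefficients"], dtype=float),
        y_center=float(payload["y_center"]),
        n_lv=int(payload["n_lv"]),
        cal_scores=np.array(payload["cal_scores"], dtype=float),
        rmsecv_curve=None if curve is None else np.array(curve, dtype=float),
        sensor_name=payload["sensor_name"],
    )
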