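"""Readers and writers for the package's delimited-text formats.

Three comma-separated dialects, all with a header row:

* sample files — input columns followed by one target column, one labeled
  training example per row;
* record files — ``base,NP_called,NP_2nd,NH_called,NH_2nd,dNS_next,dNS_prev``;
* result files — ``base,NC_P,NC_H,NC_dS,NC_o``, values at 3 decimals.

Values are validated for finiteness (hard error naming the line) and the
[0, 1] range (clipped with a logged warning).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .pipeline import BaseCallRecord, ConfidenceResult
from .training import SampleSet

logger = logging.getLogger(__name__)

RECORD_HEADER = ["base", "NP_called", "NP_2nd", "NH_called", "NH_2nd", "dNS_next", "dNS_prev"]
RESULT_HEADER = ["base", "NC_P", "NC_H", "NC_dS", "NC_o"]


def _parse_float(cell: str, path, lineno: int, column: str) -> float:
    try:
        v = float(cell)
    except ValueError:
        raise ValidationError(
            f"{path}: line {lineno}: column {column!r}: non-numeric cell {cell!r}"
        ) from None
    if not np.isfinite(v):
        raise ValidationError(
            f"{path}: line {lineno}: column {column!r}: non-finite value {cell!r}"
        )
    return v


def _clip_unit(values: np.ndarray, path) -> np.ndarray:
    out_of_range = int(np.sum((values < 0.0) | (values > 1.0)))
    if out_of_range:
        logger.warning("%s: clipped %d value(s) outside [0, 1]", path, out_of_range)
        values = np.clip(values, 0.0, 1.0)
    return values


def read_sample_file(path) -> SampleSet:
    """Read a labeled sample file; the last column is the target."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ValidationError(
                f"{path}: need at least one input column and one target column"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}: line {lineno}: expected {len(header)} cells, got {len(row)}"
                )
            rows.append(
                [_parse_float(c, path, lineno, header[i]) for i, c in enumerate(row)]
            )
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    data = _clip_unit(np.asarray(rows, dtype=float), path)
    logger.info("%s: read %d rows (%d input columns)", path, len(rows), len(header) - 1)
    return SampleSet(data[:, :-1], data[:, -1], name=path.stem)


def write_sample_file(path, samples: SampleSet, columns=None) -> None:
    path = Path(path)
    d = samples.n_inputs
    if columns is None:
        columns = [f"x{i + 1}" for i in range(d)] + ["target"]
    if len(columns) != d + 1:
        raise ValidationError(f"need {d + 1} column names, got {len(columns)}")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for x, y in zip(samples.X, samples.y):
            writer.writerow([repr(float(v)) for v in x] + [repr(float(y))])


def read_record_file(path) -> list:
    """Read per-base feature records, validating every row."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if [h.strip() for h in header] != RECORD_HEADER:
            raise ValidationError(
                f"{path}: expected header {','.join(RECORD_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(RECORD_HEADER):
                raise ValidationError(
                    f"{path}: line {lineno}: expected {len(RECORD_HEADER)} cells, "
                    f"got {len(row)}"
                )
            values = [
                _parse_float(c, path, lineno, RECORD_HEADER[i + 1])
                for i, c in enumerate(row[1:])
            ]
            values = _clip_unit(np.asarray(values), path)
            try:
                records.append(BaseCallRecord(row[0].strip(), *values))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    logger.info("%s: read %d base-call records", path, len(records))
    return records


def write_record_file(path, records) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_HEADER)
        for r in records:
            writer.writerow(
                [r.base]
                + [
                    repr(float(v))
                    for v in (r.np_called, r.np_2nd, r.nh_called, r.nh_2nd, r.dns_next, r.dns_prev)
                ]
            )


def write_result_file(path, results) -> None:
    """Write per-base scores at the report precision (3 decimals)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_HEADER)
        for r in results:
            if not isinstance(r, ConfidenceResult):
                raise ValidationError("write_result_file expects ConfidenceResult rows")
            writer.writerow(
                [r.base]
                + [f"{v:.3f}" for v in (r.features.nc_p, r.features.nc_h, r.features.nc_ds, r.nc_o)]
            )


def read_config_file(path) -> dict:
    """Parse a simple key/value (YAML-subset) configuration file."""
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a mapping of key: value pairs")
    return doc
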