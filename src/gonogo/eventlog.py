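"""Event-log format: one trial per row, delimited text, versioned header.

The canonical format is RFC-4180 CSV (UTF-8, comma-separated) preceded by
``#``-prefixed header lines carrying the format version, a config hash, the
master seed and the session start time.  Timestamps are ISO-8601 with
millisecond precision.  A JSON-lines variant is available behind a flag.
Readers validate every row and report the offending line and field.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as _dt
import hashlib
import io
import json
from pathlib import Path

from .controller import Outcome, TrialRecord
from .sequencing import TrialLabel

__all__ = [
    "FORMAT_VERSION",
    "EventLog",
    "LogFormatError",
    "write_log",
    "read_log",
    "validate_log",
    "config_hash",
]

FORMAT_VERSION = 1

COLUMNS = (
    "timestamp",
    "animal_id",
    "phase",
    "trial_label",
    "odor_id",
    "presampling_occupancy",
    "lick_blocks",
    "head_retract_ms",
    "outcome",
    "reward_ul",
    "iti_s",
    "block_id",
    "block_index",
)


class LogFormatError(ValueError):
    """Malformed log content; message names the line and field."""


@dataclasses.dataclass
class EventLog:
    """Ordered trial records plus run metadata."""

    records: list[TrialRecord]
    header: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.header.setdefault("format_version", str(FORMAT_VERSION))

    def __len__(self) -> int:
        return len(self.records)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a config mapping (canonical JSON, sha256)."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _record_to_row(r: TrialRecord) -> list[str]:
    return [
        r.timestamp.isoformat(timespec="milliseconds"),
        r.animal_id,
        r.phase,
        "" if r.trial_label is None else r.trial_label.value,
        r.odor_id,
        repr(r.presampling_occupancy),
        str(r.lick_blocks),
        "" if r.head_retract_ms is None else str(r.head_retract_ms),
        r.outcome.value,
        repr(r.reward_ul),
        repr(r.iti_s),
        "" if r.block_id is None else str(r.block_id),
        "" if r.block_index is None else str(r.block_index),
    ]


def _parse_field(row: dict[str, str], name: str, lineno: int, conv):
    try:
        return conv(row[name])
    except (KeyError, ValueError) as exc:
        raise LogFormatError(f"line {lineno}: bad field {name!r}: {exc}") from exc


def _row_to_record(row: dict[str, str], lineno: int) -> TrialRecord:
    missing = [c for c in COLUMNS if c not in row or row[c] is None]
    if missing:
        raise LogFormatError(f"line {lineno}: missing field(s) {missing}")
    label = row["trial_label"]
    try:
        rec = TrialRecord(
            timestamp=_parse_field(row, "timestamp", lineno, _dt.datetime.fromisoformat),
            animal_id=row["animal_id"],
            phase=row["phase"],
            trial_label=None if label == "" else TrialLabel(label),
            odor_id=row["odor_id"],
            presampling_occupancy=_parse_field(
                row, "presampling_occupancy", lineno, float
            ),
            lick_blocks=_parse_field(row, "lick_blocks", lineno, int),
            head_retract_ms=(
                None if row["head_retract_ms"] == "" else
                _parse_field(row, "head_retract_ms", lineno, int)
            ),
            outcome=_parse_field(row, "outcome", lineno, Outcome),
            reward_ul=_parse_field(row, "reward_ul", lineno, float),
            iti_s=_parse_field(row, "iti_s", lineno, float),
            block_id=(
                None if row["block_id"] == "" else
                _parse_field(row, "block_id", lineno, int)
            ),
            block_index=(
                None if row["block_index"] == "" else
                _parse_field(row, "block_index", lineno, int)
            ),
        )
    except ValueError as exc:
        raise LogFormatError(f"line {lineno}: {exc}") from exc
    return rec


def write_log(log: EventLog, path: str | Path, fmt: str = "csv") -> None:
    """Write an event log; ``fmt`` is ``csv`` (default) or ``jsonl``."""
    path = Path(path)
    if fmt == "csv":
        buf = io.StringIO()
        for key, value in log.header.items():
            buf.write(f"# {key}={value}\n")
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(COLUMNS)
        for rec in log.records:
            writer.writerow(_record_to_row(rec))
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            fh.write(json.dumps({"header": log.header}) + "\n")
            for rec in log.records:
                row = dict(zip(COLUMNS, _record_to_row(rec)))
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown log format {fmt!r}")


def read_log(path: str | Path, fmt: str = "csv") -> EventLog:
    """Read and validate an event log; raises :class:`LogFormatError` with
    the line number on any malformed content or unknown format version."""
    path = Path(path)
    header: dict[str, str] = {}
    records: list[TrialRecord] = []
    if fmt == "csv":
        lines = path.read_text(encoding="utf-8").splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            key, sep, value = line.lstrip("# ").partition("=")
            if sep:
                header[key.strip()] = value.strip()
        else:
            raise LogFormatError("no column header found")
        _check_version(header)
        reader = csv.reader(lines[body_start:])
        rows = list(reader)
        if not rows or rows[0] != list(COLUMNS):
            raise LogFormatError(
                f"line {body_start + 1}: column header does not match schema"
            )
        for offset, row in enumerate(rows[1:], start=body_start + 2):
            if not row:
                continue
            if len(row) != len(COLUMNS):
                raise LogFormatError(
                    f"line {offset}: expected {len(COLUMNS)} fields, got {len(row)}"
                )
            records.append(_row_to_record(dict(zip(COLUMNS, row)), offset))
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            first = fh.readline()
            try:
                header = json.loads(first)["header"]
            except (json.JSONDecodeError, KeyError) as exc:
                raise LogFormatError(f"line 1: bad header: {exc}") from exc
            _check_version(header)
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise LogFormatError(f"line {lineno}: bad JSON: {exc}") from exc
                records.append(_row_to_record(row, lineno))
    else:
        raise ValueError(f"unknown log format {fmt!r}")
    log = EventLog(records=records, header=header)
    problems = validate_log(log)
    if problems:
        raise LogFormatError("; ".join(problems))
    return log


def _check_version(header: dict[str, str]) -> None:
    version = header.get("format_version")
    if version is None:
        raise LogFormatError("header missing format_version")
    if int(float(version)) != FORMAT_VERSION:
        raise LogFormatError(
            f"unsupported format_version {version} (reader supports {FORMAT_VERSION})"
        )


def validate_log(log: EventLog) -> list[str]:
    """Structural checks beyond per-row parsing; returns violations."""
    problems: list[str] = []
    last_seen: dict[str, _dt.datetime] = {}
    for i, rec in enumerate(log.records):
        if rec.animal_id:
            prev = last_seen.get(rec.animal_id)
            if prev is not None and rec.timestamp < prev:
                problems.append(
                    f"record {i}: timestamps not ordered for animal {rec.animal_id}"
                )
            last_seen[rec.animal_id] = rec.timestamp
        if rec.outcome in (Outcome.MISS, Outcome.FALSE_ALARM) and rec.iti_s < 3.0:
            problems.append(f"record {i}: penalty ITI missing after {rec.outcome.value}")
    return problems
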