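"""Reading, filtering and exporting EMA corpora.

The filter cascade mirrors the preprocessing used for clinical EMA text
analysis: keep only records with an open-text statement, fitted in an
English-speaking country, with at least a minimum number of characters,
then apply mechanizable cleaning rules.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, NamedTuple, Sequence

from emadhc.records import EMARecord, FilterReport, normalize_satisfaction

MANDATORY_COLUMNS = ("record_id", "listener_id", "country", "tech_level", "satisfaction", "text")

#: English-speaking countries considered by default.
DEFAULT_COUNTRIES = (
    "AUSTRALIA",
    "CANADA",
    "ENGLAND",
    "IRELAND",
    "NEW ZEALAND",
    "UNITED STATES",
)

# Common short tokens accepted as aliases of the default country names.
_COUNTRY_ALIASES = {
    "US": "UNITED STATES",
    "USA": "UNITED STATES",
    "UNITED STATES OF AMERICA": "UNITED STATES",
    "CA": "CANADA",
    "CAN": "CANADA",
    "AU": "AUSTRALIA",
    "AUS": "AUSTRALIA",
    "NZ": "NEW ZEALAND",
    "NZL": "NEW ZEALAND",
    "IE": "IRELAND",
    "IRL": "IRELAND",
    "EN": "ENGLAND",
    "ENG": "ENGLAND",
}


class SchemaError(ValueError):
    """The input file does not conform to the documented record schema."""


class _RowError(Exception):
    """Internal: a single row failed validation (reported, not raised)."""


@dataclass(frozen=True)
class ParseFailure:
    """One input row/line that could not be turned into an :class:`EMARecord`."""

    line_number: int
    reason: str
    raw: str


class ReadResult(NamedTuple):
    records: list[EMARecord]
    failures: list[ParseFailure]


def normalize_whitespace(text: str) -> str:
    """Collapse whitespace runs to single spaces and trim the ends."""
    return re.sub(r"\s+", " ", text).strip()


def normalize_country(token: str) -> str:
    """Uppercase, strip punctuation/underscores, resolve known aliases."""
    norm = re.sub(r"[^A-Z0-9]+", " ", str(token).upper()).strip()
    return _COUNTRY_ALIASES.get(norm, norm)


def _record_from_mapping(row: dict, line_number: int) -> EMARecord:
    missing = [col for col in MANDATORY_COLUMNS if col not in row or row[col] is None]
    if missing:
        raise SchemaError(f"missing mandatory column(s) {missing} at line {line_number}")
    # An unknown satisfaction token is a hard error naming the record; any
    # other per-row defect (e.g. non-integer tech level) is reported.
    from emadhc.records import normalize_satisfaction as _norm

    _norm(row["satisfaction"], str(row["record_id"]))
    try:
        return EMARecord(
            record_id=str(row["record_id"]),
            listener_id=str(row["listener_id"]),
            country=str(row["country"]),
            tech_level=int(row["tech_level"]),
            satisfaction=str(row["satisfaction"]),
            text="" if row["text"] is None else str(row["text"]),
            timestamp=row.get("timestamp") or None,
        )
    except (TypeError, ValueError) as exc:
        raise _RowError(str(exc)) from exc


def read_records(path: str | Path, format: str = "jsonl") -> ReadResult:
    """Read EMA records from ``path``.

    Parameters
    ----------
    path : path
        Input file, UTF-8.
    format : {"jsonl", "delimited", "csv"}
        ``jsonl``: one JSON object per line with the mandatory keys.
        ``delimited``/``csv``: a header row naming the mandatory columns.

    Returns
    -------
    ReadResult
        ``(records, failures)`` — structurally unparseable rows are reported
        in ``failures`` rather than silently dropped.

    Raises
    ------
    SchemaError
        If a delimited file's header lacks a mandatory column.
    ValueError
        If a row carries an unknown satisfaction token (the message names
        the offending record).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "jsonl":
        return _read_jsonl(path)
    if fmt in ("delimited", "csv", "tsv"):
        return _read_delimited(path, delimiter="\t" if fmt == "tsv" else ",")
    raise ValueError(f"unknown corpus format {format!r}")


def _read_jsonl(path: Path) -> ReadResult:
    records: list[EMARecord] = []
    failures: list[ParseFailure] = []
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                failures.append(ParseFailure(line_number, f"invalid JSON: {exc}", line.rstrip("\n")))
                continue
            if not isinstance(row, dict):
                failures.append(ParseFailure(line_number, "line is not a JSON object", line.rstrip("\n")))
                continue
            missing = [col for col in MANDATORY_COLUMNS if col not in row]
            if missing:
                raise SchemaError(f"missing mandatory column(s) {missing} at line {line_number}")
            try:
                records.append(_record_from_mapping(row, line_number))
            except _RowError as exc:
                failures.append(ParseFailure(line_number, str(exc), line.rstrip("\n")))
    return ReadResult(records, failures)


def _read_delimited(path: Path, delimiter: str = ",") -> ReadResult:
    records: list[EMARecord] = []
    failures: list[ParseFailure] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [col for col in MANDATORY_COLUMNS if col not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s) {missing} in header")
        for line_number, row in enumerate(reader, start=2):
            if row.get("record_id") is None:
                failures.append(ParseFailure(line_number, "short row", str(row)))
                continue
            try:
                records.append(_record_from_mapping(row, line_number))
            except (SchemaError, _RowError) as exc:
                failures.append(ParseFailure(line_number, str(exc), str(row)))
    return ReadResult(records, failures)


def write_records_jsonl(records: Iterable[EMARecord], path: str | Path) -> None:
    """Write records as JSON-lines in the schema :func:`read_records` accepts."""
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            handle.write(json.dumps(record.to_dict(), ensure_ascii=False) + "\n")


@dataclass
class FilterConfig:
    """Settings of the corpus filter cascade.

    ``min_chars`` counts unicode characters of the whitespace-normalized
    text; texts of exactly ``min_chars`` characters are kept.  The cleaning
    stage drops texts whose share of alphabetic characters (among
    non-whitespace characters) is below ``min_alpha_proportion`` and texts
    consisting of a single repeated character run; ``replacements`` is an
    optional surface-level spelling-fix dictionary applied before cleaning;
    ``language_filter`` is an optional predicate hook (keep when True).
    """

    allowed_countries: Sequence[str] = DEFAULT_COUNTRIES
    min_chars: int = 20
    min_alpha_proportion: float = 0.5
    drop_repeated_runs: bool = True
    replacements: dict[str, str] | None = None
    language_filter: Callable[[str], bool] | None = None

    def normalized_countries(self) -> frozenset[str]:
        return frozenset(normalize_country(c) for c in self.allowed_countries)


def _alpha_proportion(text: str) -> float:
    chars = [ch for ch in text if not ch.isspace()]
    if not chars:
        return 0.0
    return sum(ch.isalpha() for ch in chars) / len(chars)


def _is_repeated_run(text: str) -> bool:
    chars = {ch for ch in text if not ch.isspace()}
    return len(chars) == 1


def _apply_replacements(text: str, replacements: dict[str, str]) -> str:
    tokens = text.split(" ")
    return " ".join(replacements.get(tok, tok) for tok in tokens)


def filter_corpus(
    records: Sequence[EMARecord], config: FilterConfig | None = None
) -> tuple[list[EMARecord], FilterReport]:
    """Apply the filter cascade in order and report per-stage counts.

    Stages: (1) drop records with empty/whitespace-only text; (2) drop
    records from countries outside ``allowed_countries``; (3) drop records
    whose whitespace-normalized text is shorter than ``min_chars``
    characters; (4) apply cleaning rules (low alphabetic share, single
    repeated character run, optional language predicate).  Spelling
    replacements modify texts at stage 4 without dropping records.

    Filters never fail; they count.  The cascade is idempotent.
    """
    config = config or FilterConfig()
    report = FilterReport(n_input=len(records))
    allowed = config.normalized_countries()

    with_text = []
    for record in records:
        if record.text and record.text.strip():
            with_text.append(record)
        else:
            report.removed["no_text"].append(record.record_id)
    report.n_with_text = len(with_text)

    in_country = []
    for record in with_text:
        if normalize_country(record.country) in allowed:
            in_country.append(record)
        else:
            report.removed["country"].append(record.record_id)
    report.n_in_allowed_countries = len(in_country)

    length_ok = []
    for record in in_country:
        if len(normalize_whitespace(record.text)) >= config.min_chars:
            length_ok.append(record)
        else:
            report.removed["too_short"].append(record.record_id)
    report.n_length_ok = len(length_ok)

    cleaned: list[EMARecord] = []
    for record in length_ok:
        text = normalize_whitespace(record.text)
        if config.replacements:
            text = _apply_replacements(text, config.replacements)
        if _alpha_proportion(text) < config.min_alpha_proportion:
            report.removed["cleaning"].append(record.record_id)
            continue
        if config.drop_repeated_runs and _is_repeated_run(text):
            report.removed["cleaning"].append(record.record_id)
            continue
        if config.language_filter is not None and not config.language_filter(text):
            report.removed["cleaning"].append(record.record_id)
            continue
        if text != record.text:
            record = EMARecord(
                record_id=record.record_id,
                listener_id=record.listener_id,
                country=record.country,
                tech_level=record.tech_level,
                satisfaction=record.satisfaction,
                text=text,
                timestamp=record.timestamp,
            )
        cleaned.append(record)
    report.n_after_cleaning = len(cleaned)
    return cleaned, report


# --- Iramuteq-style corpus export -----------------------------------------

_VARIABLE_SHORT_NAMES = {
    "country": "country",
    "satisfaction": "sat",
    "tech_level": "tech",
    "listener_id": "id",
}

_VALUE_SHORT_FORMS = {"positive": "pos", "negative": "neg"}


def _clean_variable_value(value: object) -> str:
    token = _VALUE_SHORT_FORMS.get(str(value).lower(), str(value).lower())
    token = re.sub(r"[^a-z0-9]+", "_", token).strip("_")
    return token or "na"


def export_iramuteq_corpus(
    records: Sequence[EMARecord],
    variables: Sequence[str] = ("country", "satisfaction", "tech_level"),
    path: str | Path = "corpus.txt",
) -> Path:
    """Write a starred-header plain-text corpus.

    One block per record: a header line of ``**** *var_value`` tokens
    (e.g. ``**** *country_us *sat_pos *tech_1``) followed by the text,
    blocks separated by blank lines.
    """
    for name in variables:
        if any(ch.isspace() for ch in name):
            raise ValueError(f"variable name {name!r} contains whitespace")
    path = Path(path)
    lines: list[str] = []
    for record in records:
        tokens = []
        for name in variables:
            short = _VARIABLE_SHORT_NAMES.get(name, re.sub(r"[^a-z0-9]+", "_", name.lower()))
            value = getattr(record, name)
            tokens.append(f"*{short}_{_clean_variable_value(value)}")
        lines.append("**** " + " ".join(tokens))
        lines.append(normalize_whitespace(record.text))
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def read_iramuteq_corpus(path: str | Path) -> list[tuple[dict[str, str], str]]:
    """Parse a starred-header corpus back into ``(variables, text)`` pairs."""
    blocks: list[tuple[dict[str, str], str]] = []
    variables: dict[str, str] | None = None
    text_lines: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("**** "):
            if variables is not None:
                blocks.append((variables, normalize_whitespace(" ".join(text_lines))))
            variables = {}
            for token in line[5:].split():
                key, _, value = token.lstrip("*").partition("_")
                variables[key] = value
            text_lines = []
        elif line.strip():
            text_lines.append(line.strip())
    if variables is not None:
        blocks.append((variables, normalize_whitespace(" ".join(text_lines))))
    return blocks
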