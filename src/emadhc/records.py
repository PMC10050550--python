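"""Core record types for EMA corpora.

One :class:`EMARecord` is one self-initiated ecological momentary assessment:
a free-text statement plus a binary satisfaction rating and device metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

POSITIVE = "positive"
NEGATIVE = "negative"

#: Accepted spellings of the binary satisfaction rating (case-insensitive).
_SATISFACTION_TOKENS = {
    "positive": POSITIVE,
    "pos": POSITIVE,
    "negative": NEGATIVE,
    "neg": NEGATIVE,
}


def normalize_satisfaction(value: str, record_id: str | None = None) -> str:
    """Map a satisfaction token to ``"positive"``/``"negative"``.

    Raises ``ValueError`` (naming the record when known) for anything else.
    """
    token = str(value).strip().lower()
    try:
        return _SATISFACTION_TOKENS[token]
    except KeyError:
        where = f" in record {record_id!r}" if record_id else ""
        raise ValueError(
            f"unknown satisfaction token {value!r}{where}; "
            f"expected one of {sorted(set(_SATISFACTION_TOKENS))}"
        ) from None


@dataclass(frozen=True)
class EMARecord:
    """One self-initiated EMA.

    Parameters
    ----------
    record_id : str
        Opaque identifier, unique within a corpus.
    listener_id : str
        Opaque identifier of the hearing-aid wearer.
    country : str
        Country in which the hearing aids were fitted (name or ISO-like
        token; matching is case/punctuation-insensitive).
    tech_level : int
        Ordinal technology level of the device, 1 (premium) .. 5 (basic).
    satisfaction : str
        ``"positive"`` or ``"negative"``.
    text : str
        The optional open-text statement (possibly empty).
    timestamp : str, optional
        ISO-8601 timestamp if available.
    """

    record_id: str
    listener_id: str
    country: str
    tech_level: int
    satisfaction: str
    text: str = ""
    timestamp: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "satisfaction", normalize_satisfaction(self.satisfaction, self.record_id)
        )
        level = int(self.tech_level)
        if not 1 <= level <= 5:
            raise ValueError(
                f"tech_level must be in 1..5, got {self.tech_level!r} "
                f"in record {self.record_id!r}"
            )
        object.__setattr__(self, "tech_level", level)
        object.__setattr__(self, "text", "" if self.text is None else str(self.text))

    def to_dict(self) -> dict:
        return asdict(self)


# Stage names of the corpus filter cascade, in application order.
FILTER_STAGES = ("no_text", "country", "too_short", "cleaning")


@dataclass
class FilterReport:
    """Counts and removals at each stage of the corpus filter cascade."""

    n_input: int = 0
    n_with_text: int = 0
    n_in_allowed_countries: int = 0
    n_length_ok: int = 0
    n_after_cleaning: int = 0
    removed: dict[str, list[str]] = field(
        default_factory=lambda: {stage: [] for stage in FILTER_STAGES}
    )

    @property
    def counts(self) -> tuple[int, int, int, int, int]:
        return (
            self.n_input,
            self.n_with_text,
            self.n_in_allowed_countries,
            self.n_length_ok,
            self.n_after_cleaning,
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_with_text": self.n_with_text,
            "n_in_allowed_countries": self.n_in_allowed_countries,
            "n_length_ok": self.n_length_ok,
            "n_after_cleaning": self.n_after_cleaning,
            "removed": {stage: list(ids) for stage, ids in self.removed.items()},
        }
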