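"""From raw texts to the binary text-unit x active-form matrix.

The Reinert-style classification consumes a presence/absence matrix with one
row per text unit (here: one EMA statement) and one column per retained
*active form* — the lemma of an adjective, noun, adverb or verb.  Forms with
corpus frequency below a threshold (default 3) are dropped, and the number
of columns can be capped.

Part-of-speech information comes from a pluggable tagger.  The default
backend is a bundled surface-form lemma dictionary combined with a
closed-class stoplist: dictionary hits carry their listed lemma and POS
class; unknown tokens fall back to an identity lemma and are treated as
active (open-class) unless they appear on the stoplist.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from emadhc.records import EMARecord

POS_CLASSES = ("adjective", "noun", "adverb", "verb", "other")
ACTIVE_POS = frozenset({"adjective", "noun", "adverb", "verb"})

#: Closed-class English words (determiners, pronouns, prepositions,
#: conjunctions, auxiliaries, particles): never treated as active forms by
#: the fallback tagger.
STOPLIST = frozenset(
    """
    a an the this that these those some any each every no both few all most
    more other another such same own only too also just
    i me my mine you your yours he him his she her hers it its we us our ours
    they them their theirs who whom whose which what there here
    and or but if because so as than then while although though since until
    unless nor not yes
    of in on at to for from with without by about into onto over under
    between through during before after above below near behind around
    against within
    be am is are was were been being have has had having do does did doing
    done will would can could shall should may might must
    up down out off back again
    """.split()
)


class EmptyTableError(ValueError):
    """Raised when no text unit retains any active form."""


_TOKEN_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased alphabetic tokens; punctuation and standalone digits removed.

    Intra-word apostrophes are preserved (``can't`` stays one token).
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Form:
    """One retained active form (column of the lexical table)."""

    lemma: str
    pos_class: str
    corpus_frequency: int


def load_lemma_dictionary(path: str | Path | None = None) -> dict[str, tuple[str, str]]:
    """Load a surface -> (lemma, pos_class) dictionary from TSV.

    Without ``path``, the small bundled English dictionary is used.  It
    covers function words, frequent irregular inflections and common
    hearing-aid domain vocabulary; it makes no completeness claim.
    """
    if path is None:
        source = resources.files("emadhc.data").joinpath("lemmas_en.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    dictionary: dict[str, tuple[str, str]] = {}
    for line_number, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed lemma dictionary line {line_number}: {line!r}")
        surface, lemma, pos = (p.strip() for p in parts)
        if pos not in POS_CLASSES:
            raise ValueError(f"unknown pos_class {pos!r} at line {line_number}")
        dictionary[surface.lower()] = (lemma.lower(), pos)
    return dictionary


class StoplistTagger:
    """Fallback POS backend: stoplist words are closed-class (``other``),
    everything else is treated as an active form of class ``noun``."""

    def __init__(self, stoplist: frozenset[str] = STOPLIST, active_class: str = "noun"):
        self.stoplist = stoplist
        self.active_class = active_class

    def __call__(self, token: str) -> str:
        return "other" if token in self.stoplist else self.active_class


def lemmatize(
    tokens: Sequence[str],
    lemma_dictionary: dict[str, tuple[str, str]] | None = None,
    tagger: Callable[[str], str] | None = None,
) -> list[tuple[str, str]]:
    """Map tokens to ``(lemma, pos_class)`` pairs.

    Dictionary hits use their listed lemma and class.  Misses fall back to
    an identity lemma (with a trailing possessive ``'s`` stripped) and the
    class assigned by ``tagger``; without a tagger the class is ``other``.
    """
    lemma_dictionary = lemma_dictionary if lemma_dictionary is not None else {}
    out: list[tuple[str, str]] = []
    for token in tokens:
        hit = lemma_dictionary.get(token)
        if hit is None and token.endswith("'s"):
            stripped = token[:-2]
            hit = lemma_dictionary.get(stripped)
            if hit is None:
                token = stripped
        if hit is not None:
            out.append(hit)
        else:
            pos = tagger(token) if tagger is not None else "other"
            out.append((token, pos))
    return out


@dataclass
class VocabularyStats:
    """Corpus-level vocabulary accounting (before frequency filtering).

    ``hapax`` counts forms observed exactly once, so the hapax share of
    forms is ``n_hapax / n_distinct_forms`` and the hapax share of tokens is
    ``n_hapax / n_tokens_total``.
    """

    n_tokens_total: int
    n_distinct_forms: int
    n_hapax: int

    @property
    def hapax_share_of_forms(self) -> float:
        return self.n_hapax / self.n_distinct_forms if self.n_distinct_forms else 0.0

    @property
    def hapax_share_of_tokens(self) -> float:
        return self.n_hapax / self.n_tokens_total if self.n_tokens_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_tokens_total": self.n_tokens_total,
            "n_distinct_forms": self.n_distinct_forms,
            "n_hapax": self.n_hapax,
            "hapax_share_of_forms": self.hapax_share_of_forms,
            "hapax_share_of_tokens": self.hapax_share_of_tokens,
        }


@dataclass
class LexicalTable:
    """Binary text-unit x active-form matrix.

    Attributes
    ----------
    unit_ids : list of str
        One id per retained row (text unit).
    forms : list of str
        Retained lemmas, one per column.
    cells : ndarray of shape (n_units, n_forms), values in {0, 1}
        Presence/absence; within-text repetition does not raise a cell
        above 1.
    form_info : list of Form
        Lemma, POS class and raw corpus frequency per column.
    unclassifiable_units : list of str
        Units that retained no active form and were excluded.
    vocabulary : VocabularyStats
        Whole-corpus accounting over all lemmatized tokens (all POS
        classes, before frequency filtering).
    """

    unit_ids: list[str]
    forms: list[str]
    cells: np.ndarray
    form_info: list[Form] = field(default_factory=list)
    unclassifiable_units: list[str] = field(default_factory=list)
    vocabulary: VocabularyStats | None = None

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_forms(self) -> int:
        return len(self.forms)

    @property
    def grand_total(self) -> int:
        return int(self.cells.sum())

    def subset(self, unit_ids: Sequence[str]) -> "LexicalTable":
        """Rows restricted to ``unit_ids`` (column set unchanged)."""
        index = {uid: i for i, uid in enumerate(self.unit_ids)}
        rows = [index[uid] for uid in unit_ids]
        return LexicalTable(
            unit_ids=list(unit_ids),
            forms=list(self.forms),
            cells=self.cells[rows, :].copy(),
            form_info=list(self.form_info),
        )


def _iter_unit_texts(corpus: Iterable) -> list[tuple[str, str]]:
    units = []
    for item in corpus:
        if isinstance(item, EMARecord):
            units.append((item.record_id, item.text))
        else:
            uid, text = item
            units.append((str(uid), str(text)))
    return units


def build_lexical_table(
    corpus: Iterable,
    min_frequency: int = 3,
    keep_pos: frozenset[str] | set[str] = ACTIVE_POS,
    max_forms: int = 30_000,
    lemma_dictionary: dict[str, tuple[str, str]] | None = None,
    tagger: Callable[[str], str] | None = None,
    use_bundled_dictionary: bool = True,
) -> LexicalTable:
    """Build the binary unit x form matrix from a corpus.

    Parameters
    ----------
    corpus : iterable of EMARecord or (unit_id, text) pairs
    min_frequency : int
        Minimum raw corpus occurrence count (before binarization) for a
        lemma to become a column.  Default 3.
    keep_pos : set
        POS classes admitted as active forms.
    max_forms : int
        Cap on the number of columns, filled by descending corpus
        frequency with alphabetical tie-break.  Default 30,000.
    lemma_dictionary, tagger
        Override the bundled dictionary / default stoplist tagger.
    use_bundled_dictionary : bool
        Set False to skip loading the bundled dictionary when no explicit
        ``lemma_dictionary`` is given (useful for synthetic vocabularies).

    Raises
    ------
    EmptyTableError
        If every unit ends up without a retained form.
    """
    if lemma_dictionary is None and use_bundled_dictionary:
        lemma_dictionary = load_lemma_dictionary()
    if tagger is None:
        tagger = StoplistTagger()
    units = _iter_unit_texts(corpus)
    if not units:
        raise EmptyTableError("corpus is empty")
    seen = set()
    for uid, _ in units:
        if uid in seen:
            raise ValueError(f"duplicate unit id {uid!r}")
        seen.add(uid)

    keep_pos = frozenset(keep_pos)
    unit_lemmas: list[tuple[str, set[str]]] = []
    corpus_counts: Counter[str] = Counter()
    all_form_counts: Counter[str] = Counter()
    n_tokens_total = 0
    for uid, text in units:
        pairs = lemmatize(tokenize(text), lemma_dictionary, tagger)
        n_tokens_total += len(pairs)
        active = set()
        for lemma, pos in pairs:
            all_form_counts[lemma] += 1
            if pos in keep_pos:
                corpus_counts[lemma] += 1
                active.add(lemma)
        unit_lemmas.append((uid, active))

    vocab = VocabularyStats(
        n_tokens_total=n_tokens_total,
        n_distinct_forms=len(all_form_counts),
        n_hapax=sum(1 for c in all_form_counts.values() if c == 1),
    )

    retained = [lemma for lemma, count in corpus_counts.items() if count >= min_frequency]
    retained.sort(key=lambda lemma: (-corpus_counts[lemma], lemma))
    retained = retained[:max_forms]
    retained_set = set(retained)
    forms = sorted(retained)

    col = {lemma: j for j, lemma in enumerate(forms)}
    unit_ids: list[str] = []
    rows: list[np.ndarray] = []
    unclassifiable: list[str] = []
    for uid, active in unit_lemmas:
        hits = active & retained_set
        if not hits:
            unclassifiable.append(uid)
            continue
        row = np.zeros(len(forms), dtype=np.int8)
        for lemma in hits:
            row[col[lemma]] = 1
        unit_ids.append(uid)
        rows.append(row)
    if not unit_ids:
        raise EmptyTableError(
            "no text unit retains any active form at "
            f"min_frequency={min_frequency}"
        )

    cells = np.vstack(rows)
    form_info = [Form(lemma, _majority_pos(lemma, lemma_dictionary), corpus_counts[lemma]) for lemma in forms]
    return LexicalTable(
        unit_ids=unit_ids,
        forms=forms,
        cells=cells,
        form_info=form_info,
        unclassifiable_units=unclassifiable,
        vocabulary=vocab,
    )


def _majority_pos(lemma: str, lemma_dictionary: dict[str, tuple[str, str]] | None) -> str:
    if lemma_dictionary:
        hit = lemma_dictionary.get(lemma)
        if hit is not None:
            return hit[1]
    return "noun"
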