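"""Characteristic words and texts per kept cluster.

Each retained form is cross-tabulated as a 2 x 2 presence/absence by
in/out-of-cluster table over classified units; its Pearson chi2 (no
continuity correction) scores the association.  Over-represented forms
(observed in-cluster presence above expectation) ranked by chi2 are the
cluster's characteristic words; texts are ranked by summing the chi2 of the
characteristic words they contain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from emadhc.lexicon import LexicalTable


@dataclass(frozen=True)
class FormAssociation:
    lemma: str
    chi2: float
    n_in_cluster: int
    n_outside: int
    direction: str  # "over" or "under"


@dataclass(frozen=True)
class TextScore:
    unit_id: str
    score: float


@dataclass
class ClusterProfile:
    cluster_id: int
    size: int
    percent_of_classified: float
    characteristic_forms: list[FormAssociation]
    characteristic_texts: list[TextScore]


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized Pearson chi2 of 2x2 tables [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _classified_matrix(
    table: LexicalTable, assignment: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    unit_ids = [uid for uid in table.unit_ids if uid in assignment]
    index = {uid: i for i, uid in enumerate(table.unit_ids)}
    rows = np.array([index[uid] for uid in unit_ids], dtype=int)
    X = np.asarray(table.cells, dtype=float)[rows, :]
    labels = np.array([assignment[uid] for uid in unit_ids])
    return X, labels, unit_ids


def characteristic_forms(
    table: LexicalTable,
    assignment: Mapping[str, int],
    cluster_id: int,
    top_k: int = 20,
    min_presence: int = 2,
) -> list[FormAssociation]:
    """Top ``top_k`` over-represented forms of one cluster, ranked by chi2.

    Forms present in fewer than ``min_presence`` classified units are
    excluded (chi2 on near-empty margins is unstable).  Ties in chi2 are
    broken alphabetically.
    """
    X, labels, _ = _classified_matrix(table, assignment)
    in_cluster = labels == cluster_id
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster_id!r} has no classified units")
    n_in = int(in_cluster.sum())
    n_out = int((~in_cluster).sum())
    present_in = X[in_cluster].sum(axis=0)
    present_out = X[~in_cluster].sum(axis=0)
    a = present_in
    b = n_in - present_in
    c = present_out
    d = n_out - present_out
    chi2 = _chi2_2x2(a, b, c, d)
    total_presence = present_in + present_out
    n_total = n_in + n_out
    expected_in = (a + b) * (a + c) / n_total
    over = a > expected_in

    rows = []
    for j, lemma in enumerate(table.forms):
        if total_presence[j] < min_presence:
            continue
        if not over[j]:
            continue
        rows.append(
            FormAssociation(
                lemma=lemma,
                chi2=float(chi2[j]),
                n_in_cluster=int(present_in[j]),
                n_outside=int(present_out[j]),
                direction="over",
            )
        )
    rows.sort(key=lambda fa: (-fa.chi2, fa.lemma))
    return rows[:top_k]


def characteristic_texts(
    table: LexicalTable,
    assignment: Mapping[str, int],
    cluster_id: int,
    profile: Sequence[FormAssociation],
    top_n: int = 3,
    normalize: bool = False,
) -> list[TextScore]:
    """Top ``top_n`` in-cluster units by summed chi2 of contained
    characteristic forms (each form counted once per text).

    With ``normalize=True`` the score is divided by the number of retained
    forms present in the unit.  Ties are broken by unit id.
    """
    X, labels, unit_ids = _classified_matrix(table, assignment)
    in_cluster = labels == cluster_id
    col = {lemma: j for j, lemma in enumerate(table.forms)}
    weights = np.zeros(X.shape[1])
    for fa in profile:
        weights[col[fa.lemma]] = fa.chi2
    scores = X @ weights
    if normalize:
        lengths = X.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(lengths > 0, scores / np.where(lengths > 0, lengths, 1.0), 0.0)
    ranked = sorted(
        (TextScore(uid, float(s)) for uid, s, inc in zip(unit_ids, scores, in_cluster) if inc),
        key=lambda ts: (-ts.score, ts.unit_id),
    )
    return ranked[:top_n]


def build_profiles(
    table: LexicalTable,
    assignment: Mapping[str, int],
    top_k: int = 20,
    top_texts: int = 3,
    normalize_text_scores: bool = False,
) -> dict[int, ClusterProfile]:
    """One :class:`ClusterProfile` per cluster present in ``assignment``."""
    sizes: dict[int, int] = {}
    for cid in assignment.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    n_classified = sum(sizes.values())
    profiles: dict[int, ClusterProfile] = {}
    for cid in sorted(sizes):
        forms = characteristic_forms(table, assignment, cid, top_k=top_k)
        texts = characteristic_texts(
            table, assignment, cid, forms, top_n=top_texts, normalize=normalize_text_scores
        )
        profiles[cid] = ClusterProfile(
            cluster_id=cid,
            size=sizes[cid],
            percent_of_classified=100.0 * sizes[cid] / n_classified,
            characteristic_forms=forms,
            characteristic_texts=texts,
        )
    return profiles


def profiles_to_frame(profiles: Mapping[int, ClusterProfile]) -> pd.DataFrame:
    """Long-format table (cluster_id, rank, lemma, chi2, n_in, n_out)."""
    rows = []
    for cid, profile in sorted(profiles.items()):
        for rank, fa in enumerate(profile.characteristic_forms, start=1):
            rows.append(
                {
                    "cluster_id": cid,
                    "rank": rank,
                    "lemma": fa.lemma,
                    "chi2": fa.chi2,
                    "n_in": fa.n_in_cluster,
                    "n_out": fa.n_outside,
                }
            )
    return pd.DataFrame(rows, columns=["cluster_id", "rank", "lemma", "chi2", "n_in", "n_out"])


def texts_to_frame(profiles: Mapping[int, ClusterProfile]) -> pd.DataFrame:
    """Long-format table (cluster_id, rank, record_id, score)."""
    rows = []
    for cid, profile in sorted(profiles.items()):
        for rank, ts in enumerate(profile.characteristic_texts, start=1):
            rows.append(
                {"cluster_id": cid, "rank": rank, "record_id": ts.unit_id, "score": ts.score}
            )
    return pd.DataFrame(rows, columns=["cluster_id", "rank", "record_id", "score"])
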