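from __future__ import annotations

import numpy as np
import pytest

from emadhc.lexicon import LexicalTable
from emadhc.records import EMARecord


def make_table(X, unit_ids=None, forms=None) -> LexicalTable:
    """Wrap a raw 0/1 array as a LexicalTable for algorithm-level tests."""
    X = np.asarray(X, dtype=np.int8)
    if unit_ids is None:
        unit_ids = [f"u{i:03d}" for i in range(X.shape[0])]
    if forms is None:
        forms = [f"f{j:03d}" for j in range(X.shape[1])]
    return LexicalTable(unit_ids=list(unit_ids), forms=list(forms), cells=X)


def make_record(record_id="r1", text="I can hear the tv better now thanks", **kw) -> EMARecord:
    defaults = dict(
        listener_id="l1",
        country="UNITED STATES",
        tech_level=1,
        satisfaction="positive",
    )
    defaults.update(kw)
    return EMARecord(record_id=record_id, text=text, **defaults)


@pytest.fixture
def two_block_table() -> LexicalTable:
    # units a,b use forms f0,f1; units c,d use forms f2,f3
    X = [
        [1, 1, 0, 0],
        [1, 1, 0, 0],
        [0, 0, 1, 1],
        [0, 0, 1, 1],
    ]
    return make_table(X, unit_ids=["a", "b", "c", "d"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)
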