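import numpy as np
import pytest

from screenkit.formats import ChipMap, ChipRecord, GctMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_gct(values, row_prefix="sh", col_prefix="S", descriptions=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return GctMatrix(
        row_ids=[f"{row_prefix}{i:04d}" for i in range(n)],
        row_descriptions=list(descriptions) if descriptions else [""] * n,
        column_ids=[f"{col_prefix}{j}" for j in range(m)],
        values=values,
    )


def make_chip(mapping):
    """mapping: {barcode: gene_symbol or list of (transcript, symbol)}"""
    records = []
    for barcode, val in mapping.items():
        if isinstance(val, str):
            records.append(ChipRecord(barcode, f"NM_{barcode[:6]}", "0", val))
        else:
            for k, (tx, sym) in enumerate(val):
                records.append(ChipRecord(barcode, tx, str(k), sym))
    return ChipMap(records)


@pytest.fixture
def small_gct(rng):
    return make_gct(rng.normal(size=(10, 4)))
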