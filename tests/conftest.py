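import numpy as np
import pandas as pd
import pytest

from mirtargetome import ArrayDataset, CountMatrix, MatureMiRNA


@pytest.fixture
def let7():
    return MatureMiRNA("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def mir378a():
    return MatureMiRNA("hsa-miR-378a-3p", "ACUGGACUUGGAGUCAGAAGGC")


@pytest.fixture
def small_counts():
    """Hand-sized count matrix: 4 miRNAs, 2+2 samples."""
    counts = pd.DataFrame(
        {
            "a1": [2, 3, 5, 50],
            "a2": [10, 10, 10, 50],
            "b1": [1, 1, 1, 49],
            "b2": [4, 4, 4, 50],
        },
        index=["miR-1", "miR-2", "miR-3", "miR-4"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns, name="group")
    return CountMatrix(counts=counts, groups=groups)


def make_array_dataset(signal: dict, present=None) -> ArrayDataset:
    """Build a small ArrayDataset from a {sample_name: values} dict.

    Sample names follow the condition__fraction__replicate convention.
    """
    sig = pd.DataFrame(signal)
    sig.index = [f"p{i}" for i in range(len(sig))]
    rows = []
    for c in sig.columns:
        cond, frac, rep = c.split("__")
        rows.append({"sample": c, "condition": cond, "fraction": frac,
                     "replicate": int(rep)})
    samples = pd.DataFrame(rows).set_index("sample")
    if present is None:
        present = pd.DataFrame(True, index=sig.index, columns=sig.columns)
    else:
        present = pd.DataFrame(present)
        present.index = sig.index
    return ArrayDataset(signal=sig, present=present, samples=samples)
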