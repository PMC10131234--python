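import numpy as np
import pandas as pd
import pytest

from codewatch.terminology import ClinicalCode, CodeHierarchy


@pytest.fixture
def chain_hierarchy() -> CodeHierarchy:
    """Three-code chain A -> B -> C."""
    return CodeHierarchy(
        [
            ClinicalCode("Aaaaa", "top concept", None),
            ClinicalCode("Bbbbb", "middle concept", "Aaaaa"),
            ClinicalCode("Ccccc", "leaf concept", "Bbbbb"),
        ]
    )


@pytest.fixture
def prefix_hierarchy() -> CodeHierarchy:
    """Flat codes exercising prefix and keyword queries."""
    return CodeHierarchy(
        [
            ClinicalCode("61abc", "Contraception advice", None),
            ClinicalCode("61xyz", "Contraceptive device fitted", None),
            ClinicalCode("24abc", "Examination of cardiovascular system", None),
            ClinicalCode("XaF8d", "Medication review done", None),
            ClinicalCode("Xa8Pl", "Cervical smear", None),
        ]
    )


def random_tree_codes(rng: np.random.Generator, n: int) -> list[ClinicalCode]:
    """A random forest: each code's parent is a uniformly earlier code or none."""
    codes = []
    for i in range(n):
        cid = f"N{i:04d}"
        if i == 0 or rng.random() < 0.1:
            parent = None
        else:
            parent = f"N{int(rng.integers(i)):04d}"
        codes.append(ClinicalCode(cid, f"synthetic concept {i}", parent))
    return codes


@pytest.fixture
def random_tree_factory():
    return random_tree_codes


def make_counts(rows) -> pd.DataFrame:
    """EventCounts frame from (practice, code, month, count) tuples."""
    df = pd.DataFrame(rows, columns=["practice", "code", "month", "count"])
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    return df


@pytest.fixture
def counts_builder():
    return make_counts
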