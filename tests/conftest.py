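import numpy as np
import pytest

from stemsig.core_data import ExpressionMatrix, PhenotypeTable


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [4.0, 3.0, 2.0, 1.0],
        [0.5, 0.5, 2.0, 2.0],
    ])
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def tiny_pheno() -> PhenotypeTable:
    return PhenotypeTable.from_records(
        ["s1", "s2", "s3", "s4"],
        [True, False, False, False],
        ["pluripotent", "normal", "normal", "cancer"],
    )


def brute_force_fir(values, is_anchor, w):
    """Independent oracle: enumerate every window of the sorted sample list."""
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    flags = np.asarray(is_anchor, dtype=bool)[order]
    s = len(flags)
    best_k, best_start = -1, -1
    for start in range(s - w + 1):
        k = int(flags[start:start + w].sum())
        if k > best_k:
            best_k, best_start = k, start + 1
    return best_k / w, best_k, best_start
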