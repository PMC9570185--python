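"""Small hand-built fixtures shared by test modules."""

import numpy as np
import pandas as pd

from oxysig.containers import MatchedStudy, OxylipinMatrix


def tiny_paired_study(case_values: np.ndarray, control_values: np.ndarray, analytes=None):
    """Matched study from explicit case/control value matrices."""
    n, p = case_values.shape
    analytes = analytes or [f"a{j}" for j in range(p)]
    ids = [f"c{i}" for i in range(n)] + [f"k{i}" for i in range(n)]
    values = pd.DataFrame(
        np.vstack([case_values, control_values]), index=ids, columns=analytes
    )
    subjects = pd.DataFrame(
        {"is_case": [True] * n + [False] * n, "pair_id": list(range(n)) * 2},
        index=ids,
    )
    pairs = pd.DataFrame(
        {
            "pair_id": range(n),
            "case_id": [f"c{i}" for i in range(n)],
            "control_id": [f"k{i}" for i in range(n)],
        }
    )
    return MatchedStudy(subjects, pairs, OxylipinMatrix(values, standardized=True))
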