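import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from myometa.types import Design, ExpressionStudy, StudyAnnotation


def make_study(values, subjects=None, study_id="s1", design=Design.PAIRED,
               genes=None):
    """Build an ExpressionStudy from a genes x (2*n_subjects) array laid out
    as PRE/POST pairs per subject."""
    values = np.asarray(values, dtype=float)
    n_sub = values.shape[1] // 2
    subjects = subjects or [f"sub{i + 1}" for i in range(n_sub)]
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    cols = pd.MultiIndex.from_tuples(
        [(s, c) for s in subjects for c in ("PRE", "POST")],
        names=["subject", "condition"],
    )
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=cols)
    return ExpressionStudy(study_id, frame, design)


@pytest.fixture
def rng():
    return np.random.default_rng(20200124)


@pytest.fixture
def simple_annotations():
    return [
        StudyAnnotation("s1", "acute_aerobic", n_subjects=8),
        StudyAnnotation("s2", "acute_aerobic", n_subjects=10,
                        health_status="MTI"),
        StudyAnnotation("s3", "inactivity", n_subjects=12,
                        biopsy_timing="REC"),
    ]
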