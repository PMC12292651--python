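import numpy as np
import pytest

from sfze import (
    ModelKind,
    MotifModel,
    ScoringParams,
    Site,
    SyntaxGrammar,
    TFClass,
    default_motif_set,
)

TOY_JASPAR = """\
>TOY0001 toyA
A [ 10  0  3  5 ]
C [  0 12  3  0 ]
G [  2  0  6  0 ]
T [  0  0  0  7 ]
>TOY0002 toyB
A [ 1 9 0 2 0 0 ]
C [ 8 0 0 2 0 9 ]
G [ 0 0 9 2 0 0 ]
T [ 0 0 0 3 9 0 ]
"""


@pytest.fixture
def toy_jaspar_text():
    return TOY_JASPAR


@pytest.fixture
def params():
    return ScoringParams()


@pytest.fixture
def grammar():
    return SyntaxGrammar()


@pytest.fixture
def motifs():
    return default_motif_set()


@pytest.fixture
def toy_matrix_model():
    mat = np.array(
        [
            [1, 9, 0, 2, 0, 0],
            [8, 0, 0, 2, 0, 9],
            [0, 0, 9, 2, 0, 0],
            [0, 0, 0, 3, 9, 0],
        ],
        dtype=float,
    )
    return MotifModel("toyB", TFClass.Z, ModelKind.MATRIX, matrix=mat)


def make_site(tf_class, start, end, strand="+", seq_id="region", motif_id=None,
              score=1.0):
    """Shorthand Site constructor for grammar tests."""
    cls = TFClass(tf_class)
    return Site(
        seq_id, start, end, strand, cls,
        motif_id or f"{cls.value}_test", score, "A" * (end - start),
    )


@pytest.fixture
def site_factory():
    return make_site
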