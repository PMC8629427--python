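import numpy as np
import pytest

from decodon.alignment_layer import AlignedPair
from decodon.profile_db import (
    ConsensusColumn,
    ProfileDB,
    ProfileDomain,
    clamp_normalize,
)


def db_from_matrix(mat, acc="TEST1", name=None):
    """ProfileDB with a single domain whose columns are the rows of mat."""
    mat = np.asarray(mat, dtype=float)
    cols = [ConsensusColumn(acc, k + 1, clamp_normalize(m)) for k, m in enumerate(mat)]
    dom = ProfileDomain(acc, name or acc, len(cols), cols)
    return ProfileDB({acc: dom})


def mkpair(codon="TGA", acc="PF00001", col=1, evalue=1e-20, pp="*", **kw):
    return AlignedPair(
        codon=codon, domain_acc=acc, col_index=col, evalue=evalue,
        pp_class=pp, **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def onehot_db():
    """One domain of 20 columns, column k (nearly) certain for amino acid k."""
    return db_from_matrix(np.eye(20))
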