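import numpy as np
import pytest

import remedynet as rn
from remedynet import corpus as C


@pytest.fixture(scope="session")
def small_lexicon():
    return rn.build_lexicon(5, 3, 2, seed=7)


@pytest.fixture(scope="session")
def engineered_model():
    """5x5 joint with p(s1,e1)=0.1 and uniform 0.2 marginals.

    The planted cell has analytic PMI log2(0.1 / 0.04) = 1.3219.
    """
    lex = rn.build_lexicon(5, 5, 3, seed=7)
    subs = [e.canonical for e in lex.substances]
    effs = [e.canonical for e in lex.effects]
    joint = np.full((5, 5), 0.04375)
    joint[0, :] = 0.025
    joint[:, 0] = 0.025
    joint[0, 0] = 0.1
    model = rn.AssociationModel.from_joint(
        subs, effs, joint, rate=0.3, planted=[(subs[0], effs[0])]
    )
    return lex, model


@pytest.fixture(scope="session")
def small_corpus(small_lexicon):
    model = rn.plant_associations(small_lexicon, 3, 4.0, seed=8)
    comments, gold = rn.generate_corpus(
        small_lexicon, model, n_comments=400, deleted_fraction=0.1, seed=9
    )
    return comments, gold, model


def nondeleted_sentences(comments):
    return [
        s for c in comments if not c.is_deleted for s in C.segment_sentences(c)
    ]
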