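import pytest

from sannet.annotation import (
    AnnotatedUtterance,
    DependencyArc,
    LabelScheme,
    NormalizationMap,
    ROOT_RELATION,
)
from sannet.chat_io import Token, Utterance

MINI_CHA = """\
@Begin
@Languages:\teng
@Participants:\tCHI Target_Child, MOT Mother
@ID:\teng|sample|CHI|2;06.00|female|||Target_Child||
*CHI:\tthe doggie .
%mor:\tdet|the n|doggie .
*MOT:\twhere is the doggie ?
*CHI:\tdoggie [/] doggie runs
\taway .
*CHI:\txxx .
*CHI:\tEl niño come .
@End
"""


def make_annotated(words, heads, relations, index=0, categories=None):
    """Build an AnnotatedUtterance from parallel lists (heads[i] for token i+1)."""
    categories = categories or [None] * len(words)
    tokens = [
        Token(position=i + 1, surface=w, canonical=w, category=c)
        for i, (w, c) in enumerate(zip(words, categories))
    ]
    arcs = [
        DependencyArc(h, i + 1, ROOT_RELATION if h == 0 else r)
        for i, (h, r) in enumerate(zip(heads, relations))
    ]
    utt = Utterance(index=index, speaker_code="*CHI", raw_text=" ".join(words), tokens=tokens)
    return AnnotatedUtterance(utterance=utt, arcs=arcs)


@pytest.fixture
def scheme():
    return LabelScheme()


@pytest.fixture
def the_map():
    return NormalizationMap({"mammma": "mamma", "da": "the"})


@pytest.fixture
def an_apple():
    """The DP-hypothesis worked case: the article governs the noun."""
    return make_annotated(
        ["an", "apple"],
        heads=[0, 1],
        relations=[ROOT_RELATION, "modifier"],
        categories=["article", "noun"],
    )


@pytest.fixture
def six_utterances():
    """A small hand-checkable corpus sharing words across utterances."""
    return [
        make_annotated(["an", "apple"], [0, 1], [ROOT_RELATION, "modifier"], index=0),
        make_annotated(["eat", "an", "apple"], [0, 1, 2], [ROOT_RELATION, "object", "modifier"], index=1),
        make_annotated(["the", "doggie"], [0, 1], [ROOT_RELATION, "modifier"], index=2),
        make_annotated(["doggie", "runs"], [2, 0], ["subject", ROOT_RELATION], index=3),
        make_annotated(["mamma"], [0], [ROOT_RELATION], index=4),
        make_annotated(["see", "the", "doggie"], [0, 1, 2], [ROOT_RELATION, "object", "modifier"], index=5),
    ]
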