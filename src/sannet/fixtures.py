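"""Synthetic transcripts, gold annotations and reference graphs.

Real child-speech corpora live in CHILDES and require manual expert
annotation, so nothing here claims developmental realism: the generator
emulates the *shape* of child speech that matters for software contracts — a
small vocabulary reused with Zipfian frequencies, short utterances (1–10
tokens), valid single-rooted dependency trees, customizable relation and
category labels, and special characters (ñ, accented vowels) that a correct
pipeline must not corrupt.  Everything is reproducible from an explicit seed;
no global random state is touched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import (
    AnnotatedUtterance,
    DEFAULT_SCHEME,
    DependencyArc,
    LabelScheme,
    ROOT_RELATION,
)
from .chat_io import Token, Utterance
from .network_builder import SAN

__all__ = ["FixtureSpec", "generate_corpus", "generate_reference_graph", "make_vocabulary"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus.

    Defaults mirror a short recording session of early child speech: ~100
    utterances of 1–10 tokens over a 60-word productive vocabulary with a
    Zipf exponent of 1.0 (the classical value for word-frequency rank laws).
    ``bilingual_fraction`` tags that fraction of the vocabulary with the
    scheme's second-language category, emulating a Spanish–English corpus.
    """

    n_utterances: int = 100
    vocab_size: int = 60
    zipf_exponent: float = 1.0
    utterance_length_range: tuple[int, int] = (1, 10)
    label_scheme: LabelScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    bilingual_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.utterance_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad utterance length range ({lo}, {hi})")
        if self.vocab_size < hi:
            raise ValueError(
                f"vocab_size {self.vocab_size} smaller than max utterance "
                f"length {hi}: infeasible"
            )
        if not (0.0 <= self.bilingual_fraction <= 1.0):
            raise ValueError("bilingual_fraction must lie in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")


_ONSETS = ["m", "p", "b", "t", "d", "k", "g", "n", "ñ", "l", "s"]
_VOWELS = ["a", "e", "i", "o", "u", "á", "é"]


def make_vocabulary(size: int) -> list[str]:
    """Deterministic pseudo-word list with CV(CV) shapes, ñ and accents included."""
    syllables = ["".join(p) for p in itertools.product(_ONSETS, _VOWELS)]
    words: list[str] = []
    for n_syll in (1, 2, 3):
        for combo in itertools.product(syllables, repeat=n_syll):
            if n_syll == 1 and len(combo[0]) < 2:
                continue
            words.append("".join(combo))
            if len(words) >= size:
                return words
    raise ValueError(f"cannot build a vocabulary of size {size}")


def _zipf_probabilities(size: int, exponent: float) -> np.ndarray:
    weights = np.arange(1, size + 1, dtype=float) ** -exponent
    return weights / weights.sum()


def generate_corpus(spec: FixtureSpec) -> tuple[str, list[AnnotatedUtterance]]:
    """Generate a CHAT transcript plus its gold dependency annotations.

    Word forms are sampled i.i.d. from the Zipf-ranked vocabulary; each
    utterance receives a uniformly random single-rooted dependency tree built
    by attaching every token after the first to a uniformly chosen earlier
    token (valid by construction).  The returned CHAT text parses with
    ``chat_io`` and the annotations pass ``annotation.validate``.  Equal seeds
    give byte-equal output.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = make_vocabulary(spec.vocab_size)
    probs = _zipf_probabilities(spec.vocab_size, spec.zipf_exponent)
    relations = sorted(spec.label_scheme.relation_labels)
    categories = sorted(spec.label_scheme.category_labels)

    # fixed per-word category assignment (a word keeps its category corpus-wide)
    if spec.bilingual_fraction > 0 and len(categories) >= 2:
        n_second = int(round(spec.bilingual_fraction * spec.vocab_size))
        second = set(rng.choice(spec.vocab_size, size=n_second, replace=False).tolist())
        word_category = {
            w: categories[1] if i in second else categories[0]
            for i, w in enumerate(vocab)
        }
    else:
        draws = rng.integers(0, len(categories), size=spec.vocab_size)
        word_category = {w: categories[d] for w, d in zip(vocab, draws)}

    lo, hi = spec.utterance_length_range
    chat_lines = [
        "@Begin",
        "@Languages:\tspa, eng",
        "@Participants:\tCHI Target_Child, INV Investigator",
        "@ID:\tspa|synthetic|CHI|2;06.00|female|||Target_Child||",
    ]
    annotations: list[AnnotatedUtterance] = []
    for index in range(spec.n_utterances):
        length = int(rng.integers(lo, hi + 1))
        word_ids = rng.choice(spec.vocab_size, size=length, p=probs)
        words = [vocab[int(i)] for i in word_ids]
        tokens = [
            Token(position=i, surface=w, canonical=w, category=word_category[w])
            for i, w in enumerate(words, start=1)
        ]
        arcs = [DependencyArc(0, 1, ROOT_RELATION)]
        for pos in range(2, length + 1):
            governor = int(rng.integers(1, pos))
            relation = relations[int(rng.integers(0, len(relations)))]
            arcs.append(DependencyArc(governor, pos, relation))
        utterance = Utterance(
            index=index,
            speaker_code="*CHI",
            raw_text=" ".join(words) + " .",
            tokens=tokens,
        )
        annotations.append(AnnotatedUtterance(utterance=utterance, arcs=arcs))
        chat_lines.append("*CHI:\t" + " ".join(words) + " .")
    chat_lines.append("@End")
    return "\n".join(chat_lines) + "\n", annotations


def generate_reference_graph(kind: str, size: int, seed: int = 0) -> SAN:
    """Build a SAN of a named graph family with known closed-form metrics.

    Kinds: ``path`` (diameter n−1), ``tree`` (E = n−1, C = 0), ``star``,
    ``complete`` (C = 1, L = 1), ``ring_lattice`` (cycle plus next-nearest
    neighbors when n ≥ 5), ``random`` (seeded Erdős–Rényi-style).  Nodes are
    zero-padded word labels so orderings are deterministic; relation labels
    cycle through the default scheme.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"w{i:03d}" for i in range(size)]
    relations = sorted(DEFAULT_SCHEME.relation_labels)
    san = SAN()
    for name in names:
        san.upsert_node(name)

    def link(i: int, j: int, serial: int) -> None:
        san.upsert_edge(names[i], names[j], relations[serial % len(relations)])

    serial = 0
    if kind == "path":
        for i in range(size - 1):
            link(i, i + 1, serial)
            serial += 1
    elif kind == "star":
        for i in range(1, size):
            link(0, i, serial)
            serial += 1
    elif kind == "tree":
        for i in range(1, size):
            parent = int(rng.integers(0, i))
            link(parent, i, serial)
            serial += 1
    elif kind == "complete":
        for i in range(size):
            for j in range(i + 1, size):
                link(i, j, serial)
                serial += 1
    elif kind == "ring_lattice":
        if size >= 3:
            hops = (1, 2) if size >= 5 else (1,)
            for hop in hops:
                for i in range(size):
                    link(i, (i + hop) % size, serial)
                    serial += 1
        elif size == 2:
            link(0, 1, serial)
    elif kind == "random":
        p = min(1.0, 3.0 / size) if size > 1 else 0.0
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < p:
                    link(i, j, serial)
                    serial += 1
    else:
        raise ValueError(f"unknown reference graph kind {kind!r}")
    return san
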