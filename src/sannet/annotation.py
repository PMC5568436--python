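"""Per-utterance dependency analyses: label schemes, word unification, formats.

An utterance's syntactic analysis is a set of labeled dependency arcs under
Dependency Grammar: every word is the dependent of exactly one governor, the
governor being another word of the utterance or the notional root (position 0).
The analysis is authored by a human (or imported from a standard corpus); this
module does not parse.

The default relation inventory is the five labels used in longitudinal
child-speech network studies — subject, object, complement, modifier,
attribute — plus the reserved ``root`` label for root attachment.  Both the
relation and the lexical-category inventories are user-customizable
(:class:`LabelScheme`), e.g. a bilingual study may use the categories
``English`` / ``Spanish`` / ``Proper name`` instead of parts of speech.

Word-form unification (:class:`NormalizationMap`) merges variant spellings of
one word — ``mammma`` → ``mamma``, ``da`` → ``the`` — so they land in the same
network node.  Unification is applied when annotations are read, keeping the
annotation files faithful to the transcription.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

import yaml

from .chat_io import Token, Utterance

__all__ = [
    "ROOT_RELATION",
    "DEFAULT_RELATIONS",
    "DEFAULT_CATEGORIES",
    "AnnotationError",
    "PairsFormatError",
    "LabelScheme",
    "NormalizationMap",
    "DependencyArc",
    "AnnotatedUtterance",
    "normalize",
    "read_pairs",
    "import_conllu",
    "validate",
    "apply_dp_hypothesis_check",
    "load_scheme",
    "load_normalization",
]

ROOT_RELATION = "root"

DEFAULT_RELATIONS = ("subject", "object", "complement", "modifier", "attribute")
DEFAULT_CATEGORIES = (
    "noun",
    "verb",
    "adjective",
    "adverb",
    "article",
    "pronoun",
    "preposition",
    "conjunction",
    "interjection",
    "numeral",
)


class AnnotationError(ValueError):
    """Raised for invalid annotations or annotation configuration."""


class PairsFormatError(AnnotationError):
    """Raised when a pairs/CoNLL-U stream violates its format contract."""


@dataclass(frozen=True)
class LabelScheme:
    """The active vocabularies for relation and lexical-category labels."""

    relation_labels: frozenset[str] = frozenset(DEFAULT_RELATIONS)
    category_labels: frozenset[str] = frozenset(DEFAULT_CATEGORIES)
    name: str = "default"

    def __post_init__(self) -> None:
        for kind, labels in (
            ("relation", self.relation_labels),
            ("category", self.category_labels),
        ):
            if not labels:
                raise AnnotationError(f"label scheme {self.name!r}: empty {kind} set")
            folded = {l.lower() for l in labels}
            if len(folded) != len(labels):
                raise AnnotationError(
                    f"label scheme {self.name!r}: {kind} labels not unique "
                    "case-insensitively"
                )

    def has_relation(self, label: str) -> bool:
        return label == ROOT_RELATION or label.lower() in {
            l.lower() for l in self.relation_labels
        }

    def has_category(self, label: str) -> bool:
        return label.lower() in {l.lower() for l in self.category_labels}


DEFAULT_SCHEME = LabelScheme()


class NormalizationMap:
    """Variant word form → canonical form, with canonical forms as fixed points.

    The fixed-point requirement (``map[c] == c`` or absent, for every canonical
    ``c``) rules out chains such as ``da → the → thee``; it makes
    :meth:`normalize` idempotent.
    """

    def __init__(self, mapping: Optional[Mapping[str, str]] = None):
        self.mapping: dict[str, str] = dict(mapping or {})
        for canonical in self.mapping.values():
            if self.mapping.get(canonical, canonical) != canonical:
                raise AnnotationError(
                    f"normalization map has a chain through {canonical!r}: "
                    "canonical forms must map to themselves"
                )

    def __call__(self, form: str) -> str:
        return self.mapping.get(form, form)

    def __len__(self) -> int:
        return len(self.mapping)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NormalizationMap) and self.mapping == other.mapping


IDENTITY_MAP = NormalizationMap()


def normalize(form: str, mapping: Optional[NormalizationMap] = None) -> str:
    """Unify a word form: return its canonical spelling, or itself if unmapped."""
    if not form:
        raise AnnotationError("cannot normalize an empty form")
    return (mapping or IDENTITY_MAP)(form)


@dataclass(frozen=True)
class DependencyArc:
    """Directed link governor → dependent; positions are 1-based token slots.

    ``governor_pos`` 0 is root attachment and carries the reserved ``root``
    relation.  Self-dependency is forbidden by Dependency Grammar.
    """

    governor_pos: int
    dependent_pos: int
    relation: str

    def __post_init__(self) -> None:
        if self.dependent_pos < 1:
            raise AnnotationError(
                f"dependent position must be >= 1, got {self.dependent_pos}"
            )
        if self.governor_pos == self.dependent_pos:
            raise AnnotationError(
                f"self-dependency at position {self.dependent_pos}"
            )

    @property
    def is_root(self) -> bool:
        return self.governor_pos == 0


@dataclass
class AnnotatedUtterance:
    """An utterance together with its dependency arcs (one per token)."""

    utterance: Utterance
    arcs: list[DependencyArc] = field(default_factory=list)

    @property
    def non_root_arcs(self) -> list[DependencyArc]:
        return [a for a in self.arcs if not a.is_root]

    def token_at(self, position: int) -> Token:
        return self.utterance.tokens[position - 1]


_OCCURRENCE_SUFFIX = re.compile(r"#\d+$")


def strip_occurrence_suffix(form: str) -> str:
    """Drop the ``#k`` disambiguation suffix used for repeated words in a block."""
    return _OCCURRENCE_SUFFIX.sub("", form)


def read_pairs(
    stream: Union[str, TextIO],
    scheme: LabelScheme = DEFAULT_SCHEME,
    normalization: Optional[NormalizationMap] = None,
    allow_multiple_roots: bool = False,
) -> list[AnnotatedUtterance]:
    """Read the columnar "pairs" annotation format.

    One utterance per blank-line-separated block; each line is
    ``governor<TAB>relation<TAB>dependent`` with optional 4th/5th columns for
    governor/dependent category labels.  Repeated word forms within a block are
    disambiguated with a ``#k`` occurrence suffix (``doggie#2``), stripped
    before the form becomes a token.  The unique form never appearing as a
    dependent is attached to root.

    Word unification runs here when ``normalization`` is given — at reading
    time, so the annotation file itself stays faithful to the transcription.
    """
    text = stream if isinstance(stream, str) else stream.read()
    mapping = normalization or IDENTITY_MAP

    annotated: list[AnnotatedUtterance] = []
    blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
    for block_no, block in enumerate(blocks):
        positions: dict[str, int] = {}  # occurrence-suffixed key -> position
        categories: dict[str, Optional[str]] = {}
        dependents: set[str] = set()
        raw_arcs: list[tuple[str, str, str]] = []

        def intern(key: str, category: Optional[str]) -> None:
            if key not in positions:
                positions[key] = len(positions) + 1
            if category:
                categories[key] = category

        for line_no, line in enumerate(block.strip().splitlines(), start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) <= 2:
                # bare-form line: an isolated (root-only) token, optional category
                form = cols[0].strip()
                if not form:
                    raise PairsFormatError(
                        f"block {block_no + 1}, line {line_no}: empty form"
                    )
                intern(form, cols[1].strip() if len(cols) > 1 and cols[1].strip() else None)
                continue
            gov, rel, dep = cols[0].strip(), cols[1].strip(), cols[2].strip()
            gov_cat = cols[3].strip() if len(cols) > 3 and cols[3].strip() else None
            dep_cat = cols[4].strip() if len(cols) > 4 and cols[4].strip() else None
            if not scheme.has_relation(rel):
                raise PairsFormatError(
                    f"block {block_no + 1}, line {line_no}: relation {rel!r} "
                    f"not in scheme {scheme.name!r}"
                )
            if dep in dependents:
                raise PairsFormatError(
                    f"block {block_no + 1}, line {line_no}: {dep!r} is a "
                    "dependent twice (single-head violation)"
                )
            dependents.add(dep)
            intern(gov, gov_cat)
            intern(dep, dep_cat)
            raw_arcs.append((gov, rel, dep))

        roots = [k for k in positions if k not in dependents]
        if not roots:
            raise PairsFormatError(
                f"block {block_no + 1}: no root form (every word is a dependent; "
                "the block contains a cycle)"
            )
        if len(roots) > 1 and not allow_multiple_roots:
            raise PairsFormatError(
                f"block {block_no + 1}: multiple root forms {sorted(roots)!r} "
                "(pass allow_multiple_roots=True to accept fragment forests)"
            )

        tokens = []
        for key, pos in sorted(positions.items(), key=lambda kv: kv[1]):
            surface = strip_occurrence_suffix(key)
            tokens.append(
                Token(
                    position=pos,
                    surface=surface,
                    canonical=normalize(surface, mapping),
                    category=categories.get(key),
                )
            )
        utterance = Utterance(
            index=block_no,
            speaker_code="",
            raw_text=" ".join(t.surface for t in tokens),
            tokens=tokens,
        )
        arcs = [
            DependencyArc(positions[gov], positions[dep], rel)
            for gov, rel, dep in raw_arcs
        ]
        arcs += [DependencyArc(0, positions[r], ROOT_RELATION) for r in roots]
        arcs.sort(key=lambda a: a.dependent_pos)
        annotated.append(AnnotatedUtterance(utterance=utterance, arcs=arcs))
    return annotated


def import_conllu(
    stream: Union[str, TextIO],
    scheme_map: Optional[Mapping[str, str]] = None,
    passthrough: bool = False,
    normalization: Optional[NormalizationMap] = None,
) -> list[AnnotatedUtterance]:
    """Import 10-column CoNLL-U sentences as annotated utterances.

    ``HEAD`` becomes the governor position and ``DEPREL`` is translated through
    ``scheme_map`` (``None`` means identity).  Multiword-token ranges (``3-4``)
    and empty nodes (``5.1``) are skipped.  An unmapped deprel raises unless
    ``passthrough`` is set; a non-integer HEAD raises naming the sentence.
    """
    text = stream if isinstance(stream, str) else stream.read()
    mapping = normalization or IDENTITY_MAP

    annotated: list[AnnotatedUtterance] = []
    sent_lines: list[list[str]] = []
    sent_id = ""
    ordinal = 0

    def flush() -> None:
        nonlocal sent_lines, sent_id, ordinal
        if not sent_lines:
            return
        label = sent_id or f"sentence {ordinal + 1}"
        tokens, arcs = [], []
        for cols in sent_lines:
            idx, form, head_s, deprel = cols[0], cols[1], cols[6], cols[7]
            try:
                pos, head = int(idx), int(head_s)
            except ValueError:
                raise PairsFormatError(
                    f"{label}: non-integer HEAD {head_s!r} for token {idx!r}"
                ) from None
            if head == 0 or scheme_map is None:
                rel = deprel
            elif deprel in scheme_map:
                rel = scheme_map[deprel]
            elif passthrough:
                rel = deprel
            else:
                raise PairsFormatError(
                    f"{label}: deprel {deprel!r} has no scheme mapping"
                )
            category = cols[3] if cols[3] not in ("_", "") else None
            tokens.append(
                Token(
                    position=pos,
                    surface=form,
                    canonical=normalize(form, mapping),
                    category=category,
                )
            )
            if head == 0:
                arcs.append(DependencyArc(0, pos, ROOT_RELATION))
            else:
                arcs.append(DependencyArc(head, pos, rel))
        utterance = Utterance(
            index=ordinal,
            speaker_code="",
            raw_text=" ".join(t.surface for t in tokens),
            tokens=tokens,
        )
        annotated.append(AnnotatedUtterance(utterance=utterance, arcs=arcs))
        sent_lines, sent_id = [], ""
        ordinal += 1

    for line in text.splitlines():
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*sent_id\s*=\s*(\S+)", line)
            if m:
                sent_id = m.group(1)
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise PairsFormatError(
                f"CoNLL-U line has {len(cols)} columns, expected 10: {line!r}"
            )
        if "-" in cols[0] or "." in cols[0]:  # multiword-token / empty node
            continue
        sent_lines.append(cols)
    flush()
    return annotated


def validate(
    annotated: AnnotatedUtterance,
    scheme: LabelScheme = DEFAULT_SCHEME,
    allow_multiple_roots: bool = False,
) -> list[str]:
    """Check the dependency-analysis contract; return diagnostics, not raise.

    An empty list means the analysis is well formed: every token has exactly
    one head, arcs are acyclic, positions are in range, labels belong to the
    scheme, and (by default) there is a single root attachment.
    """
    diagnostics: list[str] = []
    n = len(annotated.utterance.tokens)

    heads: dict[int, int] = {}
    roots = 0
    for arc in annotated.arcs:
        if not (0 <= arc.governor_pos <= n):
            diagnostics.append(
                f"dangling governor position {arc.governor_pos} (utterance has "
                f"{n} tokens)"
            )
        if not (1 <= arc.dependent_pos <= n):
            diagnostics.append(
                f"dangling dependent position {arc.dependent_pos} (utterance "
                f"has {n} tokens)"
            )
            continue
        if arc.dependent_pos in heads:
            diagnostics.append(
                f"token {arc.dependent_pos} has multiple heads (single-head "
                "violation)"
            )
        else:
            heads[arc.dependent_pos] = arc.governor_pos
        if arc.is_root:
            roots += 1
        elif not scheme.has_relation(arc.relation):
            diagnostics.append(
                f"unknown relation label {arc.relation!r} (scheme {scheme.name!r})"
            )

    for pos in range(1, n + 1):
        if pos not in heads:
            diagnostics.append(f"token {pos} has no head (missing arc)")

    if roots == 0 and n > 0:
        diagnostics.append("no root attachment")
    elif roots > 1 and not allow_multiple_roots:
        diagnostics.append(f"{roots} root attachments (single-root mode)")

    # cycle check: follow head pointers from every token
    for start in heads:
        seen = set()
        pos = start
        while pos != 0 and pos in heads:
            if pos in seen:
                if pos == start:
                    diagnostics.append(f"dependency cycle through token {start}")
                break
            seen.add(pos)
            pos = heads[pos]
    return diagnostics


DETERMINER_CATEGORIES = frozenset({"article", "determiner"})
NOUN_CATEGORIES = frozenset({"noun"})


def apply_dp_hypothesis_check(
    annotated: AnnotatedUtterance,
    determiner_categories: Iterable[str] = DETERMINER_CATEGORIES,
    noun_categories: Iterable[str] = NOUN_CATEGORIES,
) -> list[str]:
    """Advisory check of the DP-hypothesis convention.

    Under the DP-hypothesis the determiner governs the noun (in "an apple" the
    noun depends on the article).  Every arc where a determiner-labeled token
    instead depends on a noun is reported as a warning; nothing is rejected.
    """
    det = {c.lower() for c in determiner_categories}
    nouns = {c.lower() for c in noun_categories}
    warnings = []
    for arc in annotated.non_root_arcs:
        dep = annotated.token_at(arc.dependent_pos)
        gov = annotated.token_at(arc.governor_pos)
        if (
            dep.category
            and gov.category
            and dep.category.lower() in det
            and gov.category.lower() in nouns
        ):
            warnings.append(
                f"DP-hypothesis: determiner {dep.canonical!r} is dependent of "
                f"noun {gov.canonical!r} (expected determiner as governor)"
            )
    return warnings


def load_scheme(source: Union[str, Path, TextIO]) -> LabelScheme:
    """Load a :class:`LabelScheme` from YAML with ``relations:`` / ``categories:``."""
    data = _load_yaml(source)
    return LabelScheme(
        relation_labels=frozenset(data.get("relations", DEFAULT_RELATIONS)),
        category_labels=frozenset(data.get("categories", DEFAULT_CATEGORIES)),
        name=str(data.get("name", "custom")),
    )


def load_normalization(source: Union[str, Path, TextIO]) -> NormalizationMap:
    """Load a :class:`NormalizationMap` from YAML with a ``normalize:`` mapping."""
    data = _load_yaml(source)
    return NormalizationMap({str(k): str(v) for k, v in (data.get("normalize") or {}).items()})


def _load_yaml(source: Union[str, Path, TextIO]) -> dict:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    return yaml.safe_load(text) or {}
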