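"""Reading CHAT (.cha) transcripts and cleaning utterances.

CHAT is the transcript format of the CHILDES child-language database.  A file
is a sequence of lines: ``@`` headers carry metadata, ``*XXX:`` main tiers
carry one utterance of speaker ``XXX``, ``%xxx:`` dependent tiers carry
annotation, and a line beginning with a tab continues the previous tier.

Only the subset of the CHAT dialect needed for corpus extraction is handled
here: headers, main/dependent tiers, tab continuations, bracketed codes
(``[/]``, ``[*]`` ...), ``&``-prefixed non-words, the unintelligibility
markers ``xxx``/``yyy``/``www``, utterance terminators and bullet/timestamp
marks.  ``%mor``/``%gra`` interpretation and overlap notation are out of
scope.  All text is UTF-8 end to end; special characters (ñ, accents, umlauts)
pass through untouched.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ChatParseError",
    "Token",
    "Utterance",
    "Participant",
    "Transcript",
    "CleaningRules",
    "parse_chat",
    "read_chat",
    "select_tier",
    "clean_tokens",
    "clean_and_tokenize",
    "load_cleaning_rules",
]


class ChatParseError(ValueError):
    """Raised when a CHAT stream violates the tier-marker grammar."""


@dataclass(frozen=True)
class Token:
    """One word of an utterance.

    ``position`` is 1-based; position 0 is reserved for the notional root in
    dependency annotations.  ``canonical`` is the form that becomes a network
    node (case-folded when the case-folding rule is on); ``surface`` keeps the
    cleaned but unfolded spelling.
    """

    position: int
    surface: str
    canonical: str
    category: Optional[str] = None


@dataclass
class Utterance:
    """A single main-tier line attributed to one speaker.

    ``index`` is the 0-based ordinal within the selected tier.  ``tokens`` is
    empty until :func:`clean_and_tokenize` has run.
    """

    index: int
    speaker_code: str
    raw_text: str
    tokens: list[Token] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        """True when cleaning removed every token (excluded downstream)."""
        return not self.tokens


@dataclass(frozen=True)
class Participant:
    code: str
    role: str = ""
    age: str = ""  # "years;months.days" when stated in @ID


@dataclass
class Transcript:
    """Parsed CHAT content: headers, participants and tier lines in file order."""

    file_id: str
    participants: list[Participant] = field(default_factory=list)
    lines: list[tuple[str, str]] = field(default_factory=list)
    headers: list[str] = field(default_factory=list)

    def main_tier_lines(self) -> list[tuple[str, str]]:
        return [(code, text) for code, text in self.lines if code.startswith("*")]

    def speakers(self) -> list[str]:
        seen: list[str] = []
        for code, _ in self.main_tier_lines():
            bare = code.lstrip("*")
            if bare not in seen:
                seen.append(bare)
        return seen


_ID_FIELDS = 10  # lang|corpus|code|age|sex|group|SES|role|education|custom


def _parse_participants_header(value: str) -> list[Participant]:
    out = []
    for chunk in value.split(","):
        words = chunk.split()
        if not words:
            continue
        code = words[0]
        role = words[-1] if len(words) > 1 else ""
        out.append(Participant(code=code, role=role))
    return out


def _merge_id_header(participants: list[Participant], value: str) -> list[Participant]:
    fields = value.rstrip("|").split("|")
    if len(fields) < 8:
        return participants
    code, age, role = fields[2], fields[3], fields[7]
    merged, found = [], False
    for p in participants:
        if p.code == code:
            merged.append(Participant(code=code, role=role or p.role, age=age))
            found = True
        else:
            merged.append(p)
    if not found:
        merged.append(Participant(code=code, role=role, age=age))
    return merged


def parse_chat(stream: Union[str, TextIO], file_id: str = "<stream>") -> Transcript:
    """Parse a CHAT document into a :class:`Transcript`.

    Continuation lines (tab-indented) are joined to the preceding tier with a
    single space; everything else is preserved verbatim.  A main-tier line
    missing the ``:`` after its speaker code raises :class:`ChatParseError`
    naming the line number, as does an empty stream.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if not text.strip():
        raise ChatParseError(f"{file_id}: empty CHAT stream")

    transcript = Transcript(file_id=file_id)
    last_tier: Optional[int] = None  # index into transcript.lines
    last_header: Optional[int] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        if raw[0] == "\t" or raw[0] == " ":
            continuation = raw.strip()
            if last_tier is not None:
                code, prev = transcript.lines[last_tier]
                transcript.lines[last_tier] = (code, prev + " " + continuation)
            elif last_header is not None:
                transcript.headers[last_header] += " " + continuation
            else:
                raise ChatParseError(
                    f"{file_id}:{lineno}: continuation line with no preceding tier"
                )
            continue
        if raw[0] == "@":
            transcript.headers.append(raw)
            last_header = len(transcript.headers) - 1
            last_tier = None
            head, _, value = raw.partition(":")
            value = value.strip()
            if head == "@Participants":
                transcript.participants = _parse_participants_header(value)
            elif head == "@ID":
                transcript.participants = _merge_id_header(
                    transcript.participants, value
                )
            continue
        if raw[0] in "*%":
            marker, colon, rest = raw.partition(":")
            if not colon or not re.fullmatch(r"[*%][A-Za-z][A-Za-z0-9]*", marker):
                raise ChatParseError(
                    f"{file_id}:{lineno}: malformed tier marker {raw.split()[0]!r} "
                    "(expected '*CODE:' or '%code:')"
                )
            transcript.lines.append((marker, rest.lstrip("\t ")))
            last_tier = len(transcript.lines) - 1
            last_header = None
            continue
        raise ChatParseError(
            f"{file_id}:{lineno}: unrecognized line start {raw[0]!r} "
            "(expected '@', '*', '%' or a tab continuation)"
        )
    return transcript


def read_chat(path: Union[str, Path]) -> Transcript:
    """Read a ``.cha`` file. Strict UTF-8: undecodable bytes raise, never mangle."""
    p = Path(path)
    return parse_chat(p.read_text(encoding="utf-8"), file_id=p.name)


def select_tier(transcript: Transcript, speaker_code: str) -> list[Utterance]:
    """Keep only the main-tier utterances of one speaker, re-indexed from 0.

    ``speaker_code`` may be given with or without the leading ``*``.  An absent
    speaker yields an empty list with a logged warning (empty sessions are
    legitimate, not errors).
    """
    want = speaker_code.lstrip("*").upper()
    utterances = []
    for code, text in transcript.main_tier_lines():
        if code.lstrip("*").upper() == want:
            utterances.append(
                Utterance(index=len(utterances), speaker_code=code, raw_text=text)
            )
    if not utterances:
        logger.warning(
            "speaker %r not found in %s (speakers present: %s)",
            speaker_code,
            transcript.file_id,
            ", ".join(transcript.speakers()) or "none",
        )
    return utterances


@dataclass(frozen=True)
class CleaningRules:
    """Ordered symbol-removal rules applied before tokenization.

    ``removal_patterns`` are literal strings deleted in order (e.g. a stray
    ``"*CHI:"`` left inside the text).  The flags switch the built-in CHAT
    code classes.  Applying the rules twice equals applying them once.
    """

    removal_patterns: tuple[str, ...] = ()
    drop_bracketed: bool = True
    drop_unintelligible: bool = True
    drop_pause_and_event_codes: bool = True
    case_fold: bool = True


DEFAULT_RULES = CleaningRules()

_BRACKETED = re.compile(r"\[[^\[\]]*\]")
_TIMESTAMP = re.compile(r"\x15[^\x15]*\x15|•[^•]*•")
_PAUSE = re.compile(r"\(\.{1,3}\)")
_UNINTELLIGIBLE = frozenset({"xxx", "yyy", "www"})
# keep word-internal apostrophes and @-markers stripped on the edges only
_EDGE_PUNCT = "\"'“”‘’.,;:!?¡¿()<>«»„‟+^~_/\\|=-"


def clean_tokens(text: str, rules: CleaningRules = DEFAULT_RULES) -> list[str]:
    """Apply cleaning rules to a raw utterance and return the surviving words."""
    if rules.drop_pause_and_event_codes:
        text = _TIMESTAMP.sub(" ", text)
        text = _PAUSE.sub(" ", text)
    if rules.drop_bracketed:
        prev = None
        while prev != text:  # handles nested brackets
            prev = text
            text = _BRACKETED.sub(" ", text)
    for pattern in rules.removal_patterns:
        text = text.replace(pattern, " ")

    words: list[str] = []
    for item in text.split():
        if rules.drop_pause_and_event_codes and (
            item.startswith("&") or item.startswith("+")
        ):
            continue
        item = item.strip(_EDGE_PUNCT)
        if not item:
            continue
        if rules.drop_unintelligible and item.lower() in _UNINTELLIGIBLE:
            continue
        words.append(item)
    return words


def clean_and_tokenize(
    utterance: Utterance, rules: CleaningRules = DEFAULT_RULES
) -> Utterance:
    """Return a copy of ``utterance`` with its token list populated.

    Cleaning is total: it never raises.  An utterance whose every word is
    removed comes back with an empty token list (``is_empty``) and is excluded
    from network construction downstream.
    """
    source = (
        " ".join(t.canonical for t in utterance.tokens)
        if utterance.tokens
        else utterance.raw_text
    )
    words = clean_tokens(source, rules)
    tokens = [
        Token(
            position=i,
            surface=w,
            canonical=w.lower() if rules.case_fold else w,
        )
        for i, w in enumerate(words, start=1)
    ]
    return replace(utterance, tokens=tokens)


def load_cleaning_rules(source: Union[str, Path, TextIO]) -> CleaningRules:
    """Load :class:`CleaningRules` from a YAML document.

    Recognized keys: ``remove`` (ordered list of literal patterns),
    ``drop_bracketed``, ``drop_unintelligible``, ``drop_pause_and_event_codes``,
    ``case_fold`` (booleans).  Missing keys keep their defaults.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    data = yaml.safe_load(text) or {}
    patterns: Iterable[str] = data.get("remove", ())
    return CleaningRules(
        removal_patterns=tuple(str(p) for p in patterns),
        drop_bracketed=bool(data.get("drop_bracketed", True)),
        drop_unintelligible=bool(data.get("drop_unintelligible", True)),
        drop_pause_and_event_codes=bool(data.get("drop_pause_and_event_codes", True)),
        case_fold=bool(data.get("case_fold", True)),
    )
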