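"""Dictionary-based gene/protein token recognition in gel-label text.

Label text is tokenized on whitespace and punctuation (hyphens split, so
"β-actin" yields "β" and "actin"), filtered by exclusion rules, then
looked up case-sensitively in a gene-symbol lexicon — capitalization is
kept significant because many gel-label names are acronyms.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .figure_model import Segment, SegmentKind

__all__ = [
    "Lexicon",
    "ExclusionRules",
    "ExclusionReason",
    "Verdict",
    "GeneMention",
    "DOMAIN_WORDS",
    "tokenize",
    "is_roman_numeral",
    "is_excluded",
    "recognize",
    "gene_token_ratio",
    "load_frequent_words",
    "load_fixture_lexicon",
]

# The 22 fixed gel-context exclusion words; several coincide with gene
# symbols, which is exactly why they must be filtered.
DOMAIN_WORDS: frozenset[str] = frozenset(
    {
        "min", "hrs", "line", "type", "protein", "DNA", "RNA", "mRNA",
        "membrane", "gel", "fold", "fragment", "antigen", "enzyme",
        "kinase", "cleavage", "factor", "blot", "pro", "pre", "peptide",
        "cell",
    }
)
assert len(DOMAIN_WORDS) == 22

# Word characters minus underscore; covers unicode letters such as β.
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

_ROMAN_RE = re.compile(
    r"^M{0,4}(CM|CD|D?C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$"
)


class ExclusionReason(str, enum.Enum):
    TOO_SHORT = "TOO_SHORT"
    NUMBER = "NUMBER"
    FREQUENT_WORD = "FREQUENT_WORD"
    DOMAIN_WORD = "DOMAIN_WORD"


class Verdict(str, enum.Enum):
    MATCH = "MATCH"
    EXCLUDED = "EXCLUDED"
    NO_MATCH = "NO_MATCH"


@dataclass(frozen=True)
class Lexicon:
    """Case-preserved gene-symbol set; lookup is exact-case."""

    symbols: frozenset[str]
    source_name: str = "unnamed"
    version: str = "0"

    def __post_init__(self) -> None:
        if any(not s for s in self.symbols):
            raise ValueError("lexicon contains an empty symbol")

    def __contains__(self, token: str) -> bool:
        return token in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_file(cls, path: str | Path, source_name: str | None = None) -> "Lexicon":
        """One symbol per line, UTF-8; blank lines and '#' comments skipped."""
        path = Path(path)
        symbols = {
            line.strip()
            for line in path.read_text("utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        }
        return cls(symbols=frozenset(symbols), source_name=source_name or path.name)


@dataclass(frozen=True)
class ExclusionRules:
    min_length: int = 3
    frequent_words: frozenset[str] = field(default_factory=frozenset)
    domain_words: frozenset[str] = DOMAIN_WORDS

    @classmethod
    def default(cls) -> "ExclusionRules":
        return cls(frequent_words=load_frequent_words())


@dataclass(frozen=True)
class GeneMention:
    token: str
    verdict: Verdict
    label_segment_id: str = ""
    matched_symbol: str = ""
    exclusion_reason: ExclusionReason | None = None

    def to_dict(self) -> dict:
        return {
            "token": self.token,
            "verdict": self.verdict.value,
            "label_segment_id": self.label_segment_id,
            "matched_symbol": self.matched_symbol,
            "exclusion_reason": (
                self.exclusion_reason.value if self.exclusion_reason else None
            ),
        }


def tokenize(label_text: str) -> list[str]:
    """Split on whitespace and punctuation, including internal hyphens.

    "MDA-MB-231 NHEM" → [MDA, MB, 231, NHEM]; order preserved, empty
    tokens dropped.
    """
    return _TOKEN_RE.findall(label_text)


def is_roman_numeral(token: str) -> bool:
    """Valid Roman numeral, case-insensitive ('XII' yes, 'VV' no)."""
    upper = token.upper()
    return bool(upper) and bool(_ROMAN_RE.match(upper))


def is_excluded(
    token: str, rules: ExclusionRules
) -> tuple[bool, ExclusionReason | None]:
    """Apply exclusions in fixed precedence order.

    TOO_SHORT → NUMBER → FREQUENT_WORD → DOMAIN_WORD; the first firing
    reason is reported.
    """
    if not token:
        raise ValueError("empty token")
    if len(token) < rules.min_length:
        return True, ExclusionReason.TOO_SHORT
    if token.isdigit() or is_roman_numeral(token):
        return True, ExclusionReason.NUMBER
    if token in rules.frequent_words or token.lower() in rules.frequent_words:
        return True, ExclusionReason.FREQUENT_WORD
    if token in rules.domain_words:
        return True, ExclusionReason.DOMAIN_WORD
    return False, None


def recognize(
    labels: Sequence[Segment],
    lexicon: Lexicon,
    rules: ExclusionRules,
) -> list[GeneMention]:
    """Tokenize TEXT segments and classify every token.

    Per token: EXCLUDED if a rule fires, else MATCH iff the token is in
    the lexicon with exact case, else NO_MATCH. Pure function of its
    inputs.
    """
    mentions: list[GeneMention] = []
    for seg in labels:
        if seg.kind is not SegmentKind.TEXT:
            raise ValueError(f"segment {seg.segment_id!r} is not a TEXT segment")
        for token in tokenize(seg.text):
            excluded, reason = is_excluded(token, rules)
            if excluded:
                mentions.append(
                    GeneMention(
                        token=token,
                        verdict=Verdict.EXCLUDED,
                        label_segment_id=seg.segment_id,
                        exclusion_reason=reason,
                    )
                )
            elif token in lexicon:
                mentions.append(
                    GeneMention(
                        token=token,
                        verdict=Verdict.MATCH,
                        label_segment_id=seg.segment_id,
                        matched_symbol=token,
                    )
                )
            else:
                mentions.append(
                    GeneMention(
                        token=token,
                        verdict=Verdict.NO_MATCH,
                        label_segment_id=seg.segment_id,
                    )
                )
    return mentions


def gene_token_ratio(mentions: Iterable[GeneMention], all_tokens: int) -> float:
    """MATCH count over total token count."""
    if all_tokens < 1:
        raise ValueError("gene_token_ratio requires at least one token")
    n_match = sum(1 for m in mentions if m.verdict is Verdict.MATCH)
    return n_match / all_tokens


def _read_data_file(name: str) -> list[str]:
    text = resources.files("gelminer.data").joinpath(name).read_text("utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_frequent_words() -> frozenset[str]:
    """Bundled ~100-entry frequent-word list (editable data file)."""
    return frozenset(_read_data_file("frequent_words.txt"))


def load_fixture_lexicon() -> Lexicon:
    """Small bundled gene-symbol lexicon for tests and demos."""
    return Lexicon(
        symbols=frozenset(_read_data_file("fixture_lexicon.txt")),
        source_name="fixture_lexicon",
        version="1",
    )
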