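"""Scientific-name parsing and author-citation comparison.

Splits a verbatim name string such as ``"Primula matthioli (L.) V.A.Richt."``
into its canonical part (``Primula matthioli``) and authorship
(``(L.) V.A.Richt.``), and compares author citations under the
normalisations that matter in botany: diacritic removal ("Hultén" vs
"Hulten"), abbreviation conventions ("Hook.f." vs "Hook.fil."), and
basionym parentheses recorded on only one side.

The comparison outcome feeds the match classification used downstream:
``identical``/``normalized_match`` count as an author-exact match,
``absent`` as "noauthor", ``mismatch`` as a homonym signal.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "ParsedName",
    "AuthorComparison",
    "ComparisonOutcome",
    "InfraspecificMarker",
    "parse_name",
    "normalize_author_token",
    "compare_authorship",
]


class InfraspecificMarker(str, enum.Enum):
    NONE = "none"
    SUBSP = "subsp"
    VAR = "var"
    F = "f"


class Quality(str, enum.Enum):
    CLEAN = "clean"
    PARTIAL = "partial"
    UNPARSEABLE = "unparseable"


class ComparisonOutcome(str, enum.Enum):
    IDENTICAL = "identical"
    NORMALIZED_MATCH = "normalized_match"
    ABSENT = "absent"
    MISMATCH = "mismatch"


@dataclass
class ParsedName:
    verbatim: str
    genus: str = ""
    epithet: str = ""
    infraspecific_epithet: str = ""
    infraspecific_marker: InfraspecificMarker = InfraspecificMarker.NONE
    hybrid: bool = False
    canonical: str = ""
    authorship_verbatim: str = ""
    basionym_authors: list[str] = field(default_factory=list)
    combination_authors: list[str] = field(default_factory=list)
    year: str = ""
    quality: Quality = Quality.CLEAN


@dataclass
class AuthorComparison:
    outcome: ComparisonOutcome
    evidence: list[str] = field(default_factory=list)


def _load_abbreviations() -> dict[str, str]:
    with resources.files("taxonlink.data").joinpath("author_abbreviations.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        data = yaml.safe_load(fh) or {}
    return {str(k).lower(): str(v).lower() for k, v in data.get("equivalences", {}).items()}


_ABBREVIATIONS = _load_abbreviations()

# Latin word shapes. Epithets may be hyphenated; genera are capitalised.
_GENUS_RE = re.compile(r"^[A-ZÀ-Þ][a-zß-ÿ]+$")
_EPITHET_RE = re.compile(r"^[a-zß-ÿ][a-zß-ÿ-]+$")
_YEAR_RE = re.compile(r"\b(1[5-9]\d\d|20\d\d)[a-z]?\b")

_MARKERS = {
    "subsp": InfraspecificMarker.SUBSP,
    "ssp": InfraspecificMarker.SUBSP,
    "var": InfraspecificMarker.VAR,
    "f": InfraspecificMarker.F,
}
_MARKER_CANONICAL = {
    InfraspecificMarker.SUBSP: "subsp.",
    InfraspecificMarker.VAR: "var.",
    InfraspecificMarker.F: "f.",
}


def parse_name(verbatim: str) -> ParsedName:
    """Decompose a scientific-name string; never raises on content.

    Strings whose first word does not look like a genus name come back
    with ``quality=unparseable`` and all structured fields empty.
    """
    parsed = ParsedName(verbatim=verbatim)
    text = " ".join(verbatim.split())
    if not text:
        parsed.quality = Quality.UNPARSEABLE
        return parsed

    tokens = text.split(" ")
    i = 0

    # hybrid sign: leading multiplication sign or a standalone lowercase "x"
    if tokens[i] in ("×", "x", "X") and len(tokens) > i + 1:
        parsed.hybrid = True
        i += 1
    elif tokens[i].startswith("×"):
        parsed.hybrid = True
        tokens[i] = tokens[i][1:]

    if i >= len(tokens) or not _GENUS_RE.match(tokens[i]):
        parsed.quality = Quality.UNPARSEABLE
        return parsed
    parsed.genus = tokens[i]
    i += 1

    # species epithet (may itself carry a hybrid sign)
    if i < len(tokens):
        tok = tokens[i]
        if tok in ("×", "x") and i + 1 < len(tokens) and _EPITHET_RE.match(tokens[i + 1]):
            parsed.hybrid = True
            i += 1
            tok = tokens[i]
        elif tok.startswith("×"):
            parsed.hybrid = True
            tok = tok[1:]
        if _EPITHET_RE.match(tok):
            parsed.epithet = tok
            i += 1

    # infraspecific marker + epithet: "subsp."/"ssp."/"var."/"f." followed by
    # a lowercase epithet.  A bare "f." not followed by an epithet is the
    # filius author abbreviation, not a forma marker.
    if parsed.epithet and i + 1 < len(tokens):
        marker = _MARKERS.get(tokens[i].rstrip(".").lower())
        if marker is not None and _EPITHET_RE.match(tokens[i + 1]):
            parsed.infraspecific_marker = marker
            parsed.infraspecific_epithet = tokens[i + 1]
            i += 2

    parsed.canonical = _build_canonical(parsed)
    rest = " ".join(tokens[i:]).strip()
    parsed.authorship_verbatim = rest
    if rest:
        _parse_authorship(parsed, rest)
        if not parsed.combination_authors and not parsed.basionym_authors:
            # there was trailing text but nothing recognisable as authors
            parsed.quality = Quality.PARTIAL
    return parsed


def _build_canonical(parsed: ParsedName) -> str:
    parts = [parsed.genus]
    if parsed.epithet:
        parts.append(parsed.epithet)
        if parsed.infraspecific_epithet:
            parts.append(_MARKER_CANONICAL[parsed.infraspecific_marker])
            parts.append(parsed.infraspecific_epithet)
    return " ".join(parts)


def _parse_authorship(parsed: ParsedName, rest: str) -> None:
    """Fill basionym/combination author lists and year from a citation."""
    year_match = _YEAR_RE.search(rest)
    if year_match:
        parsed.year = year_match.group(0)
        rest = _YEAR_RE.sub(" ", rest)
    basionym = ""
    match = re.match(r"^\(([^()]*)\)\s*(.*)$", rest.strip())
    if match:
        basionym, rest = match.group(1), match.group(2)
    parsed.basionym_authors = split_author_tokens(basionym)
    parsed.combination_authors = split_author_tokens(rest)
    if "(" in rest or ")" in rest:
        parsed.quality = Quality.PARTIAL


def split_author_tokens(citation: str) -> list[str]:
    """Split an author citation into individual author name strings.

    ``"A ex B"`` keeps the publishing author(s) B; ``"A in B"`` keeps the
    name author(s) A — the usual botanical reading of those constructions.
    "et" is unified with "&"; commas also separate authors.
    """
    text = " ".join(citation.replace(",", " , ").split())
    if not text:
        return []
    ex_parts = re.split(r"\s+ex\s+", text)
    text = ex_parts[-1]
    in_parts = re.split(r"\s+in\s+", text)
    text = in_parts[0]
    text = re.sub(r"\s+et\s+", " & ", text)
    tokens = [t.strip(" ,") for t in re.split(r"[&,]", text)]
    return [t for t in tokens if t]


def normalize_author_token(token: str) -> str:
    """Normal form of one author name: diacritics stripped, lower-cased,
    trailing periods removed, abbreviation equivalences applied
    ("fil" → "f", so "Hook.fil." and "Hook.f." share one form).

    Idempotent: normalising a normal form returns it unchanged.
    """
    decomposed = unicodedata.normalize("NFKD", token)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    lowered = " ".join(stripped.lower().split())
    lowered = lowered.rstrip(".")
    segments = [s for s in lowered.split(".") if s]
    segments = [_ABBREVIATIONS.get(s, s) for s in segments]
    return ".".join(segments)


def _normalized_sequence(tokens: list[str]) -> list[str]:
    return [normalize_author_token(t) for t in tokens]


def _normalization_evidence(a_tokens: list[str], b_tokens: list[str]) -> list[str]:
    """Which normalisation steps were load-bearing for the token match."""
    evidence: list[str] = []
    for ta, tb in zip(a_tokens, b_tokens):
        if ta == tb:
            continue
        if ta.lower() == tb.lower():
            evidence.append("case-fold")
            continue
        plain_a = "".join(
            c for c in unicodedata.normalize("NFKD", ta) if not unicodedata.combining(c)
        )
        plain_b = "".join(
            c for c in unicodedata.normalize("NFKD", tb) if not unicodedata.combining(c)
        )
        if plain_a != ta or plain_b != tb:
            evidence.append("diacritic-strip")
        if plain_a.lower().rstrip(".") != plain_b.lower().rstrip("."):
            evidence.append("abbreviation-equivalence")
        elif plain_a.rstrip(".") != plain_b.rstrip("."):
            evidence.append("punctuation-strip")
    seen: set[str] = set()
    unique = []
    for step in evidence:
        if step not in seen:
            seen.add(step)
            unique.append(step)
    return unique


def compare_authorship(a: ParsedName, b: ParsedName) -> AuthorComparison:
    """Compare two author citations; symmetric in its arguments.

    ``absent`` when either side lacks an author citation; ``identical``
    for whitespace-collapsed equality of the verbatim citations;
    ``normalized_match`` when the token-normalised author sequences agree
    (basionym and combination compared separately); ``mismatch`` otherwise.

    When exactly one side records a parenthesised basionym citation, that
    side's combination authors are compared against the other side's full
    author list before declaring a mismatch — databases are inconsistent
    about recording basionym parentheses.
    """
    av = " ".join(a.authorship_verbatim.split())
    bv = " ".join(b.authorship_verbatim.split())
    if not av or not bv:
        return AuthorComparison(ComparisonOutcome.ABSENT)
    if av == bv:
        return AuthorComparison(ComparisonOutcome.IDENTICAL)

    a_bas, b_bas = _normalized_sequence(a.basionym_authors), _normalized_sequence(b.basionym_authors)
    a_com, b_com = _normalized_sequence(a.combination_authors), _normalized_sequence(b.combination_authors)

    if a_bas == b_bas and a_com == b_com and (a_com or a_bas):
        evidence = _normalization_evidence(
            a.basionym_authors + a.combination_authors,
            b.basionym_authors + b.combination_authors,
        )
        return AuthorComparison(ComparisonOutcome.NORMALIZED_MATCH, evidence)

    # one-sided basionym citation: "(L.) V.A.Richt." vs "V.A.Richt."
    if bool(a_bas) != bool(b_bas):
        with_bas, without = (a_com, b_com) if a_bas else (b_com, a_com)
        if with_bas and with_bas == without:
            return AuthorComparison(
                ComparisonOutcome.NORMALIZED_MATCH, ["basionym-citation-ignored"]
            )
    return AuthorComparison(ComparisonOutcome.MISMATCH)
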