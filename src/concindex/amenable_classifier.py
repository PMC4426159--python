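"""Classification of deaths amenable to health care by ICD-10 code and age.

The cause list is shipped as a plain CSV (``data/amenable_rules.csv``) with
one row per cause: a label, the place of intervention (primary vs
specialized health care), the timing of intervention for primary-care
causes, an inclusive age window, and one or more ICD-10 code patterns.

Pattern semantics follow the conventional ICD-10 range notation:

* ``"A00-09"`` matches every code whose letter is A and whose two-digit
  block lies in 00..09, including decimal subcodes (``A05.1``);
* ``"A48.1"`` matches exactly that subcode and its children, but not
  ``A48.0``;
* ``"L03"`` matches the single block L03 and its subcodes;
* a range never crosses a letter boundary unless both letters are written
  (``"A99-B05"``).

Codes are normalized (uppercased, dot removed) before comparison.  A rule
may carry exclusion patterns; a code matching an exclusion never matches
the rule.  Classification returns every matching rule — the analysis only
needs amenable yes/no, so overlaps are not ranked.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "IcdMatcher",
    "AmenableRule",
    "IcdPatternError",
    "parse_icd_range",
    "load_rules",
    "rules_to_csv",
    "parse_rules_csv",
    "classify_amenable",
    "is_amenable",
]

_RULES_RESOURCE = "amenable_rules.csv"

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(.*)$")
_SUBCODE_RE = re.compile(r"^([A-Z])(\d{2})\.(\d+)$")
_BLOCK_RE = re.compile(r"^([A-Z])(\d{2})$")
_RANGE_RE = re.compile(r"^([A-Z])(\d{2})[–-]([A-Z])?(\d{2})$")


class IcdPatternError(ValueError):
    """A code pattern does not parse as an ICD-10 prefix or range."""


def normalize_code(code: str) -> str:
    return code.strip().upper().replace(".", "").replace(" ", "")


@dataclass(frozen=True)
class IcdMatcher:
    """Compiled matcher for one ICD-10 pattern.

    Either an interval over (letter, two-digit block) keys, or an exact
    subcode prefix.
    """

    pattern: str
    start: tuple[str, int] | None = None
    end: tuple[str, int] | None = None
    prefix: str | None = None

    def matches(self, code: str) -> bool:
        norm = normalize_code(code)
        if self.prefix is not None:
            return norm.startswith(self.prefix)
        m = _CODE_RE.match(norm)
        if not m:
            return False
        key = (m.group(1), int(m.group(2)))
        return self.start <= key <= self.end  # type: ignore[operator]


def parse_icd_range(pattern: str) -> IcdMatcher:
    """Parse an ICD-10 pattern into a matcher; raise on malformed input."""
    raw = pattern.strip().upper()
    if not raw:
        raise IcdPatternError("empty ICD-10 pattern")
    m = _SUBCODE_RE.match(raw)
    if m:
        return IcdMatcher(pattern=raw, prefix=normalize_code(raw))
    m = _BLOCK_RE.match(raw)
    if m:
        key = (m.group(1), int(m.group(2)))
        return IcdMatcher(pattern=raw, start=key, end=key)
    m = _RANGE_RE.match(raw)
    if m:
        start = (m.group(1), int(m.group(2)))
        end_letter = m.group(3) or m.group(1)
        end = (end_letter, int(m.group(4)))
        if end < start:
            raise IcdPatternError(f"range {raw!r} runs backwards")
        return IcdMatcher(pattern=raw, start=start, end=end)
    # pinpoint the first character that breaks the expected shape
    for pos, ch in enumerate(raw):
        expected_alpha = pos == 0
        if expected_alpha != ch.isalpha() and ch not in "0123456789.-–":
            break
    else:
        pos = len(raw) - 1
    raise IcdPatternError(
        f"malformed ICD-10 pattern {raw!r} (near position {pos})"
    )


@dataclass(frozen=True)
class AmenableRule:
    """One amenable-mortality cause with its age window and code patterns."""

    cause_label: str
    place: str  # "primary health care" | "specialized health care"
    timing: str  # prevention/treatment category, or "none"
    age_min: int
    age_max: int
    icd_patterns: tuple[str, ...]
    exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.age_min < 0 or self.age_max < self.age_min:
            raise ValueError(
                f"invalid age window [{self.age_min}, {self.age_max}] "
                f"for {self.cause_label!r}"
            )
        object.__setattr__(
            self,
            "_matchers",
            tuple(parse_icd_range(p) for p in self.icd_patterns),
        )
        object.__setattr__(
            self,
            "_excl_matchers",
            tuple(parse_icd_range(p) for p in self.exclusions),
        )

    def matches(self, icd: str, age: float) -> bool:
        if not self.age_min <= age <= self.age_max:
            return False
        if any(m.matches(icd) for m in self._excl_matchers):  # type: ignore[attr-defined]
            return False
        return any(m.matches(icd) for m in self._matchers)  # type: ignore[attr-defined]


def parse_rules_csv(text: str) -> tuple[AmenableRule, ...]:
    """Parse the rule CSV dialect (patterns ';'-separated within a field)."""
    reader = csv.DictReader(io.StringIO(text))
    rules = []
    for row in reader:
        rules.append(
            AmenableRule(
                cause_label=row["cause_label"],
                place=row["place"],
                timing=row["timing"],
                age_min=int(row["age_min"]),
                age_max=int(row["age_max"]),
                icd_patterns=tuple(
                    p for p in row["icd_patterns"].split(";") if p.strip()
                ),
                exclusions=tuple(
                    p for p in (row.get("exclusions") or "").split(";") if p.strip()
                ),
            )
        )
    return tuple(rules)


def rules_to_csv(rules: tuple[AmenableRule, ...]) -> str:
    """Serialize rules back to the packaged CSV dialect (round-trippable)."""
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(
        ["cause_label", "place", "timing", "age_min", "age_max",
         "icd_patterns", "exclusions"]
    )
    for r in rules:
        writer.writerow(
            [r.cause_label, r.place, r.timing, r.age_min, r.age_max,
             ";".join(r.icd_patterns), ";".join(r.exclusions)]
        )
    return out.getvalue()


def load_rules() -> tuple[AmenableRule, ...]:
    """Load the packaged amenable-mortality cause list."""
    text = (
        resources.files("concindex").joinpath("data", _RULES_RESOURCE).read_text()
    )
    return parse_rules_csv(text)


def classify_amenable(
    icd: str, age: float, rules: tuple[AmenableRule, ...] | None = None
) -> list[AmenableRule]:
    """All rules matching an (ICD-10 code, age) pair; empty = not amenable.

    An unparseable code yields an empty result with a warning rather than an
    error, so bulk classification of raw register extracts never aborts.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if rules is None:
        rules = load_rules()
    if not _CODE_RE.match(normalize_code(icd)):
        warnings.warn(
            f"unrecognized ICD-10 code {icd!r}; treated as not amenable",
            stacklevel=2,
        )
        return []
    return [r for r in rules if r.matches(icd, age)]


def is_amenable(
    icd: str, age: float, rules: tuple[AmenableRule, ...] | None = None
) -> bool:
    """Convenience wrapper: does any rule match?"""
    return bool(classify_amenable(icd, age, rules))
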