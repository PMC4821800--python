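"""Rule-based detection of sex and age mentions in article text.

Sex detection is deliberately *minimal* dictionary matching over a small
vocabulary of sex words and both-sex phrases: no inference is attempted, so
sex implied only by proxy words such as "pregnant" is not detected, and
literal sex words in breeding descriptions ("crossing male carriers with
FVB/NJ females") do match even when no experimental cohort has a stated sex.
Both behaviors are intentional properties of the dictionary approach.

Age detection requires a numeral (digits or the number words one..twelve),
or a closed numeric range, adjacent to a day/week/month unit *and* an
explicit age clue ("aged", "old", "of age", "age of", "age:", ...).
Open-ended spans ("postnatal day 7 to several months") and bare
numeral-unit forms with no clue ("15-d timed-pregnant") therefore yield no
mention.

Rules are declarative: each rule is an id, a kind, a pattern written with
the macros <NUM>, <RANGE>, <SEP>, <UNIT>, and (for sex) the emitted
category. The shipped default set can be exported to YAML, edited, and
loaded back, so an alternative rule inventory can be swapped in without
touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

import yaml

from .models import AGE_UNITS, DAYS_PER_UNIT, AgeValue, InputError, Mention

# ---------------------------------------------------------------------------
# Pattern macros

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
}

_NUM_INT = r"(?:\d+|" + "|".join(_NUMBER_WORDS) + r")"
_NUM_DEC = r"(?:\d+(?:\.\d+)?|" + "|".join(_NUMBER_WORDS) + r")"
# range connectors: "to", "and", hyphen, en dash, em dash
_CONN = r"\s*(?:to|and|[-–—])\s*"
_SEP = r"[\s\-–—]+"
_UNIT = r"(?:days?|weeks?|wks?|months?|mos?|d|wk|mo)"

_UNIT_NORMALIZE = {
    "d": "day", "day": "day", "days": "day",
    "wk": "week", "wks": "week", "week": "week", "weeks": "week",
    "mo": "month", "mos": "month", "month": "month", "months": "month",
}


def _expand(pattern: str, allow_decimals: bool = False) -> str:
    num = _NUM_DEC if allow_decimals else _NUM_INT
    out = pattern
    out = out.replace("<RANGE>", num + _CONN + num)
    out = out.replace("<NUM>", num)
    out = out.replace("<SEP>", _SEP)
    out = out.replace("<UNIT>", _UNIT)
    return out


@dataclass(frozen=True)
class RuleSpec:
    """One declarative extraction rule."""

    rule_id: str
    kind: str  # "sex" | "age"
    pattern: str  # regex with <NUM>/<RANGE>/<SEP>/<UNIT> macros
    sex_category: Optional[str] = None  # sex rules only

    def __post_init__(self) -> None:
        if self.kind not in ("sex", "age"):
            raise ValueError(f"rule {self.rule_id}: unknown kind {self.kind!r}")
        if self.kind == "sex" and self.sex_category not in ("female", "male", "both"):
            raise ValueError(f"rule {self.rule_id}: sex rule needs a category")


# ---------------------------------------------------------------------------
# Default rule inventory
#
# The sex rules are a plain dictionary of sex words and both-sex phrases.
# Phrase rules are listed alongside the single-word rules; overlap resolution
# (leftmost-longest) makes the most specific phrase win.

DEFAULT_SEX_RULES: List[RuleSpec] = [
    RuleSpec("sex_either_sex", "sex", r"\beither\s+sex(?:es)?\b", sex_category="both"),
    RuleSpec("sex_mice_of_either_sex", "sex",
             r"\b(?:mice|mouse|animals)\s+of\s+either\s+sex(?:es)?\b", sex_category="both"),
    RuleSpec("sex_both_sexes", "sex", r"\bboth\s+sexes\b", sex_category="both"),
    RuleSpec("sex_both_sex", "sex", r"\bboth\s+sex\b", sex_category="both"),
    RuleSpec("sex_mice_of_both_sexes", "sex",
             r"\b(?:mice|mouse|animals)\s+of\s+both\s+sexes\b", sex_category="both"),
    RuleSpec("sex_male_and_female", "sex",
             r"\bmales?\s+and\s+females?\b", sex_category="both"),
    RuleSpec("sex_female_and_male", "sex",
             r"\bfemales?\s+and\s+males?\b", sex_category="both"),
    RuleSpec("sex_mixed_sex", "sex", r"\bmixed[\s-]sex(?:es)?\b", sex_category="both"),
    RuleSpec("sex_each_sex", "sex", r"\beach\s+sex\b", sex_category="both"),
    RuleSpec("sex_separated_by_sex", "sex", r"\bseparated\s+by\s+sex\b", sex_category="both"),
    RuleSpec("sex_female_mice", "sex",
             r"\bfemales?[\s-](?:mice|mouse)\b", sex_category="female"),
    RuleSpec("sex_male_mice", "sex",
             r"\bmales?[\s-](?:mice|mouse)\b", sex_category="male"),
    RuleSpec("sex_female", "sex", r"\bfemales?\b", sex_category="female"),
    RuleSpec("sex_male", "sex", r"\bmales?\b", sex_category="male"),
]

# Age rules: every pattern couples a numeral/range + unit with an age clue.
DEFAULT_AGE_RULES: List[RuleSpec] = [
    RuleSpec("age_aged_range_old", "age", r"\baged\s+<RANGE><SEP><UNIT>\s+old\b"),
    RuleSpec("age_aged_single_old", "age", r"\baged\s+<NUM><SEP><UNIT>\s+old\b"),
    RuleSpec("age_aged_range", "age", r"\baged\s+<RANGE><SEP><UNIT>\b"),
    RuleSpec("age_aged_single", "age", r"\baged\s+<NUM><SEP><UNIT>\b"),
    RuleSpec("age_aged_between", "age",
             r"\baged\s+between\s+<NUM>\s+and\s+<NUM><SEP><UNIT>\b"),
    RuleSpec("age_range_old", "age", r"\b<RANGE><SEP><UNIT><SEP>old\b"),
    RuleSpec("age_single_old", "age", r"\b<NUM><SEP><UNIT><SEP>old\b"),
    RuleSpec("age_range_of_age", "age", r"\b<RANGE><SEP><UNIT>\s+of\s+age\b"),
    RuleSpec("age_single_of_age", "age", r"\b<NUM><SEP><UNIT>\s+of\s+age\b"),
    RuleSpec("age_age_of_range", "age", r"\bage\s+of\s+<RANGE><SEP><UNIT>\b"),
    RuleSpec("age_age_of_single", "age", r"\bage\s+of\s+<NUM><SEP><UNIT>\b"),
    RuleSpec("age_at_the_age_of_range", "age",
             r"\bat\s+the\s+age\s+of\s+<RANGE><SEP><UNIT>\b"),
    RuleSpec("age_at_the_age_of_single", "age",
             r"\bat\s+the\s+age\s+of\s+<NUM><SEP><UNIT>\b"),
    RuleSpec("age_between_of_age", "age",
             r"\bbetween\s+<NUM>\s+and\s+<NUM><SEP><UNIT>\s+(?:of\s+age|old)\b"),
    RuleSpec("age_colon_range", "age", r"\bage\s*[:=]\s*<RANGE><SEP><UNIT>\b"),
    RuleSpec("age_colon_single", "age", r"\bage\s*[:=]\s*<NUM><SEP><UNIT>\b"),
    RuleSpec("age_range_of", "age", r"\bage\s+range\s+of\s+<RANGE><SEP><UNIT>\b"),
    RuleSpec("age_ranging_from", "age",
             r"\bages?\s+ranging\s+from\s+<NUM>\s+(?:to|and)\s+<NUM><SEP><UNIT>\b"),
]

# Optional extended profile: embryonic/postnatal staging, off by default.
EXTENDED_AGE_RULES: List[RuleSpec] = [
    RuleSpec("age_ext_postnatal_day", "age", r"\bpostnatal\s+day\s+(?:\(P\)\s*)?<NUM>\b"),
    RuleSpec("age_ext_p_number", "age", r"\bP<NUM>\b"),
]

DEFAULT_RULES: List[RuleSpec] = DEFAULT_SEX_RULES + DEFAULT_AGE_RULES


@dataclass(frozen=True)
class _CompiledRule:
    spec: RuleSpec
    regex: "re.Pattern[str]"
    order: int


class RuleSet:
    """Compiled, deterministic matcher over a rule inventory.

    Matching is case-insensitive. Within one kind, overlapping candidates
    are resolved leftmost-longest: at equal start the longer match shadows
    the shorter; rule order breaks exact ties.
    """

    def __init__(self, rules: List[_CompiledRule]):
        self._rules = rules

    @property
    def specs(self) -> List[RuleSpec]:
        return [r.spec for r in self._rules]

    def n_rules(self, kind: Optional[str] = None) -> int:
        return sum(1 for r in self._rules if kind is None or r.spec.kind == kind)

    def match(self, text: str, kind: str, doc_id: str = "doc") -> List[Mention]:
        candidates = []
        for rule in self._rules:
            if rule.spec.kind != kind:
                continue
            for m in rule.regex.finditer(text):
                candidates.append((m.start(), -(m.end() - m.start()), rule.order, m.end(), rule))
        candidates.sort(key=lambda c: c[:3])
        mentions: List[Mention] = []
        last_end = 0
        for start, _neglen, _order, end, rule in candidates:
            if start < last_end:
                continue  # shadowed by an earlier (leftmost-longest) winner
            surface = text[start:end]
            if rule.spec.kind == "sex":
                mentions.append(Mention(
                    doc_id=doc_id, start=start, end=end, surface=surface,
                    kind="sex", rule_id=rule.spec.rule_id,
                    sex_category=rule.spec.sex_category,
                ))
            else:
                mentions.append(Mention(
                    doc_id=doc_id, start=start, end=end, surface=surface,
                    kind="age", rule_id=rule.spec.rule_id,
                    age_value=parse_age_phrase(surface),
                ))
            last_end = end
        return mentions


def compile_rules(specs: Iterable[RuleSpec], allow_decimals: bool = False) -> RuleSet:
    """Compile rule specs into a matcher; raises on bad pattern or duplicate id."""
    compiled: List[_CompiledRule] = []
    seen = set()
    for i, spec in enumerate(specs):
        if spec.rule_id in seen:
            raise InputError(f"duplicate rule_id {spec.rule_id!r}")
        seen.add(spec.rule_id)
        try:
            regex = re.compile(_expand(spec.pattern, allow_decimals), re.IGNORECASE)
        except re.error as exc:
            raise InputError(f"rule {spec.rule_id!r}: pattern does not compile: {exc}") from exc
        compiled.append(_CompiledRule(spec=spec, regex=regex, order=i))
    return RuleSet(compiled)


def default_ruleset(extended: bool = False, allow_decimals: bool = False) -> RuleSet:
    rules = list(DEFAULT_RULES)
    if extended:
        rules += EXTENDED_AGE_RULES
    return compile_rules(rules, allow_decimals=allow_decimals)


def match_sex_mentions(text: str, rules: RuleSet, doc_id: str = "doc") -> List[Mention]:
    """All sex mentions in reading order after overlap resolution."""
    return rules.match(text, "sex", doc_id=doc_id)


def match_age_mentions(text: str, rules: RuleSet, doc_id: str = "doc") -> List[Mention]:
    """All age mentions in reading order; each carries a parsed AgeValue."""
    return rules.match(text, "age", doc_id=doc_id)


# ---------------------------------------------------------------------------
# Age phrase parsing

_NUMERAL_RE = re.compile(
    r"\d+(?:\.\d+)?|\b(?:" + "|".join(_NUMBER_WORDS) + r")\b", re.IGNORECASE
)
_UNIT_RE = re.compile(r"\b" + _UNIT + r"\b", re.IGNORECASE)


def parse_age_phrase(surface: str) -> AgeValue:
    """Parse an age-rule surface form into an AgeValue.

    Accepts one or two numerals (digits, or the number words one..twelve)
    plus a day/week/month unit token in any of its abbreviated forms.
    A single numeral yields an exact age (min == max).
    """
    nums = []
    for tok in _NUMERAL_RE.findall(surface):
        low = tok.lower()
        nums.append(float(_NUMBER_WORDS[low]) if low in _NUMBER_WORDS else float(tok))
    unit_match = _UNIT_RE.search(surface)
    if not nums or unit_match is None:
        raise InputError(f"cannot parse age phrase {surface!r}: no numeral/unit found")
    if len(nums) > 2:
        raise InputError(f"cannot parse age phrase {surface!r}: too many numerals")
    unit = _UNIT_NORMALIZE[unit_match.group(0).lower()]
    if len(nums) == 1:
        return AgeValue(nums[0], nums[0], unit, qualifier="exact")
    lo, hi = sorted(nums)
    return AgeValue(lo, hi, unit, qualifier="range")


def normalize_age_to_days(v: AgeValue) -> tuple:
    """Convert an AgeValue to a day range under day=1, week=7, month=30."""
    k = DAYS_PER_UNIT[v.unit]
    return (v.min_value * k, v.max_value * k)


# ---------------------------------------------------------------------------
# Rule file I/O (YAML, one mapping per rule)

def save_rules(specs: Iterable[RuleSpec], path) -> None:
    entries = []
    for s in specs:
        e = {"id": s.rule_id, "kind": s.kind, "pattern": s.pattern}
        if s.sex_category:
            e["category"] = s.sex_category
        entries.append(e)
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False), encoding="utf-8")


def load_rules(path) -> List[RuleSpec]:
    p = Path(path)
    if not p.exists():
        raise InputError(f"rule file not found: {p}")
    raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    if not isinstance(raw, list):
        raise InputError(f"rule file {p}: expected a list of rule entries")
    specs = []
    for e in raw:
        try:
            specs.append(RuleSpec(
                rule_id=e["id"], kind=e["kind"], pattern=e["pattern"],
                sex_category=e.get("category"),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"rule file {p}: bad entry {e!r}: {exc}") from exc
    return specs
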