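"""Collapse candidate mentions into one document-level annotation.

When a document yields several candidate mentions for one characteristic,
the longest span is selected (usually the most informative); among mentions
of equal length the earliest offset wins. The result is at most one sex and
one age mention per document.

A document containing separate "male" and "female" mentions but no explicit
both-sex phrase resolves to whichever single mention wins — a deliberate
property of the unification algorithm (it can under-count both-sex designs);
such documents are flagged via a debug log line.
"""

from __future__ import annotations

import logging
import re
from typing import List, Optional

from .models import ArticleDoc, DocAnnotation, Mention
from .extraction import RuleSet, match_age_mentions, match_sex_mentions

logger = logging.getLogger(__name__)

_MIXED_RE = re.compile(r"\bmix", re.IGNORECASE)
_SEPARATED_RE = re.compile(r"\bseparat", re.IGNORECASE)


def unify_mentions(mentions: List[Mention], kind: str) -> Optional[Mention]:
    """Pick the single representative mention: longest span, earliest on ties.

    The result is independent of input order (ties beyond length are broken
    by offset, then rule id). Returns None on empty input; raises on mixed
    kinds.
    """
    if not mentions:
        return None
    for m in mentions:
        if m.kind != kind:
            raise ValueError(
                f"unify_mentions({kind!r}) got a {m.kind!r} mention ({m.rule_id})"
            )
    return min(mentions, key=lambda m: (-(m.end - m.start), m.start, m.rule_id))


def classify_sex_status(m: Mention) -> str:
    """Map a sex mention to its document-level category (female|male|both)."""
    if m.kind != "sex":
        raise ValueError(f"expected a sex mention, got kind={m.kind!r}")
    return m.sex_category


def _both_qualifier(m: Mention) -> str:
    """mixed / separated only when the winning surface itself encodes it."""
    if _SEPARATED_RE.search(m.surface):
        return "separated"
    if _MIXED_RE.search(m.surface):
        return "mixed"
    return "unspecified"


def annotate_document(doc: ArticleDoc, rules: RuleSet) -> DocAnnotation:
    """Run both extractors on the document text and unify each kind."""
    sex_mentions = match_sex_mentions(doc.text, rules, doc_id=doc.doc_id)
    age_mentions = match_age_mentions(doc.text, rules, doc_id=doc.doc_id)

    categories = {m.sex_category for m in sex_mentions}
    if {"male", "female"} <= categories and "both" not in categories:
        logger.debug(
            "doc %s: separate male and female mentions, no both-phrase; "
            "unification keeps a single category", doc.doc_id,
        )

    sex = unify_mentions(sex_mentions, "sex")
    age = unify_mentions(age_mentions, "age")
    return DocAnnotation(
        doc_id=doc.doc_id,
        sex_status=classify_sex_status(sex) if sex else "none",
        sex_mention=sex,
        sex_qualifier=(_both_qualifier(sex) if sex and sex.sex_category == "both" else None),
        age_status="reported" if age else "none",
        age_value=age.age_value if age else None,
        age_mention=age,
    )


def annotate_corpus(docs, rules: RuleSet) -> List[DocAnnotation]:
    return [annotate_document(d, rules) for d in docs]
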