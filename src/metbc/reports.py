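"""Rule-based ER-status extraction from pathology-report text.

The parser looks for an anchor token ("ER" as a standalone word, or any
word starting with "estrogen"), then for the closest status keyword within
a configurable line window and character distance. Positive keywords
default to {positive, detect, expression}; negative to {negative, rare}.
Negation tokens between the anchor and the keyword flip the status
("ER staining was not detected" -> negative). Boilerplate regions such as
staining-interpretation guides are removed before matching. When several
anchors yield evidence, the smallest anchor-keyword distance wins; exact
distance ties resolve to negative (conservative clinical default). Double
negation is not handled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd


@dataclass
class ParserConfig:
    positive_keywords: tuple = ("positive", "detect", "expression")
    negative_keywords: tuple = ("negative", "rare")
    negation_tokens: tuple = ("not", "no", "non-", "negative for", "without")
    negation_window_chars: int = 25
    window_lines: int = 3
    max_distance_chars: int = 130
    boilerplate_patterns: tuple = (
        r"(?im)^.*interpretation guide.*$",
        r"(?im)^.*reference manual.*$",
        r"(?im)^.*bibliograph.*$",
    )


@dataclass
class ParseResult:
    status: str                      # positive / negative / unknown
    anchor: str | None = None
    anchor_offset: int | None = None
    evidence: str | None = None
    evidence_offset: int | None = None
    distance_chars: int | None = None
    negated: bool = False
    filtered_reason: str | None = None


_ANCHOR_RE = re.compile(r"\bER\b|\bestrogen\w*", re.IGNORECASE)


def _strip_boilerplate(text: str, config: ParserConfig) -> str:
    for pat in config.boilerplate_patterns:
        # blank out instead of deleting so offsets stay comparable
        text = re.sub(pat, lambda m: " " * len(m.group(0)), text)
    return text


def _line_index(text: str):
    idx = []
    line = 0
    for ch in text:
        idx.append(line)
        if ch == "\n":
            line += 1
    return idx


def parse_er_status(text: str, config: ParserConfig | None = None) -> ParseResult:
    """Extract ER status from free text; always returns a ParseResult."""
    config = config or ParserConfig()
    if not text or not text.strip():
        return ParseResult(status="unknown", filtered_reason="empty text")
    clean = _strip_boilerplate(text, config)
    lines = _line_index(clean)

    keyword_re = re.compile(
        "|".join(
            f"(?P<p{i}>\\b{re.escape(k)}\\w*)" for i, k in enumerate(config.positive_keywords)
        ) + "|" + "|".join(
            f"(?P<n{i}>\\b{re.escape(k)}\\w*)" for i, k in enumerate(config.negative_keywords)
        ),
        re.IGNORECASE,
    )
    neg_res = [re.compile(r"\b" + re.escape(tok).replace(r"\-", r"\-?") + r"\b",
                          re.IGNORECASE)
               for tok in config.negation_tokens]

    candidates = []  # (distance, is_negative_keyword, anchor_m, kw_m, polarity)
    for am in _ANCHOR_RE.finditer(clean):
        a_line = lines[am.start()] if am.start() < len(lines) else lines[-1]
        for km in keyword_re.finditer(clean):
            k_line = lines[km.start()] if km.start() < len(lines) else lines[-1]
            if abs(k_line - a_line) > config.window_lines:
                continue
            if km.start() >= am.start():
                dist = km.start() - am.end()
            else:
                dist = am.start() - km.end()
            dist = max(dist, 0)
            if dist > config.max_distance_chars:
                continue
            polarity = "positive" if any(
                km.groupdict().get(f"p{i}") for i in range(len(config.positive_keywords))
            ) else "negative"
            candidates.append((dist, polarity == "negative", am, km, polarity))

    if not candidates:
        return ParseResult(status="unknown",
                           filtered_reason="no evidence within window/threshold")

    def resolve(am, km, polarity):
        # negation tokens between anchor and keyword, or in a short window
        # before the earlier of the two ("No ER expression ..."), flip the
        # status; the keyword's own text is never part of the search region
        lo = min(am.end(), km.end())
        hi = max(am.start(), km.start())
        span = clean[lo:hi] if hi > lo else ""
        first = min(am.start(), km.start())
        pre = clean[max(0, first - config.negation_window_chars):first]
        negated = any(nre.search(span) or nre.search(pre) for nre in neg_res)
        status = polarity
        if negated:
            status = "negative" if status == "positive" else "positive"
        return status, negated

    # smallest distance wins; exact ties resolve toward the negative reading
    def sort_key(c):
        dist, _, am, km, pol = c
        status, _ = resolve(am, km, pol)
        return (dist, 0 if status == "negative" else 1)

    dist, _, am, km, polarity = min(candidates, key=sort_key)
    status, negated = resolve(am, km, polarity)
    return ParseResult(
        status=status, anchor=am.group(0), anchor_offset=am.start(),
        evidence=km.group(0), evidence_offset=km.start(),
        distance_chars=int(dist), negated=bool(negated),
    )


def evaluate_parser(reports: list[str], truth: list[str],
                    config: ParserConfig | None = None) -> dict:
    """Exact-match accuracy of the parser over labelled reports."""
    if not reports:
        raise ValueError("need at least one labelled report")
    results = [parse_er_status(t, config) for t in reports]
    statuses = [r.status for r in results]
    acc = float(sum(s == t for s, t in zip(statuses, truth)) / len(truth))
    return {"accuracy": acc,
            "results": pd.DataFrame({"parsed": statuses, "truth": truth})}
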