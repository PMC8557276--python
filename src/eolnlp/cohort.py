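"""Proximity + fuzzy phrase retrieval over the document corpus.

Reproduces search-engine style phrase queries: a term like
``"family discussion"~5`` matches any contiguous span of at most
``len(tokens) + slop`` document tokens containing every query token
(order-free, each query token consuming a distinct position), so it
covers both "family discussion" and "discussion with the family".
Tokens of length >= 5 additionally match within one restricted
Damerau-Levenshtein edit when the fuzzy flag is on, absorbing
character inversions and mistypes.

Matched documents are aggregated to unique patients per query group;
patients with in-range documents matching no group form the no-phrase
control cohort.

An inverted index with a deletion-neighbourhood (SymSpell-style)
side table accelerates candidate retrieval; correctness is defined
solely by the span rule and is checked against an exhaustive-span
oracle in the tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date

import yaml

from .concepts import MIN_FUZZY_LEN, damerau_levenshtein, tokens_match
from .synth import Document, PatientRecord
from .textprep import TokenizedDoc, tokenize

__all__ = [
    "PhraseTerm",
    "PhraseQuery",
    "MatchResult",
    "CorpusIndex",
    "match_term",
    "run_query",
    "control_cohort",
    "parse_phrase_string",
    "load_queries_yaml",
]


@dataclass
class PhraseTerm:
    tokens: list[str]
    slop: int = 0
    fuzzy: bool = True
    max_edits: int = 1

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("a phrase term needs at least one token")
        if self.slop < 0:
            raise ValueError("slop must be >= 0")


@dataclass
class PhraseQuery:
    or_groups: list[PhraseTerm]          # any term matching suffices
    date_start: date
    date_end: date
    group_label: str
    patient_filter: str = "inpatient"    # fidelity hook; the corpus is all-inpatient

    def __post_init__(self) -> None:
        if not self.or_groups:
            raise ValueError("a query needs at least one term")
        if self.date_start > self.date_end:
            raise ValueError("query date_start must not exceed date_end")


@dataclass
class MatchResult:
    group_label: str
    matched_patient_ids: set[str] = field(default_factory=set)
    matched_doc_ids: set[str] = field(default_factory=set)
    positions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# span matching
# ---------------------------------------------------------------------------

def _assign(poslists: list[list[int]], used: set[int], j: int) -> bool:
    """Backtracking injective assignment of query tokens to positions."""
    if j == len(poslists):
        return True
    for p in poslists[j]:
        if p not in used:
            used.add(p)
            if _assign(poslists, used, j + 1):
                used.discard(p)
                return True
            used.discard(p)
    return False


def match_term(doc: TokenizedDoc | list[str], term: PhraseTerm) -> list[tuple[int, int]]:
    """All matching spans ``(start, end)`` (end exclusive).

    A span matches when its width is at most ``len(term.tokens) +
    term.slop`` and every query token can be assigned a distinct
    position inside it whose document token matches (exactly, or
    fuzzily for long tokens when enabled).
    """
    toks = doc.tokens if isinstance(doc, TokenizedDoc) else doc
    q = term.tokens
    max_edits = term.max_edits if term.fuzzy else 0
    width = len(q) + term.slop
    n = len(toks)
    # positions matching each query token
    matches = [
        [i for i in range(n) if tokens_match(toks[i], qt, max_edits)] for qt in q
    ]
    if any(not m for m in matches):
        return []
    spans = []
    for start in range(n):
        for end in range(start + len(q), min(start + width, n) + 1):
            posl = [[p for p in m if start <= p < end] for m in matches]
            if any(not pl for pl in posl):
                continue
            if _assign(posl, set(), 0):
                spans.append((start, end))
    return spans


def term_matches(doc: TokenizedDoc | list[str], term: PhraseTerm) -> bool:
    return bool(match_term(doc, term))


# ---------------------------------------------------------------------------
# corpus index
# ---------------------------------------------------------------------------

def _deletions(token: str) -> set[str]:
    return {token[:i] + token[i + 1:] for i in range(len(token))} | {token}


class CorpusIndex:
    """Tokenized corpus + inverted index + fuzzy candidate side table."""

    def __init__(self, documents: list[Document]):
        self.documents = documents
        self.doc_by_id = {d.doc_id: d for d in documents}
        self.tokens: dict[str, list[str]] = {
            d.doc_id: tokenize(d.text) for d in documents
        }
        self.postings: dict[str, set[str]] = {}
        for doc_id, toks in self.tokens.items():
            for t in set(toks):
                self.postings.setdefault(t, set()).add(doc_id)
        # SymSpell-style: deletion neighbourhood of vocab tokens long
        # enough to be a 1-edit variant of a fuzzy-eligible query token
        self._del_index: dict[str, set[str]] = {}
        for t in self.postings:
            if len(t) >= MIN_FUZZY_LEN - 1:
                for d in _deletions(t):
                    self._del_index.setdefault(d, set()).add(t)

    def fuzzy_vocabulary(self, query_token: str, max_edits: int = 1) -> set[str]:
        """Vocabulary tokens matching a query token under the per-token
        rule (exact, or DL <= max_edits for long tokens)."""
        out = set()
        if query_token in self.postings:
            out.add(query_token)
        if max_edits >= 1 and len(query_token) >= MIN_FUZZY_LEN:
            cands: set[str] = set()
            for d in _deletions(query_token):
                cands |= self._del_index.get(d, set())
            for c in cands:
                if c != query_token and damerau_levenshtein(c, query_token) <= max_edits:
                    out.add(c)
        return out

    def candidate_docs(self, term: PhraseTerm) -> set[str]:
        """Superset of documents that can match the term: intersection
        of per-token posting unions, seeded from the rarest token."""
        max_edits = term.max_edits if term.fuzzy else 0
        doc_sets = []
        for qt in term.tokens:
            variants = self.fuzzy_vocabulary(qt, max_edits)
            docs: set[str] = set()
            for v in variants:
                docs |= self.postings.get(v, set())
            if not docs:
                return set()
            doc_sets.append(docs)
        doc_sets.sort(key=len)
        out = doc_sets[0]
        for s in doc_sets[1:]:
            out = out & s
            if not out:
                break
        return out


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def run_query(index: CorpusIndex, patients: list[PatientRecord],
              query: PhraseQuery) -> MatchResult:
    """Documents matching any OR-group term inside the date range,
    aggregated to unique patients."""
    result = MatchResult(query.group_label)
    for term in query.or_groups:
        for doc_id in sorted(index.candidate_docs(term)):
            doc = index.doc_by_id[doc_id]
            if not (query.date_start <= doc.doc_date <= query.date_end):
                continue
            if doc_id in result.matched_doc_ids:
                continue
            spans = match_term(index.tokens[doc_id], term)
            if spans:
                result.matched_doc_ids.add(doc_id)
                result.matched_patient_ids.add(doc.patient_id)
                result.positions[doc_id] = spans
    return result


def control_cohort(index: CorpusIndex, patients: list[PatientRecord],
                   all_queries: list[PhraseQuery],
                   results: list[MatchResult] | None = None) -> set[str]:
    """Patients with at least one in-range document matching no query
    in any group.  Disjoint from every group's matched set."""
    if not all_queries:
        raise ValueError("control cohort needs the query list")
    start = all_queries[0].date_start
    end = all_queries[0].date_end
    for q in all_queries:
        if (q.date_start, q.date_end) != (start, end):
            raise ValueError("all queries must share one date range")
    if results is None:
        results = [run_query(index, patients, q) for q in all_queries]
    matched: set[str] = set()
    for r in results:
        matched |= r.matched_patient_ids
    in_range = {
        d.patient_id
        for d in index.documents
        if start <= d.doc_date <= end
    }
    return in_range - matched


# ---------------------------------------------------------------------------
# query files
# ---------------------------------------------------------------------------

_PHRASE_RE = re.compile(r'^\s*"(?P<phrase>[^"]+)"\s*(?:~(?P<slop>\d+))?\s*$')


def parse_phrase_string(s: str, fuzzy: bool = True, max_edits: int = 1) -> PhraseTerm:
    """Parse ``"ceiling of care"~5`` into a PhraseTerm (slop defaults
    to 0 without the ``~`` suffix; bare unquoted strings are allowed)."""
    m = _PHRASE_RE.match(s)
    if m:
        phrase, slop = m.group("phrase"), int(m.group("slop") or 0)
    else:
        phrase, slop = s, 0
    toks = tokenize(phrase)
    if not toks:
        raise ValueError(f"phrase parses to no tokens: {s!r}")
    return PhraseTerm(toks, slop=slop, fuzzy=fuzzy, max_edits=max_edits)


def load_queries_yaml(path: str, date_start: date | None = None,
                      date_end: date | None = None) -> list[PhraseQuery]:
    """Load query groups from YAML.

    Expected structure::

        date_range: {start: 2018-10-01, end: 2019-09-30}
        groups:
          - label: ceiling_of_care
            fuzzy: true          # optional, default true
            phrases: ['"ceiling of care"~5', '"limit of care"']
    """
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    dr = obj.get("date_range", {})

    def _coerce(v, fallback):
        if v is None:
            return fallback
        return v if isinstance(v, date) else date.fromisoformat(str(v))

    start = _coerce(dr.get("start"), date_start)
    end = _coerce(dr.get("end"), date_end)
    if start is None or end is None:
        raise ValueError("query file must define date_range (or pass explicit dates)")
    queries = []
    for grp in obj["groups"]:
        fuzzy = bool(grp.get("fuzzy", True))
        terms = [parse_phrase_string(p, fuzzy=fuzzy) for p in grp["phrases"]]
        queries.append(PhraseQuery(terms, start, end, grp["label"]))
    return queries
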