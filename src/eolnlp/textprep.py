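"""Tokenization and collocation phrasing.

Clinical free text is split into lowercase word tokens and then passed
through a statistical *phraser* that merges frequently co-occurring
adjacent tokens into 2-, 3- and 4-gram units ("ceiling_of_care"), so
that downstream embedding training treats recurring multi-word phrases
as single vocabulary items.

The phraser scores an adjacent token pair (a, b) with the discounted
normalized co-occurrence score

    score(a, b) = (count(a, b) - delta) * N / (count(a) * count(b))

where N is the corpus token count and ``delta`` discounts rare
accidental pairings.  Pairs scoring above a threshold are merged
greedily left to right.  Two sequential fit+apply passes turn words
into up-to-4-gram tokens (pass 1: words -> up to 2-grams; pass 2: can
pair two bigrams, or a bigram with a unigram).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

__all__ = [
    "TokenizedDoc",
    "PhraserModel",
    "tokenize",
    "fit_phraser",
    "apply_phraser",
    "build_ngrams",
    "ngram_span",
    "split_ngram",
    "display_form",
    "join_tokens",
]

#: separator used to join merged tokens; tokens produced by
#: :func:`tokenize` can never contain it, so splitting on it inverts
#: the merge exactly.
SEP = "_"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Split free text into lowercase word tokens.

    Splits on any run of non-alphanumeric characters; pure-digit tokens
    are retained; empty strings are dropped.  ``"not for I.T.U."`` ->
    ``["not", "for", "i", "t", "u"]``.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass
class TokenizedDoc:
    """A tokenized document.  After phrasing, tokens may be n-grams
    joined with :data:`SEP`."""

    doc_id: str
    tokens: list[str]


def ngram_span(token: str) -> int:
    """Number of source words the (possibly merged) token spans."""
    return token.count(SEP) + 1


def split_ngram(token: str) -> list[str]:
    """Invert the merge: split a joined n-gram back into its words."""
    return token.split(SEP)


def join_tokens(tokens: list[str]) -> str:
    """Join word tokens into the phraser's internal n-gram form."""
    return SEP.join(tokens)


def display_form(token: str) -> str:
    """Human-readable form of an n-gram token ('ceiling of care')."""
    return token.replace(SEP, " ")


@dataclass
class PhraserModel:
    """Collocation statistics for merging adjacent token pairs.

    Pairs observed fewer than ``min_count`` times are pruned at fit
    time, so their score is ``-delta * N / (count(a) * count(b)) <= 0``.
    """

    unigram_counts: dict[str, int]
    pair_counts: dict[tuple[str, str], int]
    delta: float
    threshold: float
    total_tokens: int
    min_count: int = 10
    max_span: int = 4  # merged token may span at most this many source words

    def score(self, a: str, b: str) -> float:
        ca = self.unigram_counts.get(a, 0)
        cb = self.unigram_counts.get(b, 0)
        if ca == 0 or cb == 0:
            return float("-inf")
        cab = self.pair_counts.get((a, b), 0)
        return (cab - self.delta) * self.total_tokens / (ca * cb)

    # -- serialization (JSON; pair keys joined with a tab) ------------

    def to_json(self, path: str) -> None:
        obj = {
            "unigram_counts": self.unigram_counts,
            "pair_counts": {f"{a}\t{b}": c for (a, b), c in self.pair_counts.items()},
            "delta": self.delta,
            "threshold": self.threshold,
            "total_tokens": self.total_tokens,
            "min_count": self.min_count,
            "max_span": self.max_span,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "PhraserModel":
        with open(path) as fh:
            obj = json.load(fh)
        pairs = {}
        for key, c in obj["pair_counts"].items():
            a, b = key.split("\t")
            pairs[(a, b)] = c
        return cls(
            unigram_counts=obj["unigram_counts"],
            pair_counts=pairs,
            delta=obj["delta"],
            threshold=obj["threshold"],
            total_tokens=obj["total_tokens"],
            min_count=obj.get("min_count", 10),
            max_span=obj.get("max_span", 4),
        )


def fit_phraser(
    corpus: list[TokenizedDoc] | list[list[str]],
    min_count: int = 10,
    threshold: float = 20.0,
    delta: float | None = None,
    max_span: int = 4,
) -> PhraserModel:
    """Count unigrams and adjacent pairs and return a scoring model.

    ``delta`` defaults to ``min_count`` so that any pair seen fewer than
    ``min_count`` times scores non-positive.  Adjacent pairs are counted
    within documents only (no pairs across document boundaries).
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if not corpus:
        raise ValueError("cannot fit a phraser on an empty corpus")
    if delta is None:
        delta = float(min_count)

    unigrams: dict[str, int] = {}
    pairs: dict[tuple[str, str], int] = {}
    total = 0
    for doc in corpus:
        tokens = doc.tokens if isinstance(doc, TokenizedDoc) else doc
        total += len(tokens)
        for tok in tokens:
            unigrams[tok] = unigrams.get(tok, 0) + 1
        for a, b in zip(tokens, tokens[1:]):
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
    # prune rare pairs: they can never merge and the model stays small
    pairs = {k: c for k, c in pairs.items() if c >= min_count}
    return PhraserModel(
        unigram_counts=unigrams,
        pair_counts=pairs,
        delta=delta,
        threshold=threshold,
        total_tokens=total,
        min_count=min_count,
        max_span=max_span,
    )


def _merge_pass(model: PhraserModel, tokens: list[str]) -> list[str]:
    """One greedy left-to-right merge pass (non-overlapping)."""
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n:
            a, b = tokens[i], tokens[i + 1]
            if (
                ngram_span(a) + ngram_span(b) <= model.max_span
                and model.score(a, b) > model.threshold
            ):
                out.append(a + SEP + b)
                i += 2
                continue
        out.append(tokens[i])
        i += 1
    return out


def apply_phraser(model: PhraserModel, doc: TokenizedDoc) -> TokenizedDoc:
    """Merge adjacent high-scoring pairs in one greedy pass.

    Deterministic: scans left to right; a merged pair is consumed and
    its components cannot take part in another merge within the pass.
    """
    return TokenizedDoc(doc.doc_id, _merge_pass(model, doc.tokens))


def build_ngrams(
    corpus: list[TokenizedDoc],
    min_count: int = 10,
    threshold: float = 20.0,
) -> tuple[list[TokenizedDoc], tuple[PhraserModel, PhraserModel]]:
    """Two-pass phrasing: words -> <=2-grams -> <=4-grams.

    Pass 2 can pair two bigrams into a 4-gram or a bigram with a
    unigram into a trigram; no output token ever spans more than four
    source words.
    """
    model1 = fit_phraser(corpus, min_count=min_count, threshold=threshold)
    pass1 = [apply_phraser(model1, doc) for doc in corpus]
    model2 = fit_phraser(pass1, min_count=min_count, threshold=threshold)
    pass2 = [apply_phraser(model2, doc) for doc in pass1]
    return pass2, (model1, model2)
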