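"""Abstract phrase concepts: fuzzy mention linking, context-averaged
concept vectors, and 2-D projection.

A concept database maps integer IDs to a canonical phrase and its known
surface variants (abstract entities, not ontology-linked).  Mentions in
tokenized documents are linked token-by-token with a restricted
Damerau-Levenshtein allowance that absorbs clinical typing errors
("resusciation" -> "resuscitation"), each concept's vector is the
incremental mean of the mean context-word vectors around its mentions,
and t-SNE projects the concept vectors to two dimensions for
visualisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .textprep import TokenizedDoc, tokenize

__all__ = [
    "damerau_levenshtein",
    "ConceptDatabase",
    "ConceptEmbedding",
    "TsneConfig",
    "Projection2D",
    "build_cdb",
    "link_mentions",
    "tokens_match",
    "train_concept_vectors",
    "conditional_gaussian_probs",
    "joint_probabilities",
    "project_2d",
]


# ---------------------------------------------------------------------------
# edit distance
# ---------------------------------------------------------------------------

def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment)
    distance: insertions, deletions, substitutions and adjacent
    transpositions, no substring edited twice."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1 and j > 1
                and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


#: per-token fuzzy rule: tokens shorter than this must match exactly
#: (prevents "of" -> "or" false hits).
MIN_FUZZY_LEN = 5


@lru_cache(maxsize=1 << 20)
def tokens_match(doc_token: str, query_token: str, max_edits: int = 1) -> bool:
    """True if the document token matches the query token exactly, or —
    for query tokens of length >= 5 — within ``max_edits`` restricted
    Damerau-Levenshtein edits.  Short query tokens ("of") must match
    exactly so that near-misses like "or" never fire."""
    if doc_token == query_token:
        return True
    if max_edits <= 0:
        return False
    if len(query_token) < MIN_FUZZY_LEN:
        return False
    if abs(len(doc_token) - len(query_token)) > max_edits:
        return False
    return damerau_levenshtein(doc_token, query_token) <= max_edits


# ---------------------------------------------------------------------------
# concept database
# ---------------------------------------------------------------------------

@dataclass
class ConceptDatabase:
    """phrase -> ID store; every variant maps to exactly one concept."""

    canonical: dict[int, str] = field(default_factory=dict)        # id -> phrase
    variants: dict[int, list[tuple[str, ...]]] = field(default_factory=dict)
    variant_to_id: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.canonical)

    def label(self, cid: int) -> str:
        return self.canonical[cid]

    def to_json(self, path: str) -> None:
        obj = {
            str(cid): {
                "canonical": self.canonical[cid],
                "variants": [" ".join(v) for v in self.variants[cid]],
            }
            for cid in self.canonical
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ConceptDatabase":
        with open(path) as fh:
            obj = json.load(fh)
        pairs = []
        for cid in sorted(obj, key=int):
            entry = obj[cid]
            extra = [v for v in entry["variants"] if v != entry["canonical"]]
            pairs.append((entry["canonical"], extra))
        return build_cdb(pairs)


def build_cdb(phrases: list[str | tuple[str, list[str]]]) -> ConceptDatabase:
    """Build a concept database from canonical phrases with optional
    variant lists.  Variants are normalized through the tokenizer; the
    canonical phrase is always one of its own variants.  Duplicate
    canonical phrases or a variant shared by two concepts are errors.
    """
    if not phrases:
        raise ValueError("cannot build a concept database from an empty phrase list")
    cdb = ConceptDatabase()
    for cid, item in enumerate(phrases):
        if isinstance(item, str):
            canon, extra = item, []
        else:
            canon, extra = item[0], list(item[1] or [])
        canon_toks = tuple(tokenize(canon))
        if not canon_toks:
            raise ValueError(f"canonical phrase tokenizes to nothing: {canon!r}")
        if any(canon == c for c in cdb.canonical.values()):
            raise ValueError(f"duplicate canonical phrase: {canon!r}")
        cdb.canonical[cid] = canon
        cdb.variants[cid] = []
        for surface in [canon] + extra:
            toks = tuple(tokenize(surface))
            if not toks:
                continue
            owner = cdb.variant_to_id.get(toks)
            if owner is not None and owner != cid:
                raise ValueError(
                    f"variant {surface!r} already belongs to concept "
                    f"{cdb.canonical[owner]!r} (id {owner})"
                )
            if toks not in cdb.variants[cid]:
                cdb.variants[cid].append(toks)
            cdb.variant_to_id[toks] = cid
    return cdb


def link_mentions(doc: TokenizedDoc, cdb: ConceptDatabase,
                  max_edits: int = 1) -> list[tuple[int, tuple[int, int]]]:
    """Find concept mentions in a tokenized document.

    A variant of t tokens matches a window of t consecutive document
    tokens when every aligned token pair satisfies :func:`tokens_match`.
    Per concept, matches are taken leftmost-longest and non-overlapping;
    different concepts may overlap.  Returns ``(concept_id, (start,
    end))`` spans with ``end`` exclusive, sorted by (start, concept_id).
    """
    toks = doc.tokens
    out: list[tuple[int, tuple[int, int]]] = []
    for cid in cdb.canonical:
        variants = sorted(cdb.variants[cid], key=len, reverse=True)
        i = 0
        n = len(toks)
        while i < n:
            matched_end = None
            for var in variants:  # longest first
                t = len(var)
                if i + t > n:
                    continue
                if all(tokens_match(toks[i + j], var[j], max_edits) for j in range(t)):
                    matched_end = i + t
                    break
            if matched_end is not None:
                out.append((cid, (i, matched_end)))
                i = matched_end
            else:
                i += 1
    out.sort(key=lambda m: (m[1][0], m[0]))
    return out


# ---------------------------------------------------------------------------
# concept vectors
# ---------------------------------------------------------------------------

@dataclass
class ConceptEmbedding:
    vectors: dict[int, np.ndarray]   # concept id -> vector
    n_mentions: dict[int, int]
    unembedded: list[int]            # concepts with zero linked mentions


def train_concept_vectors(corpus: list[TokenizedDoc], cdb: ConceptDatabase,
                          word_model, context_window: int = 10,
                          max_edits: int = 1) -> ConceptEmbedding:
    """Incremental-mean concept vectors.

    For every linked mention, the mean of the word vectors within
    ``context_window`` tokens either side (the mention's own tokens
    excluded; out-of-vocabulary context tokens skipped) is folded into
    the concept's running mean.  Concepts with no mention carry no
    vector and are listed in ``unembedded``.
    """
    vectors: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for doc in corpus:
        mentions = link_mentions(doc, cdb, max_edits=max_edits)
        if not mentions:
            continue
        toks = doc.tokens
        for cid, (start, end) in mentions:
            lo = max(0, start - context_window)
            hi = min(len(toks), end + context_window)
            ctx = toks[lo:start] + toks[end:hi]
            vecs = [word_model.vector(t) for t in ctx if t in word_model]
            if not vecs:
                continue
            mean = np.mean(np.asarray(vecs, dtype=np.float64), axis=0)
            c = counts.get(cid, 0)
            if c == 0:
                vectors[cid] = mean
            else:
                vectors[cid] = vectors[cid] + (mean - vectors[cid]) / (c + 1)
            counts[cid] = c + 1
    unembedded = [cid for cid in cdb.canonical if cid not in vectors]
    return ConceptEmbedding(vectors, counts, unembedded)


# ---------------------------------------------------------------------------
# t-SNE (exact)
# ---------------------------------------------------------------------------

@dataclass
class TsneConfig:
    perplexity: float = 5.0
    n_iterations: int = 1000
    rng_seed: int = 0
    early_exaggeration: float = 12.0
    exaggeration_iters: int = 250
    learning_rate: float = 100.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8

    def __post_init__(self) -> None:
        if self.n_iterations < 250:
            raise ValueError("n_iterations must be >= 250")
        if self.perplexity <= 1.0:
            raise ValueError("perplexity must exceed 1")


@dataclass
class Projection2D:
    coords: dict[int, tuple[float, float]]
    kl_divergence: float
    kl_history: list[float] = field(default_factory=list)


def conditional_gaussian_probs(D2: np.ndarray, perplexity: float,
                               tol: float = 1e-7, max_iter: int = 200):
    """Row-conditional Gaussian affinities calibrated by bisection so
    each row's Shannon perplexity matches the target.

    ``D2`` is the squared-distance matrix.  Returns ``(P, betas)`` with
    zero diagonal; each row of P sums to 1.
    """
    n = D2.shape[0]
    P = np.zeros((n, n))
    betas = np.ones(n)
    log_target = np.log(perplexity)
    for i in range(n):
        d = np.delete(D2[i], i)
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        for _ in range(max_iter):
            w = np.exp(-d * beta)
            sw = w.sum()
            if sw <= 0:
                beta = beta_lo + (beta - beta_lo) / 2.0
                continue
            p = w / sw
            # Shannon entropy of the row distribution
            nz = p > 0
            H = -np.sum(p[nz] * np.log(p[nz]))
            diff = H - log_target
            if abs(diff) < tol:
                break
            if diff > 0:  # entropy too high -> sharpen
                beta_lo = beta
                beta = beta * 2.0 if beta_hi == np.inf else (beta + beta_hi) / 2.0
            else:
                beta_hi = beta
                beta = (beta + beta_lo) / 2.0
        row = np.zeros(n)
        row[np.arange(n) != i] = p
        P[i] = row
        betas[i] = beta
    return P, betas


def joint_probabilities(X: np.ndarray, perplexity: float) -> np.ndarray:
    """Symmetrized joint distribution p_ij = (p_j|i + p_i|j) / 2n."""
    D2 = squareform(pdist(X, "sqeuclidean"))
    P, _ = conditional_gaussian_probs(D2, perplexity)
    P = (P + P.T) / (2.0 * X.shape[0])
    return np.maximum(P, 1e-12)


def _q_distribution(Y: np.ndarray):
    D2 = squareform(pdist(Y, "sqeuclidean"))
    W = 1.0 / (1.0 + D2)
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    return np.maximum(Q, 1e-12), W


def project_2d(embeddings: ConceptEmbedding | dict[int, np.ndarray],
               cfg: TsneConfig | None = None) -> Projection2D:
    """Exact t-SNE of the concept vectors to 2-D.

    Standard formulation: Gaussian joint p (perplexity-calibrated by
    bisection), Student-t q, gradient descent with early exaggeration,
    momentum and adaptive per-parameter gains.  Returns coordinates,
    the final KL divergence and the per-iteration KL history (computed
    on the un-exaggerated p throughout, so descent is comparable across
    phases).
    """
    cfg = cfg or TsneConfig()
    vecs = embeddings.vectors if isinstance(embeddings, ConceptEmbedding) else embeddings
    ids = sorted(vecs)
    n = len(ids)
    if n < 3:
        raise ValueError(f"t-SNE needs at least 3 points, got {n}")
    if cfg.perplexity >= n:
        raise ValueError(f"perplexity ({cfg.perplexity}) must be < number of points ({n})")
    X = np.asarray([vecs[i] for i in ids], dtype=np.float64)

    P = joint_probabilities(X, cfg.perplexity)
    rng = np.random.default_rng(cfg.rng_seed)
    Y = rng.normal(scale=1e-4, size=(n, 2))
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)

    kl_history: list[float] = []
    for it in range(cfg.n_iterations):
        exag = cfg.early_exaggeration if it < cfg.exaggeration_iters else 1.0
        momentum = cfg.momentum_early if it < cfg.exaggeration_iters else cfg.momentum_late
        Q, W = _q_distribution(Y)
        PQ = (exag * P - Q) * W
        grad = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
        incr = np.sign(grad) != np.sign(dY)
        gains = np.where(incr, gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        dY = momentum * dY - cfg.learning_rate * gains * grad
        Y = Y + dY
        Y = Y - Y.mean(axis=0)
        kl_history.append(float(np.sum(P * np.log(P / Q))))

    coords = {cid: (float(x), float(y)) for cid, (x, y) in zip(ids, Y)}
    return Projection2D(coords, kl_history[-1], kl_history)


def write_projection_figure(proj: Projection2D, cdb: ConceptDatabase, path: str,
                            group_of: dict[int, str] | None = None) -> None:
    """Scatter plot of the 2-D concept projection, coloured by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    group_of = group_of or {}
    groups = sorted({group_of.get(cid, "") for cid in proj.coords})
    cmap = plt.get_cmap("tab10")
    color = {g: cmap(i % 10) for i, g in enumerate(groups)}
    fig, ax = plt.subplots(figsize=(7, 6))
    for cid, (x, y) in proj.coords.items():
        g = group_of.get(cid, "")
        ax.scatter(x, y, color=color[g], s=24)
        ax.annotate(cdb.label(cid), (x, y), fontsize=6, alpha=0.8,
                    xytext=(2, 2), textcoords="offset points")
    for g in groups:
        if g:
            ax.scatter([], [], color=color[g], label=g)
    if any(groups):
        ax.legend(fontsize=7)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
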