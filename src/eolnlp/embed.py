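"""Word / n-gram embeddings: skip-gram with negative sampling (SGNS).

Trains 300-dimensional embeddings over the phrased corpus with the
configuration window_size=10, n_iterations=2, min_word_frequency=10,
and answers top-k cosine-similarity neighbour queries used for
seed-phrase expansion.

Model
-----
For a centre token c and a context token o drawn from a dynamically
sampled window (uniform half-width in 1..window_size per position), the
pair loss with k negatives n_1..n_k sampled from the unigram^0.75
distribution is

    L = -log sigma(u_c . v_o) - sum_i log sigma(-u_c . v_{n_i})

with input vectors u (reported) and output vectors v (training side).
Training is plain per-pair stochastic gradient descent with the
learning rate decaying linearly over all scheduled pairs; the inner
loop is JIT-compiled (numba) with an explicit integer RNG for negative
sampling, so single-threaded training is bit-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .textprep import SEP, TokenizedDoc, join_tokens

__all__ = [
    "EmbeddingHyperparams",
    "EmbeddingModel",
    "NeighborResult",
    "train_word2vec",
    "cosine_similarity",
    "most_similar",
    "expand_seeds",
    "resolve_seed",
    "sgns_loss_and_grads",
]


@dataclass
class EmbeddingHyperparams:
    dimension: int = 300
    window_size: int = 10
    n_iterations: int = 2
    min_word_frequency: int = 10
    n_negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.min_word_frequency < 1:
            raise ValueError("min_word_frequency must be >= 1")


@dataclass
class EmbeddingModel:
    """Vocabulary plus input/output vector matrices."""

    vocab: dict[str, int]            # token -> row index
    counts: np.ndarray               # corpus frequency per vocab token
    input_vectors: np.ndarray        # (V, d) float32 — similarity side
    output_vectors: np.ndarray       # (V, d) float32 — training side
    hyperparams: EmbeddingHyperparams
    index_to_token: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.index_to_token:
            self.index_to_token = [None] * len(self.vocab)
            for tok, i in self.vocab.items():
                self.index_to_token[i] = tok

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def vector(self, token: str) -> np.ndarray:
        return self.input_vectors[self.vocab[token]]

    def save(self, vocab_path: str, matrix_path: str) -> None:
        """Vocabulary as TSV (token, frequency); matrices as .npz."""
        with open(vocab_path, "w") as fh:
            for i, tok in enumerate(self.index_to_token):
                fh.write(f"{tok}\t{int(self.counts[i])}\n")
        np.savez(matrix_path, input_vectors=self.input_vectors,
                 output_vectors=self.output_vectors)


@dataclass
class NeighborResult:
    query: str
    neighbors: list[tuple[str, float]]  # sorted by cosine similarity, descending


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _build_vocab(corpus: list[TokenizedDoc], min_count: int):
    counts: dict[str, int] = {}
    for doc in corpus:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = [(tok, c) for tok, c in counts.items() if c >= min_count]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))  # frequency desc, token asc: stable ids
    vocab = {tok: i for i, (tok, _) in enumerate(kept)}
    freq = np.array([c for _, c in kept], dtype=np.int64)
    return vocab, freq


def _training_pairs(doc_ids: list[np.ndarray], window: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(centre, context) index pairs for one epoch, dynamic window."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for ids in doc_ids:
        L = len(ids)
        if L < 2:
            continue
        b = rng.integers(1, window + 1, size=L)
        for i in range(L):
            lo = max(0, i - int(b[i]))
            hi = min(L, i + int(b[i]) + 1)
            span = hi - lo - 1
            if span <= 0:
                continue
            ctx = np.concatenate([ids[lo:i], ids[i + 1:hi]])
            centers.append(np.full(span, ids[i], dtype=np.int32))
            contexts.append(ctx)
    if not centers:
        return (np.empty(0, dtype=np.int32),) * 2
    return np.concatenate(centers), np.concatenate(contexts).astype(np.int32)


def train_word2vec(corpus: list[TokenizedDoc],
                   hp: EmbeddingHyperparams | None = None) -> EmbeddingModel:
    """Train SGNS embeddings over a tokenized (phrased) corpus.

    Deterministic for a fixed seed (single-threaded numpy).  Raises if
    the vocabulary is empty after the minimum-frequency filter.
    """
    hp = hp or EmbeddingHyperparams()
    vocab, freq = _build_vocab(corpus, hp.min_word_frequency)
    if not vocab:
        raise ValueError(
            f"vocabulary is empty after the min_word_frequency={hp.min_word_frequency} filter"
        )
    V, d = len(vocab), hp.dimension
    rng = np.random.default_rng(hp.rng_seed)

    W_in = ((rng.random((V, d), dtype=np.float32) - 0.5) / d).astype(np.float32)
    W_out = np.zeros((V, d), dtype=np.float32)

    # negative-sampling distribution: unigram^0.75
    noise = freq.astype(np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    # map docs to in-vocab index arrays once (OOV tokens are dropped and
    # the window then operates on the surviving sequence)
    doc_ids = []
    for doc in corpus:
        ids = [vocab[t] for t in doc.tokens if t in vocab]
        if len(ids) >= 2:
            doc_ids.append(np.asarray(ids, dtype=np.int32))

    # schedule: pairs are regenerated per epoch (fresh dynamic windows)
    epochs = [
        _training_pairs(doc_ids, hp.window_size, rng) for _ in range(hp.n_iterations)
    ]
    total_pairs = sum(len(c) for c, _ in epochs)
    if total_pairs == 0:
        return EmbeddingModel(vocab, freq, W_in, W_out, hp)

    rng_state = np.array([rng.integers(1, 2**63 - 1)], dtype=np.uint64)
    seen = 0
    for centers, contexts in epochs:
        _sgd_epoch(
            W_in, W_out, centers, contexts, noise_cdf,
            np.int64(hp.n_negative),
            np.float64(hp.learning_rate), np.float64(hp.min_learning_rate),
            np.int64(seen), np.int64(total_pairs), rng_state,
        )
        seen += len(centers)
    return EmbeddingModel(vocab, freq, W_in, W_out, hp)


@njit(cache=True)
def _xorshift(state: np.uint64) -> np.uint64:
    # xorshift64*: fast deterministic stream for negative sampling
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state


@njit(cache=True)
def _sgd_epoch(W_in, W_out, centers, contexts, noise_cdf, n_negative,
               lr0, lr_min, seen0, total_pairs, rng_state_arr):
    """Per-pair SGNS SGD over one epoch's (centre, context) stream."""
    d = W_in.shape[1]
    mult = np.uint64(0x2545F4914F6CDD1D)
    inv64 = 1.0 / 18446744073709551616.0  # 2**-64
    rng_state = rng_state_arr[0]
    for t in range(centers.shape[0]):
        frac = (seen0 + t) / total_pairs
        lr = lr0 + (lr_min - lr0) * frac
        c = centers[t]
        u = W_in[c]
        grad_u = np.zeros(d, dtype=np.float32)
        for s in range(n_negative + 1):
            if s == 0:
                tgt = contexts[t]
                label = 1.0
            else:
                rng_state = _xorshift(rng_state)
                r = float(rng_state * mult) * inv64
                tgt = np.searchsorted(noise_cdf, r)
                label = 0.0
            v = W_out[tgt]
            dot = 0.0
            for j in range(d):
                dot += u[j] * v[j]
            if dot > 8.0:
                sig = 1.0
            elif dot < -8.0:
                sig = 0.0
            else:
                sig = 1.0 / (1.0 + np.exp(-dot))
            g = np.float32((sig - label) * lr)
            for j in range(d):
                grad_u[j] += g * v[j]
                W_out[tgt, j] -= g * u[j]
        for j in range(d):
            W_in[c, j] -= grad_u[j]
    rng_state_arr[0] = rng_state


def sgns_loss_and_grads(u: np.ndarray, v_pos: np.ndarray, v_negs: np.ndarray):
    """Loss and analytic gradients for one (centre, context, negatives)
    triple, in float64 — the unit against which the finite-difference
    oracle is checked.

    Returns ``(loss, grad_u, grad_v_pos, grad_v_negs)``.
    """
    u = np.asarray(u, dtype=np.float64)
    v_pos = np.asarray(v_pos, dtype=np.float64)
    v_negs = np.asarray(v_negs, dtype=np.float64)

    def sigma(x):
        return 1.0 / (1.0 + np.exp(-x))

    s_pos = sigma(u @ v_pos)
    s_negs = sigma(v_negs @ u)
    loss = -np.log(s_pos) - np.sum(np.log(1.0 - s_negs))
    grad_u = (s_pos - 1.0) * v_pos + s_negs @ v_negs
    grad_v_pos = (s_pos - 1.0) * u
    grad_v_negs = s_negs[:, None] * u[None, :]
    return loss, grad_u, grad_v_pos, grad_v_negs


# ---------------------------------------------------------------------------
# similarity queries
# ---------------------------------------------------------------------------

def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); raises on a zero vector."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def most_similar(model: EmbeddingModel, query: str, k: int = 10) -> NeighborResult:
    """Exact top-k neighbours by cosine over the input vectors.

    The query itself is excluded; ties are broken by vocabulary index
    ascending (stable sort).
    """
    if query not in model.vocab:
        raise KeyError(f"token not in vocabulary: {query!r}")
    if k <= 0:
        return NeighborResult(query, [])
    qi = model.vocab[query]
    W = model.input_vectors.astype(np.float64)
    norms = np.linalg.norm(W, axis=1)
    norms[norms == 0.0] = 1.0
    sims = (W @ (W[qi] / max(norms[qi], 1e-300))) / norms
    sims[qi] = -np.inf
    order = np.argsort(-sims, kind="stable")[:k]
    return NeighborResult(query, [(model.index_to_token[i], float(sims[i])) for i in order])


def resolve_seed(seed: str, model: EmbeddingModel, phrasers=None) -> str | None:
    """Resolve a (possibly multi-word) seed phrase to a vocabulary token.

    Tries the underscore-joined form first; otherwise runs the seed's
    word tokens through the fitted phraser passes and accepts the
    result if it collapses to a single in-vocabulary token.
    """
    from .textprep import apply_phraser, tokenize

    words = tokenize(seed)
    if not words:
        return None
    joined = join_tokens(words)
    if joined in model.vocab:
        return joined
    if len(words) == 1:
        return None
    if phrasers:
        doc = TokenizedDoc("_seed", words)
        for ph in phrasers:
            doc = apply_phraser(ph, doc)
        if len(doc.tokens) == 1 and doc.tokens[0] in model.vocab:
            return doc.tokens[0]
    return None


@dataclass
class SeedExpansion:
    per_seed: dict[str, NeighborResult]        # resolved seed -> neighbours
    union: list[str]                           # first-retrieval order, deduplicated
    provenance: dict[str, list[str]]           # neighbour -> seeds that retrieved it
    unresolved: list[str]                      # seeds that could not be mapped


def expand_seeds(model: EmbeddingModel, seeds: list[str], k: int = 10,
                 phrasers=None) -> SeedExpansion:
    """Collect and consolidate the top-k neighbours of each seed phrase.

    Unresolvable seeds are reported, not fatal — unless every seed is
    unresolvable.
    """
    per_seed: dict[str, NeighborResult] = {}
    union: list[str] = []
    prov: dict[str, list[str]] = {}
    unresolved: list[str] = []
    for seed in seeds:
        tok = resolve_seed(seed, model, phrasers)
        if tok is None:
            unresolved.append(seed)
            continue
        res = most_similar(model, tok, k)
        per_seed[seed] = res
        for ng, _ in res.neighbors:
            if ng not in prov:
                prov[ng] = [seed]
                union.append(ng)
            elif seed not in prov[ng]:
                prov[ng].append(seed)
    if not per_seed:
        raise ValueError(f"no seed could be resolved to the vocabulary: {seeds}")
    return SeedExpansion(per_seed, union, prov, unresolved)
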