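"""Concept database, fuzzy linking, concept vectors and t-SNE."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eolnlp.concepts import (ConceptDatabase, TsneConfig, build_cdb,
                             conditional_gaussian_probs, damerau_levenshtein,
                             joint_probabilities, link_mentions, project_2d,
                             tokens_match, train_concept_vectors, _q_distribution)
from eolnlp.embed import EmbeddingHyperparams, EmbeddingModel
from eolnlp.textprep import TokenizedDoc


# -- edit distance ----------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,d",
    [
        ("resusciation", "resuscitation", 1),   # deletion
        ("celiing", "ceiling", 1),              # adjacent transposition
        ("of", "or", 1),                        # substitution
        ("ceiling", "ceiling", 0),
        ("", "abc", 3),
        ("abc", "", 3),
        ("ca", "abc", 3),                       # OSA: no double edit of a substring
        ("kitten", "sitting", 3),
    ],
)
def test_damerau_levenshtein_known_values(a, b, d):
    assert damerau_levenshtein(a, b) == d


@given(st.text(alphabet="abcd", max_size=6), st.text(alphabet="abcd", max_size=6))
def test_damerau_levenshtein_symmetric_and_bounded(a, b):
    d = damerau_levenshtein(a, b)
    assert d == damerau_levenshtein(b, a)
    assert abs(len(a) - len(b)) <= d <= max(len(a), len(b))
    assert (d == 0) == (a == b)


def test_tokens_match_short_tokens_exact_only():
    assert tokens_match("of", "of")
    assert not tokens_match("or", "of")          # would be 1 edit but too short
    assert tokens_match("resusciation", "resuscitation")
    assert not tokens_match("resuscitatixx", "resuscitation")


# -- concept database -------------------------------------------------------

def test_build_cdb_variants_linked():
    cdb = build_cdb([("end of life care", ["eol care", "eolc"])])
    assert len(cdb) == 1
    assert len(cdb.variants[0]) == 3
    assert cdb.variant_to_id[("eolc",)] == 0


def test_build_cdb_errors():
    with pytest.raises(ValueError):
        build_cdb([])
    with pytest.raises(ValueError):
        build_cdb(["ceiling of care", "ceiling of care"])
    with pytest.raises(ValueError, match="eol care"):
        build_cdb([("end of life care", ["eol care"]),
                   ("terminal care", ["eol care"])])


def test_cdb_json_roundtrip(tmp_path):
    cdb = build_cdb([("ceiling of care", ["ceiling of rx"]), "terminal care"])
    path = tmp_path / "cdb.json"
    cdb.to_json(str(path))
    back = ConceptDatabase.from_json(str(path))
    assert back.canonical == cdb.canonical
    assert back.variants == cdb.variants


# -- linking ----------------------------------------------------------------

def test_link_typo_variant():
    cdb = build_cdb(["resuscitation discussed"])
    doc = TokenizedDoc("d", ["the", "resusciation", "discussed", "today"])
    assert link_mentions(doc, cdb, max_edits=1) == [(0, (1, 3))]


def test_link_exact_mention_zero_edits():
    cdb = build_cdb(["ceiling of care"])
    doc = TokenizedDoc("d", ["agreed", "ceiling", "of", "care", "today"])
    assert link_mentions(doc, cdb) == [(0, (1, 4))]


def test_link_leftmost_longest_nonoverlapping():
    cdb = build_cdb([("end of life care", ["end of life"])])
    doc = TokenizedDoc("d", ["end", "of", "life", "care", "end", "of", "life"])
    assert link_mentions(doc, cdb) == [(0, (0, 4)), (0, (4, 7))]


def _oracle_link(doc, cdb, max_edits):
    """All-windows scan + leftmost-longest selection, written directly
    from the matching rule."""
    out = []
    for cid in cdb.canonical:
        wins = []
        for var in cdb.variants[cid]:
            t = len(var)
            for s in range(len(doc.tokens) - t + 1):
                if all(tokens_match(doc.tokens[s + j], var[j], max_edits)
                       for j in range(t)):
                    wins.append((s, s + t))
        chosen, cursor = [], 0
        for s, e in sorted(wins, key=lambda w: (w[0], -(w[1] - w[0]))):
            if s >= cursor:
                chosen.append((cid, (s, e)))
                cursor = e
        out.extend(chosen)
    return sorted(out, key=lambda m: (m[1][0], m[0]))


def test_linker_equals_all_windows_oracle(rng):
    words = ["alpha", "beta", "gamma", "delta", "epsilonn", "zeta", "etaa",
             "of", "in", "on"]
    cdb = build_cdb(["alpha beta", ("gamma delta of", ["gamma delta"]),
                     "epsilonn zeta", "etaa of beta", "delta on"])
    for _ in range(30):
        doc = TokenizedDoc("d", [words[i] for i in rng.integers(0, len(words), 10)])
        assert link_mentions(doc, cdb, 1) == _oracle_link(doc, cdb, 1)


# -- concept vectors --------------------------------------------------------

def _word_model(vectors):
    vocab = {t: i for i, t in enumerate(vectors)}
    W = np.asarray(list(vectors.values()), dtype=np.float32)
    return EmbeddingModel(vocab, np.full(len(vocab), 50), W, W.copy(),
                          EmbeddingHyperparams(dimension=W.shape[1]))


def test_single_mention_single_context_word():
    wm = _word_model({"w": [1.0, 2.0, 3.0], "other": [9.0, 9.0, 9.0]})
    cdb = build_cdb(["target phrase"])
    corpus = [TokenizedDoc("d", ["w", "target", "phrase"])]
    ce = train_concept_vectors(corpus, cdb, wm, context_window=5)
    assert ce.n_mentions[0] == 1
    np.testing.assert_allclose(ce.vectors[0], [1.0, 2.0, 3.0])


def test_unmentioned_concept_reported():
    wm = _word_model({"w": [1.0, 0.0]})
    cdb = build_cdb(["present phrase", "absent phrase"])
    corpus = [TokenizedDoc("d", ["w", "present", "phrase"])]
    ce = train_concept_vectors(corpus, cdb, wm, context_window=5)
    assert 0 in ce.vectors
    assert ce.unembedded == [1]


def test_mention_tokens_excluded_from_context():
    wm = _word_model({"w": [2.0, 0.0], "target": [100.0, 100.0],
                      "phrase": [100.0, 100.0]})
    cdb = build_cdb(["target phrase"])
    corpus = [TokenizedDoc("d", ["w", "target", "phrase"])]
    ce = train_concept_vectors(corpus, cdb, wm, context_window=3)
    np.testing.assert_allclose(ce.vectors[0], [2.0, 0.0])


def test_shared_template_concepts_cluster(rng):
    # concepts A and B live in identical contexts, C in disjoint ones
    wm = _word_model({f"x{i}": np.eye(6)[i % 3] for i in range(3)}
                     | {f"y{i}": np.eye(6)[3 + i % 3] for i in range(3)})
    cdb = build_cdb(["aa bb", "cc dd", "ee ff"])
    corpus = []
    for i in range(60):
        x = f"x{rng.integers(0, 3)}"
        y = f"y{rng.integers(0, 3)}"
        corpus.append(TokenizedDoc(str(i), [x, "aa", "bb", x]))
        corpus.append(TokenizedDoc(str(i) + "b", [x, "cc", "dd", x]))
        corpus.append(TokenizedDoc(str(i) + "c", [y, "ee", "ff", y]))
    ce = train_concept_vectors(corpus, cdb, wm, context_window=4)
    from eolnlp.embed import cosine_similarity
    assert cosine_similarity(ce.vectors[0], ce.vectors[1]) > \
        cosine_similarity(ce.vectors[0], ce.vectors[2])


# -- t-SNE ------------------------------------------------------------------

def test_joint_probabilities_normalized(rng):
    X = rng.normal(size=(12, 5))
    P = joint_probabilities(X, perplexity=4.0)
    assert P.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(P, P.T)
    Q, _ = _q_distribution(rng.normal(size=(12, 2)))
    assert Q.sum() == pytest.approx(1.0, abs=1e-9)


def test_perplexity_calibration(rng):
    X = rng.normal(size=(20, 6))
    from scipy.spatial.distance import pdist, squareform
    D2 = squareform(pdist(X, "sqeuclidean"))
    target = 6.0
    P, _ = conditional_gaussian_probs(D2, target)
    for i in range(20):
        p = P[i][P[i] > 0]
        perp = np.exp(-np.sum(p * np.log(p)))
        assert perp == pytest.approx(target, abs=1e-3)


def test_equidistant_points_stay_equidistant():
    X = {0: np.array([1.0, 0.0, 0.0]), 1: np.array([0.0, 1.0, 0.0]),
         2: np.array([0.0, 0.0, 1.0])}
    proj = project_2d(X, TsneConfig(perplexity=1.5, n_iterations=500, rng_seed=0))
    pts = np.array([proj.coords[i] for i in range(3)])
    d = [np.linalg.norm(pts[i] - pts[j]) for i, j in itertools.combinations(range(3), 2)]
    assert max(d) / min(d) < 1.05


def test_kl_descends_after_exaggeration(rng):
    X = {i: v for i, v in enumerate(rng.normal(size=(15, 8)))}
    cfg = TsneConfig(perplexity=4.0, n_iterations=600, rng_seed=1)
    proj = project_2d(X, cfg)
    assert proj.kl_divergence >= 0
    assert proj.kl_divergence <= proj.kl_history[cfg.exaggeration_iters]


def test_tsne_input_validation(rng):
    X2 = {i: v for i, v in enumerate(rng.normal(size=(2, 4)))}
    with pytest.raises(ValueError):
        project_2d(X2, TsneConfig(perplexity=1.5))
    X5 = {i: v for i, v in enumerate(rng.normal(size=(5, 4)))}
    with pytest.raises(ValueError):
        project_2d(X5, TsneConfig(perplexity=5.0))
    with pytest.raises(ValueError):
        TsneConfig(n_iterations=100)


def test_projection_figure_written(tmp_path, rng):
    from eolnlp.concepts import write_projection_figure
    cdb = build_cdb(["alpha one", "beta two", "gamma three", "delta four"])
    X = {i: v for i, v in enumerate(rng.normal(size=(4, 5)))}
    proj = project_2d(X, TsneConfig(perplexity=1.5, n_iterations=250))
    out = tmp_path / "proj.png"
    write_projection_figure(proj, cdb, str(out), {0: "g1", 1: "g1", 2: "g2", 3: "g2"})
    assert out.stat().st_size > 0
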