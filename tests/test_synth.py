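"""Synthetic corpus generator: determinism, planting, typos, deaths."""

from dataclasses import replace
from datetime import timedelta

import numpy as np
import pytest
from scipy import stats

from eolnlp.synth import (CorpusConfig, corrupt_token, default_config,
                          default_groups, embedding_config, generate_corpus,
                          inject_typos)


def _small_config(**kw):
    defaults = dict(n_patients=500, rng_seed=3)
    defaults.update(kw)
    return default_config(**defaults)


def test_zero_patients_empty_corpus():
    docs, patients, log = generate_corpus(_small_config(n_patients=0))
    assert docs == [] and patients == [] and log.entries == []


def test_determinism_byte_identical():
    a = generate_corpus(_small_config())
    b = generate_corpus(_small_config())
    assert [(d.doc_id, d.patient_id, d.doc_date, d.text) for d in a[0]] == \
           [(d.doc_id, d.patient_id, d.doc_date, d.text) for d in b[0]]
    assert [(p.patient_id, p.death_date) for p in a[1]] == \
           [(p.patient_id, p.death_date) for p in b[1]]
    assert a[2].entries == b[2].entries


def test_different_seed_differs():
    a = generate_corpus(_small_config(rng_seed=1))
    b = generate_corpus(_small_config(rng_seed=2))
    assert [d.text for d in a[0]] != [d.text for d in b[0]]


def test_no_typos_means_verbatim_phrases():
    docs, _, log = generate_corpus(_small_config(typo_rate=0.0))
    by_id = {d.doc_id: d for d in docs}
    assert log.entries
    for e in log.entries:
        assert e.surface == e.phrase
        assert e.phrase in by_id[e.doc_id].text


def test_logged_surface_always_present_in_document():
    docs, _, log = generate_corpus(_small_config(typo_rate=0.05))
    by_id = {d.doc_id: d for d in docs}
    for e in log.entries:
        assert e.surface in by_id[e.doc_id].text


def test_background_documents_clean_of_phrases():
    docs, _, log = generate_corpus(_small_config(typo_rate=0.0))
    planted_docs = {e.doc_id for e in log.entries}
    phrases = [p for g in default_groups() for p in g.phrases]
    for d in docs:
        if d.doc_id not in planted_docs:
            for p in phrases:
                assert p not in d.text


def test_doc_dates_inside_range_and_death_after_first_doc():
    cfg = _small_config()
    docs, patients, _ = generate_corpus(cfg)
    first_doc = {}
    for d in docs:
        assert cfg.date_start <= d.doc_date <= cfg.date_end
        assert d.text
        cur = first_doc.get(d.patient_id)
        first_doc[d.patient_id] = d.doc_date if cur is None else min(cur, d.doc_date)
    for p in patients:
        if p.death_date is not None:
            assert p.death_date >= first_doc[p.patient_id]


# -- typo injection ---------------------------------------------------------

def test_resusciation_reachable_by_single_deletion():
    surfaces = {
        corrupt_token("resuscitation", np.random.default_rng(s), op="delete")
        for s in range(300)
    }
    assert "resusciation" in surfaces


def test_typo_preserves_token_count_and_edges():
    rng = np.random.default_rng(7)
    text = "the resuscitation discussion happened yesterday evening"
    n = len(text.split())
    for _ in range(50):
        out = inject_typos(text, 0.8, rng)
        toks = out.split(" ")
        assert len(toks) == n
        for orig, new in zip(text.split(), toks):
            if len(orig) >= 5:
                assert new[0] == orig[0] and new[-1] == orig[-1]
            else:
                assert new == orig


def test_zero_rate_is_identity():
    rng = np.random.default_rng(0)
    text = "some clinical narrative text"
    assert inject_typos(text, 0.0, rng) == text


def test_corruption_rate_within_binomial_interval():
    # 10 000 eligible tokens at rate 0.05; exact binomial 99% interval
    rng = np.random.default_rng(11)
    tokens = ["flexor"] * 10_000
    out = inject_typos(" ".join(tokens), 0.05, rng).split(" ")
    changed = sum(1 for t in out if t != "flexor")
    lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.05)
    # substitution is a no-op with probability 1/26: widen the lower edge
    assert lo * (1 - 1 / 26) <= changed <= hi


# -- death-date assignment --------------------------------------------------

def _window_death_exists(docs_of, patient):
    if patient.death_date is None:
        return False
    return any(0 <= (patient.death_date - d).days <= 7 for d in docs_of[patient.patient_id])


def _docs_by_patient(docs):
    out = {}
    for d in docs:
        out.setdefault(d.patient_id, []).append(d.doc_date)
    return out


def test_zero_mortality_everywhere_no_window_deaths():
    groups = [replace(g, mortality_7d=0.0) for g in default_groups()]
    cfg = _small_config(background_mortality_7d=0.0, groups=groups)
    docs, patients, _ = generate_corpus(cfg)
    docs_of = _docs_by_patient(docs)
    assert not any(_window_death_exists(docs_of, p) for p in patients)


def test_certain_mortality_group_always_dies_near_phrase_doc():
    groups = [replace(default_groups()[0], mortality_7d=1.0,
                      planting_probability=0.2)]
    cfg = _small_config(groups=groups, background_mortality_7d=0.0)
    docs, patients, log = generate_corpus(cfg)
    by_id = {d.doc_id: d for d in docs}
    death = {p.patient_id: p.death_date for p in patients}
    planted = {}
    for e in log.entries:
        planted.setdefault(e.patient_id, []).append(by_id[e.doc_id].doc_date)
    assert planted
    for pid, dates in planted.items():
        assert death[pid] is not None
        assert any(0 <= (death[pid] - dd).days <= 7 for dd in dates)


def test_group_mortality_within_binomial_interval():
    group = replace(default_groups()[0], mortality_7d=0.576,
                    planting_probability=0.8)
    cfg = default_config(n_patients=2000, rng_seed=5, groups=[group],
                         background_mortality_7d=0.0, late_death_fraction=0.0)
    docs, patients, log = generate_corpus(cfg)
    by_id = {d.doc_id: d for d in docs}
    death = {p.patient_id: p.death_date for p in patients}
    planted = {}
    for e in log.entries:
        planted.setdefault(e.patient_id, []).append(by_id[e.doc_id].doc_date)
    n = len(planted)
    d = sum(
        1 for pid, dates in planted.items()
        if death[pid] is not None
        and any(0 <= (death[pid] - dd).days <= 7 for dd in dates)
    )
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.576)
    assert lo <= d <= hi


def test_background_mortality_within_binomial_interval():
    cfg = default_config(n_patients=50_000, rng_seed=9, groups=[],
                         background_mortality_7d=0.008, late_death_fraction=0.0)
    docs, patients, _ = generate_corpus(cfg)
    docs_of = _docs_by_patient(docs)
    d = sum(1 for p in patients if _window_death_exists(docs_of, p))
    lo, hi = stats.binom.ppf([0.005, 0.995], 50_000, 0.008)
    assert lo <= d <= hi


def test_late_deaths_outside_window():
    cfg = _small_config(background_mortality_7d=0.0, late_death_fraction=1.0,
                        groups=[])
    docs, patients, _ = generate_corpus(cfg)
    docs_of = _docs_by_patient(docs)
    died = [p for p in patients if p.death_date is not None]
    assert died
    for p in died:
        last = max(docs_of[p.patient_id])
        assert (p.death_date - last).days >= 30


def test_config_validation():
    with pytest.raises(ValueError):
        CorpusConfig(n_patients=-1)
    with pytest.raises(ValueError):
        default_config(background_mortality_7d=1.5)
    with pytest.raises(ValueError):
        replace(default_groups()[0], phrases=["single"])


def test_embedding_config_raises_planting():
    cfg = embedding_config(n_patients=100)
    assert all(g.planting_probability == 0.15 for g in cfg.groups)
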