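"""End-to-end pipeline: generate -> tokenize/phrase -> embed -> expand
seeds -> query -> associate -> project.

Each stage reads and writes declared plain-text artefacts (JSONL
corpus, CSV tables, JSON models) inside one output directory and
appends a manifest entry (stage, input hashes, seed, package version),
so any stage can be re-run from its inputs and a fixed config + seed
reproduces every artefact byte for byte in single-threaded mode.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import date
from importlib import resources

import yaml

from . import __version__
from .cohort import CorpusIndex, load_queries_yaml, run_query, control_cohort
from .concepts import TsneConfig, build_cdb, project_2d, train_concept_vectors
from .embed import EmbeddingHyperparams, expand_seeds, train_word2vec
from .outcomes import (AssociationTable, build_association_table,
                       table_from_counts, write_association_csv,
                       write_association_markdown)
from .synth import (CorpusConfig, read_corpus_jsonl, read_patients_csv,
                    write_corpus_jsonl, write_patients_csv, write_plant_log_csv,
                    generate_corpus)
from .textprep import TokenizedDoc, build_ngrams, display_form, tokenize

__all__ = [
    "PipelineConfig",
    "DEFAULT_SEED_PHRASES",
    "run_pipeline",
    "load_counts_csv",
    "table_only",
    "default_queries_path",
    "reference_counts_path",
]

log = logging.getLogger("eolnlp")

#: the a-priori seed phrases used for neighbour expansion.
DEFAULT_SEED_PHRASES = [
    "ceiling of care",
    "withdrawal of care",
    "limit of care",
    "palliative treatments only",
    "palliative care only",
    "end of life care",
    "liverpool care pathway",
    "not for intubation",
    "not for itu",
    "not for critical care",
]


def default_queries_path() -> str:
    return str(resources.files("eolnlp.data") / "synthetic_queries.yaml")


def reference_counts_path() -> str:
    return str(resources.files("eolnlp.data") / "reference_counts.csv")


@dataclass
class PipelineConfig:
    out_dir: str = "eolnlp_out"
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    corpus_path: str | None = None       # pre-existing corpus JSONL (skips generate)
    patients_path: str | None = None
    hyperparams: EmbeddingHyperparams = field(default_factory=EmbeddingHyperparams)
    seed_phrases: list[str] = field(default_factory=lambda: list(DEFAULT_SEED_PHRASES))
    k_neighbors: int = 10
    query_file: str = field(default_factory=default_queries_path)
    window_days: int = 7
    tsne: TsneConfig = field(default_factory=TsneConfig)
    phrase_min_count: int = 10
    phrase_threshold: float = 20.0
    concept_context_window: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        # one global seed drives every stage unless overridden explicitly
        self.corpus.rng_seed = self.rng_seed
        self.hyperparams.rng_seed = self.rng_seed
        self.tsne.rng_seed = self.rng_seed


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: str, seed: int):
        self.path = os.path.join(out_dir, "manifest.json")
        self.entries: list[dict] = []
        self.seed = seed

    def record(self, stage: str, inputs: list[str], outputs: list[str]) -> None:
        self.entries.append({
            "stage": stage,
            "seed": self.seed,
            "version": __version__,
            "inputs": {os.path.basename(p): _sha256(p) for p in inputs},
            "outputs": [os.path.basename(p) for p in outputs],
        })
        with open(self.path, "w") as fh:
            json.dump(self.entries, fh, indent=1)


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute all stages in order; returns the artefact manifest
    (name -> path).  Any stage failure raises with the stage name."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = _Manifest(cfg.out_dir, cfg.rng_seed)
    art: dict[str, str] = {}

    def path(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    stage = "generate"
    try:
        if cfg.corpus_path:
            documents = read_corpus_jsonl(cfg.corpus_path)
            patients = read_patients_csv(cfg.patients_path)
            plant_log = None
            art["corpus"] = cfg.corpus_path
            art["patients"] = cfg.patients_path
        else:
            log.info("generating synthetic corpus (%d patients)", cfg.corpus.n_patients)
            documents, patients, plant_log = generate_corpus(cfg.corpus)
            write_corpus_jsonl(documents, path("corpus.jsonl"))
            write_patients_csv(patients, path("patients.csv"))
            write_plant_log_csv(plant_log, path("plant_log.csv"))
            art["corpus"] = path("corpus.jsonl")
            art["patients"] = path("patients.csv")
            art["plant_log"] = path("plant_log.csv")
            manifest.record(stage, [], [art["corpus"], art["patients"]])

        stage = "phrase"
        log.info("tokenizing and phrasing %d documents", len(documents))
        tokenized = [TokenizedDoc(d.doc_id, tokenize(d.text)) for d in documents]
        phrased, phrasers = build_ngrams(tokenized, cfg.phrase_min_count,
                                         cfg.phrase_threshold)
        phrasers[0].to_json(path("phraser_pass1.json"))
        phrasers[1].to_json(path("phraser_pass2.json"))
        art["phraser_pass1"] = path("phraser_pass1.json")
        art["phraser_pass2"] = path("phraser_pass2.json")
        manifest.record(stage, [art["corpus"]],
                        [art["phraser_pass1"], art["phraser_pass2"]])

        stage = "embed"
        log.info("training SGNS embeddings")
        model = train_word2vec(phrased, cfg.hyperparams)
        model.save(path("vocabulary.tsv"), path("vectors.npz"))
        art["vocabulary"] = path("vocabulary.tsv")
        manifest.record(stage, [art["corpus"]], [art["vocabulary"]])

        stage = "neighbors"
        expansion = expand_seeds(model, cfg.seed_phrases, cfg.k_neighbors,
                                 phrasers=phrasers)
        with open(path("neighbors.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["seed", "rank", "ngram", "cosine"])
            for seed, res in expansion.per_seed.items():
                for rank, (ng, sim) in enumerate(res.neighbors, 1):
                    w.writerow([seed, rank, display_form(ng), f"{sim:.6f}"])
        art["neighbors"] = path("neighbors.csv")
        manifest.record(stage, [art["vocabulary"]], [art["neighbors"]])

        stage = "query"
        queries = load_queries_yaml(cfg.query_file)
        index = CorpusIndex(documents)
        results = [run_query(index, patients, q) for q in queries]
        control_ids = control_cohort(index, patients, queries, results)
        with open(path("cohorts.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["group_label", "n_patients", "n_docs"])
            for r in results:
                w.writerow([r.group_label, len(r.matched_patient_ids),
                            len(r.matched_doc_ids)])
            w.writerow(["control", len(control_ids), ""])
        art["cohorts"] = path("cohorts.csv")
        manifest.record(stage, [art["corpus"], cfg.query_file], [art["cohorts"]])

        stage = "associate"
        table = build_association_table(
            results, control_ids, patients, index, cfg.window_days,
            date_start=queries[0].date_start, date_end=queries[0].date_end,
        )
        write_association_csv(table, path("association.csv"))
        write_association_markdown(table, path("association.md"))
        art["association"] = path("association.csv")
        manifest.record(stage, [art["cohorts"], art["patients"]],
                        [art["association"]])

        stage = "project"
        phrase_lists = [display_form(p) for q in queries for t in q.or_groups
                        for p in [" ".join(t.tokens)]]
        cdb = build_cdb(phrase_lists)
        label_of = {}
        i = 0
        for q in queries:
            for _ in q.or_groups:
                label_of[i] = q.group_label
                i += 1
        concept_vecs = train_concept_vectors(tokenized, cdb, model,
                                             cfg.concept_context_window)
        if len(concept_vecs.vectors) >= 3:
            proj = project_2d(concept_vecs, cfg.tsne)
            with open(path("projection.csv"), "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["concept_id", "label", "x", "y", "group_label"])
                for cid, (x, y) in proj.coords.items():
                    w.writerow([cid, cdb.label(cid), f"{x:.6f}", f"{y:.6f}",
                                label_of.get(cid, "")])
            art["projection"] = path("projection.csv")
            manifest.record(stage, [art["vocabulary"]], [art["projection"]])
        else:
            log.warning("fewer than 3 embedded concepts; skipping projection")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    art["manifest"] = manifest.path
    return art


# ---------------------------------------------------------------------------
# table-only path: published counts in, printed % and RR out
# ---------------------------------------------------------------------------

def load_counts_csv(path: str):
    """Read (label, n, deaths) rows; a blank deaths cell marks a
    source-suppressed count.  The row labelled 'control' (or in the
    'control' cluster) is the control."""
    rows: list[tuple[str, int, int | None]] = []
    control = None
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            label = rec["label"]
            n = int(rec["n_patients"])
            d_raw = rec["n_deaths_7d"].strip()
            d = int(d_raw) if d_raw else None
            if rec.get("cluster", "").strip() == "control" or label == "control":
                control = (label, n, d)
            else:
                rows.append((label, n, d))
    if control is None or control[2] is None:
        raise ValueError("counts file must contain a control row with explicit deaths")
    return rows, control


def table_only(counts_path: str | None = None) -> AssociationTable:
    """Association table straight from aggregate counts (no corpus)."""
    rows, control = load_counts_csv(counts_path or reference_counts_path())
    return table_from_counts(rows, control)
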