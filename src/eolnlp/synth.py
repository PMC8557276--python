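"""Synthetic EHR corpus generator.

Emulates the statistical structure of a hospital free-text corpus for a
12-month inpatient cohort: many short clinical documents per patient,
rare multi-word end-of-life phrases planted inside group-specific
sentence templates (so that phrases of one meaning group share context
words and their embeddings cluster), per-token typographical corruption
("resuscitation" -> "resusciation"), and group-conditional 7-day
mortality with a large low-mortality background (0.8% control rate).

A plant log records exactly which phrase was planted where (and its
possibly typo-corrupted surface form), providing ground truth for
parameter-recovery tests.

Everything is driven by a single seeded :class:`numpy.random.Generator`
so a fixed config + seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

__all__ = [
    "PhraseGroupSpec",
    "CorpusConfig",
    "Document",
    "PatientRecord",
    "PlantEntry",
    "PlantLog",
    "default_groups",
    "default_config",
    "embedding_config",
    "generate_corpus",
    "inject_typos",
    "corrupt_token",
    "assign_death_dates",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_patients_csv",
    "read_patients_csv",
    "write_plant_log_csv",
    "read_plant_log_csv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PhraseGroupSpec:
    """A semantically coherent group of planted multi-word phrases.

    ``planting_probability`` is the fraction of patients receiving at
    least one phrase from this group; ``mortality_7d`` the probability
    that a planted patient's death falls within 7 days after one of
    their phrase-bearing documents.
    """

    group_label: str
    phrases: list[str]
    context_templates: list[str]  # each contains one "{phrase}" slot
    planting_probability: float
    mortality_7d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.planting_probability <= 1.0):
            raise ValueError("planting_probability must be in [0, 1]")
        if not (0.0 <= self.mortality_7d <= 1.0):
            raise ValueError("mortality_7d must be in [0, 1]")
        if not self.phrases:
            raise ValueError("phrase group must contain at least one phrase")
        for p in self.phrases:
            if len(p.split()) < 2:
                raise ValueError(f"planted phrases must have >=2 tokens: {p!r}")
        for t in self.context_templates:
            if "{phrase}" not in t:
                raise ValueError(f"template lacks a {{phrase}} slot: {t!r}")


@dataclass
class CorpusConfig:
    n_patients: int = 50_000
    docs_per_patient_mean: float = 4.0
    docs_per_patient_dispersion: float = 2.0  # negative-binomial r
    date_start: date = date(2018, 10, 1)
    date_end: date = date(2019, 9, 30)
    background_mortality_7d: float = 0.008
    typo_rate: float = 0.01
    groups: list[PhraseGroupSpec] = field(default_factory=lambda: default_groups())
    rng_seed: int = 0
    late_death_fraction: float = 0.05  # extra distant deaths, 30-365 d after last doc
    sentences_per_doc: tuple[int, int] = (2, 4)  # inclusive range of background sentences

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.date_start >= self.date_end:
            raise ValueError("date_start must precede date_end")
        if not (0.0 <= self.background_mortality_7d <= 1.0):
            raise ValueError("background_mortality_7d must be in [0, 1]")


@dataclass
class Document:
    doc_id: str
    patient_id: str
    doc_date: date
    text: str


@dataclass
class PatientRecord:
    patient_id: str
    death_date: date | None = None


@dataclass
class PlantEntry:
    patient_id: str
    group_label: str
    phrase: str       # canonical phrase as configured
    doc_id: str
    surface: str      # phrase as it actually appears (possibly typo-corrupted)


@dataclass
class PlantLog:
    entries: list[PlantEntry] = field(default_factory=list)

    def by_group(self) -> dict[str, list[PlantEntry]]:
        out: dict[str, list[PlantEntry]] = {}
        for e in self.entries:
            out.setdefault(e.group_label, []).append(e)
        return out

    def patients_by_group(self) -> dict[str, set[str]]:
        return {g: {e.patient_id for e in es} for g, es in self.by_group().items()}


# ---------------------------------------------------------------------------
# template library
# ---------------------------------------------------------------------------
# Background sentences are neutral ward prose.  They deliberately avoid
# every content word used inside the planted phrases (care, ceiling,
# escalation, life, palliative, "not", "for", ...) so that no background
# document can spuriously match a phrase query, and the contamination
# invariant is checkable by substring scan.

BACKGROUND_SENTENCES: list[str] = [
    "the patient was reviewed on the morning ward round and is comfortable",
    "observations were stable overnight with no new concerns raised by the nursing staff",
    "bloods were repeated today and the results are awaited from the laboratory",
    "the chest is now clear on auscultation and oxygen saturations are maintained",
    "continues on intravenous antibiotics and this is day three of the planned course",
    "the abdomen is soft and non tender with bowels opening normally",
    "a physiotherapy session was completed and mobility is slowly improving with a frame",
    "a dietitian review was requested as the oral intake is still poor this week",
    "urine output is adequate and renal function is improving on repeat bloods",
    "the patient was afebrile overnight and inflammatory markers are trending downwards",
    "the wound site is clean and dry with no evidence of infection",
    "the medication chart was reviewed and analgesia was adjusted with good effect",
    "an echocardiogram is awaited and this will be reviewed with cardiology",
    "a social work referral was made to assist with discharge planning",
    "the patient slept well and the appetite is slightly better this morning",
    "mild ankle swelling was noted and compression stockings were applied",
    "glucose readings remain within target range on the current insulin regime",
    "the speech and language team are happy that the diet is at a safe consistency",
    "the daughter visited this afternoon and was updated by the nursing team",
    "the plan is to repeat the chest radiograph tomorrow and to review the response",
    "a falls risk assessment was completed and bed rails are now in place",
    "pressure areas are intact and the repositioning regime continues as before",
    "an occupational therapy assessment was arranged ahead of discharge",
    "electrolytes were replaced this morning and the magnesium is now within range",
    "the family are aware that the recovery is likely to be slow",
    "nursing staff report that the patient is eating and drinking a little more",
]

# Group templates: >=5 per group, one {phrase} slot each.  Within a
# group the templates share content words (so same-group phrases see
# overlapping embedding contexts); across groups the content words are
# largely distinct (so groups separate in the embedding space).


def default_groups() -> list[PhraseGroupSpec]:
    """The three planted meaning groups used throughout.

    Rates mirror a published 12-month inpatient cohort: explicit
    end-of-life phrasing carries ~57% 7-day mortality against a 0.8%
    no-phrase background.
    """
    ceiling = PhraseGroupSpec(
        group_label="ceiling_of_care",
        phrases=[
            "ceiling of care",
            "ceilings of care",
            "ceiling of treatment",
            "ceilings of treatment",
            "ceiling of rx",
            "limit of care",
            "limits of care",
            "ward based care",
            "escalation beyond ward",
            "treatment escalation plan",
        ],
        context_templates=[
            "the consultant ward round documented the {phrase} and the family were updated",
            "a decision on the {phrase} was agreed with the next of kin",
            "senior review confirmed that {phrase} is appropriate and this was recorded in the notes",
            "the {phrase} was discussed at the board round this morning",
            "the frailty assessment supports a {phrase} with ongoing ward level management",
            "a family discussion was held and the {phrase} was documented by the registrar",
            "the registrar recorded a {phrase} to guide overnight management",
            "the {phrase} is still in place and was reviewed by the consultant",
            "the comorbidity burden was weighed and a {phrase} was agreed this evening",
            "the medical team revisited the {phrase} on the post take round",
        ],
        planting_probability=0.02,
        mortality_7d=0.576,
    )
    eol = PhraseGroupSpec(
        group_label="end_of_life",
        phrases=[
            "end of life care",
            "end of life",
            "eol care",
            "terminal care",
            "palliative care only",
            "palliative treatments only",
            "palliative input",
            "liverpool care pathway",
            "withdrawal of care",
            "withdrawal of treatment",
        ],
        context_templates=[
            "priorities are now comfort focused and {phrase} was commenced this evening",
            "a syringe driver was started alongside the {phrase} with anticipatory medications prescribed",
            "the team recognised the dying phase and agreed that {phrase} is appropriate",
            "comfort measures were prioritised as {phrase} continues on the ward",
            "the patient was transitioned to {phrase} with mouth moistening and repositioning",
            "relatives were present at the bedside as the {phrase} was documented",
            "the plan is {phrase} with anticipatory prescribing and chaplaincy offered",
            "nursing staff ensuring dignity and comfort while the {phrase} is maintained overnight",
            "discussed with the family that {phrase} was now the priority",
            "the ward sister was aware that the {phrase} is continuing with regular review",
        ],
        planting_probability=0.02,
        mortality_7d=0.575,
    )
    lst = PhraseGroupSpec(
        group_label="lst_limitation",
        phrases=[
            "not for intubation",
            "not for itu",
            "not for icu",
            "not for critical care",
            "not for resuscitation",
            "not for cpr",
            "not for inotropes",
            "not for niv",
            "not for hdu",
            "not for escalation",
        ],
        context_templates=[
            "the anaesthetic review concluded that {phrase} is appropriate given the physiological reserve",
            "the intensive unit consultant advised that the patient is {phrase} at this time",
            "documented that the patient was {phrase} after assessment by the intensivist",
            "resuscitation status was clarified as {phrase} and the form was countersigned",
            "organ support was discussed and {phrase} was agreed with the intensive consultant",
            "the deterioration plan states the patient to be {phrase} with ward measures to continue",
            "the dnacpr form was completed and {phrase} was also documented",
            "escalation status was recorded and the patient was {phrase} on this admission",
            "the night team are aware that the patient is {phrase} while on the ward",
            "assessment by the outreach team concluded the patient is {phrase} at present",
        ],
        planting_probability=0.02,
        mortality_7d=0.567,
    )
    return [ceiling, eol, lst]


def default_config(**overrides) -> CorpusConfig:
    """Desk-scale default: 50 000 patients, mean 4 documents each."""
    return CorpusConfig(**overrides)


def embedding_config(n_patients: int = 2500, planting_probability: float = 0.15,
                     **overrides) -> CorpusConfig:
    """Denser planting for embedding experiments.

    Embedding/phrasing needs each planted phrase to clear the
    minimum-frequency threshold (10), so the per-group planting
    probability is raised; everything else matches the default
    conditions.
    """
    groups = [replace(g, planting_probability=planting_probability)
              for g in default_groups()]
    return CorpusConfig(n_patients=n_patients, groups=groups, **overrides)


# ---------------------------------------------------------------------------
# typo injection
# ---------------------------------------------------------------------------

_TYPO_OPS = ("transpose", "delete", "substitute")
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def corrupt_token(token: str, rng: np.random.Generator, op: str | None = None) -> str:
    """Apply one typographical corruption to a word-internal character.

    Operators: adjacent-character transposition, single deletion,
    single substitution.  The first and last characters are never
    touched, so token boundaries (and the token count) survive.
    Tokens shorter than 5 characters are returned unchanged: that is
    the length below which downstream fuzzy matching is off, so a
    corrupted short token would be irrecoverable by design and would
    confound cohort retrieval rather than exercise it.
    """
    if len(token) < 5:
        return token
    if op is None:
        op = _TYPO_OPS[rng.integers(0, len(_TYPO_OPS))]
    # internal positions are 1 .. len-2
    if op == "transpose":
        # swap internal chars i, i+1 (i+1 may be the last-but-one)
        i = int(rng.integers(1, len(token) - 2))
        return token[:i] + token[i + 1] + token[i] + token[i + 2:]
    if op == "delete":
        i = int(rng.integers(1, len(token) - 1))
        return token[:i] + token[i + 1:]
    if op == "substitute":
        i = int(rng.integers(1, len(token) - 1))
        c = _ALPHABET[rng.integers(0, 26)]
        return token[:i] + c + token[i + 1:]
    raise ValueError(f"unknown corruption operator {op!r}")


def inject_typos(text: str, rate: float, rng: np.random.Generator) -> str:
    """Corrupt each whitespace token independently with probability ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or not text:
        return text
    tokens = text.split(" ")
    u = rng.random(len(tokens))
    changed = False
    for i in np.nonzero(u < rate)[0]:
        new = corrupt_token(tokens[i], rng)
        if new != tokens[i]:
            tokens[i] = new
            changed = True
    return " ".join(tokens) if changed else text


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _check_contamination(groups: list[PhraseGroupSpec]) -> None:
    for g in groups:
        for p in g.phrases:
            for s in BACKGROUND_SENTENCES:
                if p in s:
                    raise ValueError(
                        f"background sentence contains planted phrase {p!r}: {s!r}"
                    )


def generate_corpus(
    config: CorpusConfig,
) -> tuple[list[Document], list[PatientRecord], PlantLog]:
    """Generate the corpus, the patient registry and the plant log.

    Deterministic for a fixed config + seed.  Each patient receives a
    shifted negative-binomial number of documents (min 1) made of
    neutral background sentences; for each group, a Bernoulli draw per
    patient decides planting, and a planted patient gets one group
    sentence (template + phrase, typo-corrupted like everything else)
    inserted into one of their documents.  Death dates are then
    assigned by :func:`assign_death_dates`.
    """
    _check_contamination(config.groups)
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients
    if n == 0:
        return [], [], PlantLog()

    span_days = (config.date_end - config.date_start).days

    # documents per patient: 1 + NegBin(r, p) with mean-1 extra docs
    r = config.docs_per_patient_dispersion
    extra_mean = max(config.docs_per_patient_mean - 1.0, 0.0)
    if extra_mean > 0:
        p = r / (r + extra_mean)
        n_docs = 1 + rng.negative_binomial(r, p, size=n)
    else:
        n_docs = np.ones(n, dtype=int)

    lo, hi = config.sentences_per_doc
    documents: list[Document] = []
    patients: list[PatientRecord] = []
    doc_index_of_patient: list[list[int]] = []

    bg = BACKGROUND_SENTENCES
    n_bg = len(bg)
    for i in range(n):
        pid = f"p{i:06d}"
        patients.append(PatientRecord(pid))
        my_docs: list[int] = []
        k = int(n_docs[i])
        dates = np.sort(rng.integers(0, span_days + 1, size=k))
        for j in range(k):
            n_sent = int(rng.integers(lo, hi + 1))
            idx = rng.integers(0, n_bg, size=n_sent)
            text = " . ".join(bg[s] for s in idx)
            if config.typo_rate > 0:
                text = inject_typos(text, config.typo_rate, rng)
            doc_id = f"d{len(documents):07d}"
            my_docs.append(len(documents))
            documents.append(
                Document(doc_id, pid, config.date_start + timedelta(days=int(dates[j])), text)
            )
        doc_index_of_patient.append(my_docs)

    # plant group phrases; a patient planted in several groups has every
    # group's sentence placed in the SAME document, mirroring how such
    # documentation co-occurs in one clinical note (and keeping the
    # per-group mortality recovery unbiased for overlapping cohorts)
    log = PlantLog()
    planted_mask = [
        np.nonzero(rng.random(n) < g.planting_probability)[0] for g in config.groups
    ]
    groups_of: dict[int, list[PhraseGroupSpec]] = {}
    for g, idx in zip(config.groups, planted_mask):
        for i in idx:
            groups_of.setdefault(int(i), []).append(g)
    for i in sorted(groups_of):
        docs_i = doc_index_of_patient[i]
        di = docs_i[int(rng.integers(0, len(docs_i)))]
        for g in groups_of[i]:
            phrase = g.phrases[int(rng.integers(0, len(g.phrases)))]
            template = g.context_templates[int(rng.integers(0, len(g.context_templates)))]
            sentence = template.format(phrase=phrase)
            # corrupt the plant sentence and recover the phrase surface
            pre, _post = template.split("{phrase}")
            n_pre = len(pre.split()) if pre.strip() else 0
            corrupted = inject_typos(sentence, config.typo_rate, rng)
            ctoks = corrupted.split(" ")
            n_phrase = len(phrase.split())
            surface = " ".join(ctoks[n_pre:n_pre + n_phrase])
            doc = documents[di]
            # insert plant sentence at a random sentence boundary
            parts = doc.text.split(" . ")
            pos = int(rng.integers(0, len(parts) + 1))
            parts.insert(pos, corrupted)
            documents[di] = Document(doc.doc_id, doc.patient_id, doc.doc_date,
                                     " . ".join(parts))
            log.entries.append(
                PlantEntry(doc.patient_id, g.group_label, phrase, doc.doc_id, surface)
            )

    patients = assign_death_dates(
        patients, log, config.groups, config.background_mortality_7d, rng,
        documents=documents, late_death_fraction=config.late_death_fraction,
    )
    return documents, patients, log


def assign_death_dates(
    patients: list[PatientRecord],
    log: PlantLog,
    groups: list[PhraseGroupSpec],
    background_mortality_7d: float,
    rng: np.random.Generator,
    documents: list[Document],
    late_death_fraction: float = 0.0,
    window_days: int = 7,
) -> list[PatientRecord]:
    """Populate death dates.

    A planted patient dies within ``[0, window_days]`` days of one of
    their phrase-bearing documents with their group's ``mortality_7d``
    (the maximum over groups when planted in several); a non-planted
    patient dies within the window of a random document with the
    background probability; a further ``late_death_fraction`` of the
    remaining patients receive a distant death 30-365 days after their
    last document.
    """
    doc_by_id = {d.doc_id: d for d in documents}
    docs_of: dict[str, list[Document]] = {}
    for d in documents:
        docs_of.setdefault(d.patient_id, []).append(d)

    rate_of_group = {g.group_label: g.mortality_7d for g in groups}
    # per planted patient: the group with maximal mortality and one of
    # its phrase documents
    plan: dict[str, tuple[float, str]] = {}  # pid -> (rate, doc_id)
    for e in log.entries:
        rate = rate_of_group[e.group_label]
        cur = plan.get(e.patient_id)
        if cur is None or rate > cur[0]:
            plan[e.patient_id] = (rate, e.doc_id)

    out: list[PatientRecord] = []
    undecided: list[int] = []
    for idx, pat in enumerate(patients):
        entry = plan.get(pat.patient_id)
        if entry is not None:
            rate, doc_id = entry
            if rng.random() < rate:
                offset = int(rng.integers(0, window_days + 1))
                out.append(PatientRecord(pat.patient_id,
                                         doc_by_id[doc_id].doc_date + timedelta(days=offset)))
            else:
                out.append(PatientRecord(pat.patient_id, None))
                undecided.append(idx)
        else:
            if rng.random() < background_mortality_7d:
                docs = docs_of[pat.patient_id]
                d = docs[int(rng.integers(0, len(docs)))]
                offset = int(rng.integers(0, window_days + 1))
                out.append(PatientRecord(pat.patient_id,
                                         d.doc_date + timedelta(days=offset)))
            else:
                out.append(PatientRecord(pat.patient_id, None))
                undecided.append(idx)

    if late_death_fraction > 0 and undecided:
        sel = rng.random(len(undecided)) < late_death_fraction
        for j, idx in enumerate(undecided):
            if sel[j]:
                pid = out[idx].patient_id
                last = max(d.doc_date for d in docs_of[pid])
                offset = int(rng.integers(30, 366))
                out[idx] = PatientRecord(pid, last + timedelta(days=offset))
    return out


# ---------------------------------------------------------------------------
# plain-text I/O (JSONL corpus, CSV registry and plant log)
# ---------------------------------------------------------------------------

def write_corpus_jsonl(documents: list[Document], path: str) -> None:
    with open(path, "w") as fh:
        for d in documents:
            fh.write(json.dumps({
                "doc_id": d.doc_id,
                "patient_id": d.patient_id,
                "doc_date": d.doc_date.isoformat(),
                "text": d.text,
            }) + "\n")


def read_corpus_jsonl(path: str) -> list[Document]:
    out = []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            out.append(Document(obj["doc_id"], obj["patient_id"],
                                date.fromisoformat(obj["doc_date"]), obj["text"]))
    return out


def write_patients_csv(patients: list[PatientRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "death_date"])
        for p in patients:
            w.writerow([p.patient_id, p.death_date.isoformat() if p.death_date else ""])


def read_patients_csv(path: str) -> list[PatientRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dd = row["death_date"]
            out.append(PatientRecord(row["patient_id"],
                                     date.fromisoformat(dd) if dd else None))
    return out


def write_plant_log_csv(log: PlantLog, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "group_label", "phrase", "doc_id", "surface"])
        for e in log.entries:
            w.writerow([e.patient_id, e.group_label, e.phrase, e.doc_id, e.surface])


def read_plant_log_csv(path: str) -> PlantLog:
    log = PlantLog()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            log.entries.append(PlantEntry(row["patient_id"], row["group_label"],
                                          row["phrase"], row["doc_id"], row["surface"]))
    return log
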