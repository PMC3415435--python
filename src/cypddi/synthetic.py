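"""Synthetic knowledge bases, abstract corpora, and EMR tables.

Every downstream stage of the DDI pipeline is exercised against data with a
known generative truth. Three generators are provided:

* :func:`generate_knowledge_base` — per-drug CYP roles, metabolism extent and
  inhibition constants (Ki, µM);
* :func:`generate_abstract_corpus` / :func:`spike_decoy_corpus` — labelled
  abstracts that do or do not instantiate the DDI sentence patterns;
* :func:`generate_emr` — minimal OMOP-CDM-like person / drug_exposure /
  condition_occurrence tables in which myopathy events are drawn from a risk
  model with demographic effects (female vs male patient-level risk
  0.086 vs 0.054; age odds multiplier 1.0015 per year) and an injectable
  synergistic joint-exposure multiplier theta, applied on the risk scale as
  Risk12 = theta * (Risk1 + Risk2).

:func:`simulate_exposure_groups` draws the three-cohort design directly
(substrate alone / inhibitor alone / joint) and is the workhorse for test
calibration, power and parameter-recovery studies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .lexicon import (
    CYP_ENZYMES,
    FDA_PROBE_SUBSTRATES,
    PROHIBITED_TERMS,
)

logger = logging.getLogger(__name__)

WINDOW_DAYS = 30  # "one month" is fixed at 30 days throughout

_DEFAULT_ROLE_PROBS = {"none": 0.55, "substrate": 0.20, "inhibitor": 0.15, "both": 0.10}

# Syllable pools for pronounceable synthetic generic drug names.
_PREFIX = ("ab", "cor", "dal", "el", "fen", "gal", "hex", "ib", "jan", "kel",
           "lor", "mav", "nor", "op", "pral", "quin", "rov", "sal", "tor", "ux",
           "vel", "wex", "xan", "yor", "zal")
_MID = ("a", "e", "i", "o", "u", "ami", "eti", "ora", "ilu", "uvo")
_SUFFIX = ("zole", "statin", "pril", "mab", "oxacin", "idine", "azepam",
           "profen", "mycin", "arone", "tadine", "setron")


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic EMR world.

    Defaults state the demographic world of the source cohort: ~59% female,
    age 40.2 +/- 23 years, female/male patient-level myopathy risks
    0.086/0.054, and an age odds multiplier of 1.0015 per year. Drug and
    interaction effects default to none; injecting them is the caller's
    statement of the world under study.
    """

    n_patients: int = 20_000
    study_start: date = date(2004, 1, 1)
    study_end: date = date(2009, 12, 31)
    female_fraction: float = 0.591
    age_distribution: tuple[float, float] = (40.2, 23.0)
    baseline_window_risk: float = 0.005
    sex_risk_pair: tuple[float, float] = (0.086, 0.054)  # (female, male)
    age_or_per_year: float = 1.0015
    drug_risks: dict[str, float] = field(default_factory=dict)
    ddi_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    comed_rate: float = 2.6
    seed: int = 0
    # Exposure mechanics (not part of the epidemiological model, but the
    # world needs a rule for who is exposed):
    pair_exposure: tuple[float, float, float] = (0.04, 0.04, 0.02)  # f1, f2, f12
    single_exposure_fraction: float = 0.05

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        for p in (self.female_fraction, self.baseline_window_risk,
                  *self.sex_risk_pair, *self.drug_risks.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for pair, theta in self.ddi_effects.items():
            if theta <= 0:
                raise ValueError(f"theta must be > 0 for pair {pair}")
        f1, f2, f12 = self.pair_exposure
        n_pairs = max(len(self.ddi_effects), 1)
        if (f1 + f2 + f12) * n_pairs > 1.0:
            raise ValueError("pair exposure fractions exceed the population")


@dataclass
class GroundTruth:
    """Generative truth of a synthetic dataset, for parameter-recovery tests."""

    kb: pd.DataFrame | None = None
    ddi_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    abstract_labels: dict[str, dict] = field(default_factory=dict)
    emr: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = {
            "ddi_pairs": {" | ".join(k): float(v) for k, v in self.ddi_pairs.items()},
            "abstract_labels": self.abstract_labels,
            "emr": _jsonable(self.emr),
        }
        if self.kb is not None:
            payload["kb"] = self.kb.to_dict(orient="records")
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _drug_names(n: int, rng: np.random.Generator) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        name = rng.choice(_PREFIX) + rng.choice(_MID) + rng.choice(_SUFFIX)
        if name not in seen:
            seen.add(name)
            names.append(str(name))
    return names


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------

def generate_knowledge_base(
    n_drugs: int,
    enzyme_list: Sequence[str] = CYP_ENZYMES,
    role_probs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a drug knowledge base: per (drug, enzyme) a role, extent and Ki.

    Returns a long-format DataFrame with columns
    ``drug, enzyme, role, extent, ki_um`` (one row per drug-enzyme
    combination with a non-``none`` role) and the :class:`GroundTruth`.
    """
    if n_drugs <= 0:
        raise ValueError("n_drugs must be positive")
    unknown = set(enzyme_list) - set(CYP_ENZYMES)
    if unknown:
        raise ValueError(f"unknown enzymes: {sorted(unknown)}")
    probs = dict(_DEFAULT_ROLE_PROBS if role_probs is None else role_probs)
    total = sum(probs.values())
    if not np.isclose(total, 1.0):
        probs = {k: v / total for k, v in probs.items()}

    rng = np.random.default_rng(seed)
    drugs = _drug_names(n_drugs, rng)
    roles = list(probs)
    p = np.array([probs[r] for r in roles])

    rows = []
    for drug in drugs:
        for enzyme in enzyme_list:
            role = roles[rng.choice(len(roles), p=p)]
            if role == "none":
                continue
            is_sub = role in ("substrate", "both")
            is_inh = role in ("inhibitor", "both")
            extent = str(rng.choice(["major", "minor"])) if is_sub else "none"
            # Ki log-uniform over 1-1000 uM spans the strong/moderate/weak bins
            ki = float(10 ** rng.uniform(0, 3)) if is_inh else np.nan
            rows.append(
                {"drug": drug, "enzyme": enzyme, "role": role,
                 "extent": extent, "ki_um": ki}
            )
    kb = pd.DataFrame(rows, columns=["drug", "enzyme", "role", "extent", "ki_um"])
    truth = GroundTruth(kb=kb.copy())
    return kb, truth


def write_kb_tsv(kb: pd.DataFrame, path) -> None:
    kb.to_csv(path, sep="\t", index=False)


def read_kb_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Abstract corpora
# ---------------------------------------------------------------------------

_PATTERN_TAGS = ("DEO", "DOE", "EOD", "IDD1", "IDD2", "DID")

# Sentence templates instantiating exactly one pattern each. {D}/{D2} are
# drugs, {E} an enzyme. Negated variants flip the assertion.
_POS_TEMPLATES: dict[str, list[tuple[str, bool]]] = {
    "DEO": [
        ("{D} is a {E} substrate in vitro.", False),
        ("{D} was shown to be a {E} substrate.", False),
        ("{D} is not a {E} substrate.", True),
    ],
    "DOE": [
        ("{D} inhibits {E} activity.", False),
        ("{D} is a potent inhibitor of {E}.", False),
        ("{D} did not inhibit {E}.", True),
    ],
    "EOD": [
        ("{E} is inhibited by {D}.", False),
        ("{E} was induced by {D} treatment.", False),
        ("{E} was not inhibited by {D}.", True),
    ],
    "IDD1": [
        ("a significant interaction between {D} and {D2} was observed.", False),
        ("there is not interaction between {D} and {D2}.", True),
    ],
    "IDD2": [
        ("marked impact of {D} on {D2} clearance was seen.", False),
        ("no impact of {D} on {D2} pharmacokinetics was found.", True),
    ],
    "DID": [
        ("{D} strongly interacts with {D2}.", False),
        ("{D} does not interact with {D2}.", True),
    ],
}

# Filler sentences: carry required IR-template terms but no drug+operator
# co-occurrence that could instantiate a pattern.
_CONTEXT_TEMPLATES = [
    "incubation was performed with {SYSTEM_TERM} preparations.",
    "apparent ki and km values were estimated from kinetic analysis.",
    "ic50 determinations used standard microsomes under linear conditions.",
]

_DECOY_SENTENCES = [
    "patients were randomized to receive standard supportive care.",
    "the questionnaire assessed sleep quality over twelve weeks.",
    "renal function remained stable throughout the observation period.",
    "dietary sodium intake was recorded in a food frequency diary.",
    "the imaging protocol was approved by the local ethics committee.",
]

_SYSTEMS = ("human liver microsome", "human hepatocyte", "recombinant cyp")
_SYSTEM_TERM = {
    "human liver microsome": "human liver microsome",
    "human hepatocyte": "human hepatocyte",
    "recombinant cyp": "recombinant",
}


def generate_abstract_corpus(
    kb: pd.DataFrame,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
) -> tuple[list[dict], GroundTruth]:
    """Generate a labelled corpus of abstracts.

    Positive abstracts contain exactly one DDI-relevant pattern sentence plus
    assay-context filler satisfying the retrieval template; negatives contain
    no pattern (plain decoys, or decoys carrying a prohibited term).
    """
    if kb.empty:
        raise ValueError("knowledge base is empty")
    if n_pos + n_neg == 0:
        raise ValueError("n_pos + n_neg must be positive")
    rng = np.random.default_rng(seed)
    drugs = sorted(kb["drug"].unique().tolist())
    enzymes = sorted(kb["enzyme"].unique().tolist())

    corpus: list[dict] = []
    truth = GroundTruth()
    for i in range(n_pos):
        tag = _PATTERN_TAGS[rng.choice(len(_PATTERN_TAGS))]
        template, negated = _POS_TEMPLATES[tag][
            rng.choice(len(_POS_TEMPLATES[tag]))
        ]
        drug = drugs[rng.choice(len(drugs))]
        drug2 = drugs[rng.choice(len(drugs))]
        while drug2 == drug and len(drugs) > 1:
            drug2 = drugs[rng.choice(len(drugs))]
        enzyme = enzymes[rng.choice(len(enzymes))]
        system = _SYSTEMS[rng.choice(len(_SYSTEMS))]
        probe = FDA_PROBE_SUBSTRATES[enzyme][0]
        pattern_sentence = template.format(D=drug, D2=drug2, E=enzyme.lower())
        sentences = [
            pattern_sentence,
            # probe sentence: one drug token, no enzyme, no operator verb
            f"the probe compound {probe} was included as reference.",
            _CONTEXT_TEMPLATES[0].format(SYSTEM_TERM=_SYSTEM_TERM[system]),
            _CONTEXT_TEMPLATES[1],
        ]
        if tag in ("IDD1", "IDD2", "DID"):
            # enzyme mention required by the IR template; drug-free sentence
            sentences.append(f"{enzyme.lower()} activity was monitored throughout.")
        abstract_id = f"pos{i:05d}"
        annotations = {
            "system": system,
            "probe_used": probe,
            "enzyme": enzyme,
        }
        corpus.append(
            {"id": abstract_id, "sentences": sentences, "annotations": annotations}
        )
        truth.abstract_labels[abstract_id] = {
            "relevant": True,
            "pattern": tag,
            "drugs": [drug] if tag in ("DEO", "DOE", "EOD") else [drug, drug2],
            "enzyme": enzyme if tag in ("DEO", "DOE", "EOD") else None,
            "negated": bool(negated),
        }

    prohibited = sorted(PROHIBITED_TERMS)
    for i in range(n_neg):
        abstract_id = f"neg{i:05d}"
        k = int(rng.integers(2, 5))
        idx = rng.choice(len(_DECOY_SENTENCES), size=k)
        sentences = [_DECOY_SENTENCES[j] for j in idx]
        if rng.random() < 0.5:  # prohibited-term decoy
            term = prohibited[rng.choice(len(prohibited))]
            sentences.append(f"findings were discussed in the context of {term} care.")
        corpus.append({"id": abstract_id, "sentences": sentences, "annotations": {}})
        truth.abstract_labels[abstract_id] = {
            "relevant": False, "pattern": None, "drugs": [],
            "enzyme": None, "negated": False,
        }
    return corpus, truth


def spike_decoy_corpus(
    positives: list[dict],
    n_decoys: int,
    seed: int = 0,
) -> tuple[list[dict], set[str]]:
    """Mix positives with decoy abstracts drawn from a non-DDI sentence model.

    Returns the shuffled corpus and the set of positive abstract ids, for
    recall estimation.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n_decoys):
        k = int(rng.integers(2, 5))
        idx = rng.choice(len(_DECOY_SENTENCES), size=k)
        decoys.append(
            {"id": f"decoy{i:06d}",
             "sentences": [_DECOY_SENTENCES[j] for j in idx],
             "annotations": {}}
        )
    mixed = list(positives) + decoys
    order = rng.permutation(len(mixed))
    mixed = [mixed[j] for j in order]
    return mixed, {a["id"] for a in positives}


def write_corpus_jsonl(corpus: list[dict], path) -> None:
    with open(path, "w") as fh:
        for abstract in corpus:
            fh.write(json.dumps(abstract) + "\n")


def read_corpus_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# EMR tables
# ---------------------------------------------------------------------------

@dataclass
class EMRTables:
    person: pd.DataFrame
    drug_exposure: pd.DataFrame
    condition_occurrence: pd.DataFrame

    def to_csv(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.person.to_csv(d / "person.csv", index=False)
        self.drug_exposure.to_csv(d / "drug_exposure.csv", index=False)
        self.condition_occurrence.to_csv(d / "condition_occurrence.csv", index=False)

    @classmethod
    def from_csv(cls, directory) -> "EMRTables":
        from pathlib import Path

        d = Path(directory)
        return cls(
            person=pd.read_csv(d / "person.csv"),
            drug_exposure=pd.read_csv(d / "drug_exposure.csv", parse_dates=["start_date"]),
            condition_occurrence=pd.read_csv(
                d / "condition_occurrence.csv", parse_dates=["event_date"]
            ),
        )


_MYOPATHY_CONCEPT_POOL = (
    "Myalgia and myositis",
    "Muscle weakness",
    "Polymyositis",
    "Rhabdomyolysis",
    "Myoglobinuria",
)


def _truncated_ages(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    ages = rng.normal(mean, sd, size=n)
    bad = (ages < 0) | (ages > 100)
    while bad.any():
        ages[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (ages < 0) | (ages > 100)
    return ages


def _window_risk(
    base: np.ndarray | float,
    female: np.ndarray,
    age: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Logit-adjust a window-level risk for sex and age.

    The sex effect is the odds ratio implied by the configured female/male
    patient-level risks; the age effect is the per-year odds multiplier,
    centred at the configured mean age.
    """
    rf, rm = cfg.sex_risk_pair
    sex_lor = logit(rf) - logit(rm)
    base = np.clip(np.asarray(base, dtype=float), 1e-9, 1 - 1e-9)
    lo = (
        logit(base)
        + female * sex_lor
        + (age - cfg.age_distribution[0]) * np.log(cfg.age_or_per_year)
    )
    return expit(lo)


def generate_emr(
    config: SimulationConfig,
    kb: pd.DataFrame,
) -> tuple[EMRTables, GroundTruth]:
    """Simulate person / drug_exposure / condition_occurrence tables.

    Mechanism, per patient:

    * demographics: sex ~ Bernoulli(female_fraction); age truncated normal
      on [0, 100]; birth year derived from age at study start.
    * idiopathic myopathy: one event with probability
      expit(logit(sex risk) + log(age OR) * (age - mean age)), dated
      uniformly in the study period. This channel calibrates the marginal
      female/male risks to the configured 0.086/0.054.
    * index exposure: each patient is assigned at most one scenario —
      joint / drug1-alone / drug2-alone for a configured interaction pair,
      or a standalone risky drug. A single-drug window carries risk
      baseline_window_risk + drug risk (logit-adjusted for sex/age); a joint
      window carries theta * (risk1 + risk2), capped at 1 with a logged
      warning. Events are dated so the dispensing(s) fall inside the 30-day
      look-back window before the event.
    * co-medications: every patient has one care episode at which
      Poisson(comed_rate) benign drugs are dispensed together — on the index
      anchor date for exposed patients, on a random date otherwise. Clustered
      same-visit prescribing makes co-medication a genuine confounder while
      benign drug pairs still acquire an unexposed background population.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    n_days = (end - start).days

    female = rng.random(n) < config.female_fraction
    ages = _truncated_ages(n, *config.age_distribution, rng)
    birth_year = start.year - ages.astype(int)
    person_ids = np.array([f"P{i:07d}" for i in range(n)])

    person = pd.DataFrame(
        {"person_id": person_ids,
         "sex": np.where(female, "F", "M"),
         "birth_year": birth_year}
    )

    # --- idiopathic channel (marginal demographic calibration) ---
    rf, rm = config.sex_risk_pair
    p_idio = expit(
        np.where(female, logit(rf), logit(rm))
        + (ages - config.age_distribution[0]) * np.log(config.age_or_per_year)
    )
    has_idio = rng.random(n) < p_idio
    idio_day = rng.integers(0, n_days + 1, size=n)

    rx_person: list[np.ndarray | list] = []
    rx_drug: list = []
    rx_date: list = []
    cond_person: list = []
    cond_name: list = []
    cond_date: list = []

    idio_idx = np.flatnonzero(has_idio)
    cond_person.extend(person_ids[idio_idx])
    cond_name.extend(
        np.array(_MYOPATHY_CONCEPT_POOL)[
            rng.integers(0, len(_MYOPATHY_CONCEPT_POOL), size=idio_idx.size)
        ]
    )
    cond_date.extend(start + pd.to_timedelta(idio_day[idio_idx], unit="D"))

    # --- exposure scenario assignment ---
    pairs = list(config.ddi_effects.items())
    pair_drugs = {d for (a, b) in config.ddi_effects for d in (a, b)}
    singles = [d for d in config.drug_risks if d not in pair_drugs]
    scenarios: list[tuple] = []  # (kind, payload, prob)
    f1, f2, f12 = config.pair_exposure
    for (a, b), theta in pairs:
        scenarios.append(("joint", (a, b, theta), f12))
        scenarios.append(("single", a, f1))
        scenarios.append(("single", b, f2))
    for d in singles:
        scenarios.append(("single", d, config.single_exposure_fraction))
    probs = np.array([s[2] for s in scenarios], dtype=float)
    if probs.sum() > 1.0:
        raise ValueError("exposure fractions sum to more than 1")
    cut = np.concatenate([[0.0], np.cumsum(probs)])
    u = rng.random(n)
    scenario_of = np.full(n, -1)
    for k in range(len(scenarios)):
        scenario_of[(u >= cut[k]) & (u < cut[k + 1])] = k

    emr_truth: dict = {
        "theta": {f"{a}|{b}": t for (a, b), t in pairs},
        "assignment_counts": {},
        "capped_windows": 0,
        "comed_rate": config.comed_rate,
    }

    all_drugs = sorted(kb["drug"].unique().tolist()) if not kb.empty else []
    risky = set(config.drug_risks) | pair_drugs
    benign_pool = np.array([d for d in all_drugs if d not in risky])
    if benign_pool.size == 0:
        benign_pool = np.array([f"comed{i:02d}" for i in range(10)])

    def _add_comeds(idx: np.ndarray, anchor_days: np.ndarray) -> None:
        counts = rng.poisson(config.comed_rate, size=idx.size)
        for j, (i_pat, day, c) in enumerate(zip(idx, anchor_days, counts)):
            if c == 0:
                continue
            k = min(int(c), benign_pool.size)
            meds = rng.choice(benign_pool, size=k, replace=False)
            for m in meds:
                rx_person.append(person_ids[i_pat])
                rx_drug.append(m)
                rx_date.append(start + pd.Timedelta(int(day), "D"))

    n_capped = 0
    margin = WINDOW_DAYS + 5
    for k, (kind, payload, _) in enumerate(scenarios):
        idx = np.flatnonzero(scenario_of == k)
        if idx.size == 0:
            continue
        if kind == "single":
            drug = payload
            r = config.baseline_window_risk + config.drug_risks.get(drug, 0.0)
            q = _window_risk(r, female[idx].astype(float), ages[idx], config)
            disp_day = rng.integers(margin, n_days - margin, size=idx.size)
            event = rng.random(idx.size) < q
            for i_pat, day in zip(idx, disp_day):
                rx_person.append(person_ids[i_pat])
                rx_drug.append(drug)
                rx_date.append(start + pd.Timedelta(int(day), "D"))
            ev_idx = idx[event]
            ev_day = disp_day[event] + rng.integers(0, WINDOW_DAYS + 1, size=ev_idx.size)
            cond_person.extend(person_ids[ev_idx])
            cond_name.extend(
                np.array(_MYOPATHY_CONCEPT_POOL)[
                    rng.integers(0, len(_MYOPATHY_CONCEPT_POOL), size=ev_idx.size)
                ]
            )
            cond_date.extend(start + pd.to_timedelta(ev_day, unit="D"))
            _add_comeds(idx, disp_day)
            emr_truth["assignment_counts"][f"single:{drug}"] = int(idx.size)
        else:
            a, b, theta = payload
            ra = config.baseline_window_risk + config.drug_risks.get(a, 0.0)
            rb = config.baseline_window_risk + config.drug_risks.get(b, 0.0)
            qa = _window_risk(ra, female[idx].astype(float), ages[idx], config)
            qb = _window_risk(rb, female[idx].astype(float), ages[idx], config)
            q12 = theta * (qa + qb)
            capped = q12 > 1.0
            if capped.any():
                n_capped += int(capped.sum())
                logger.warning(
                    "joint window risk exceeded 1 for %d patients of pair (%s, %s); capped",
                    int(capped.sum()), a, b,
                )
            q12 = np.clip(q12, 0.0, 1.0)
            day_a = rng.integers(margin, n_days - margin, size=idx.size)
            delta = rng.integers(-15, 16, size=idx.size)
            day_b = day_a + delta
            event = rng.random(idx.size) < q12
            for i_pat, da, db in zip(idx, day_a, day_b):
                rx_person.append(person_ids[i_pat])
                rx_drug.append(a)
                rx_date.append(start + pd.Timedelta(int(da), "D"))
                rx_person.append(person_ids[i_pat])
                rx_drug.append(b)
                rx_date.append(start + pd.Timedelta(int(db), "D"))
            ev_idx = idx[event]
            hi = WINDOW_DAYS - np.abs(delta[event])  # keep both drugs in window
            ev_day = np.maximum(day_a[event], day_b[event]) + (
                rng.random(ev_idx.size) * (hi + 1)
            ).astype(int)
            cond_person.extend(person_ids[ev_idx])
            cond_name.extend(
                np.array(_MYOPATHY_CONCEPT_POOL)[
                    rng.integers(0, len(_MYOPATHY_CONCEPT_POOL), size=ev_idx.size)
                ]
            )
            cond_date.extend(start + pd.to_timedelta(ev_day, unit="D"))
            _add_comeds(idx, np.maximum(day_a, day_b))
            emr_truth["assignment_counts"][f"joint:{a}|{b}"] = int(idx.size)

    emr_truth["capped_windows"] = n_capped

    # care-episode co-medications for unexposed patients
    unexposed = np.flatnonzero(scenario_of == -1)
    if unexposed.size:
        care_day = rng.integers(0, n_days + 1, size=unexposed.size)
        _add_comeds(unexposed, care_day)

    drug_exposure = pd.DataFrame(
        {"person_id": rx_person, "drug_name": rx_drug, "start_date": rx_date}
    ).sort_values(["person_id", "start_date", "drug_name"], kind="stable").reset_index(drop=True)
    condition = pd.DataFrame(
        {"person_id": cond_person, "concept_name": cond_name, "event_date": cond_date}
    ).sort_values(["person_id", "event_date", "concept_name"], kind="stable").reset_index(drop=True)

    truth = GroundTruth(ddi_pairs=dict(config.ddi_effects), emr=emr_truth)
    return EMRTables(person, drug_exposure, condition), truth


# ---------------------------------------------------------------------------
# Direct three-cohort simulator
# ---------------------------------------------------------------------------

def simulate_exposure_groups(
    n1: int,
    n2: int,
    n12: int,
    risk1: float,
    risk2: float,
    theta: float = 1.0,
    risk12: float | None = None,
    with_covariates: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw episode data for the three-cohort design directly.

    Group risks are (risk1, risk2, theta * (risk1 + risk2)) unless ``risk12``
    is given explicitly. With ``with_covariates=True`` the risks are
    logit-modulated by sex and age (female OR from the default 0.086/0.054
    pair; 1.0015 per year of age) while joint windows remain exactly
    theta * (risk1(x) + risk2(x)), so the synergy parameter is invariant to
    the covariate mix.
    """
    if min(n1, n2, n12) < 0:
        raise ValueError("group sizes must be non-negative")
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig()
    groups = np.repeat(
        ["substrate_alone", "inhibitor_alone", "joint"], [n1, n2, n12]
    )
    n = n1 + n2 + n12
    if with_covariates:
        female = (rng.random(n) < cfg.female_fraction).astype(float)
        age = _truncated_ages(n, *cfg.age_distribution, rng)
        q1 = _window_risk(risk1, female, age, cfg)
        q2 = _window_risk(risk2, female, age, cfg)
    else:
        female = np.zeros(n)
        age = np.full(n, cfg.age_distribution[0])
        q1 = np.full(n, risk1)
        q2 = np.full(n, risk2)
    if risk12 is None:
        q12 = np.clip(theta * (q1 + q2), 0.0, 1.0)
    else:
        q12 = np.clip(
            _window_risk(risk12, female, age, cfg) if with_covariates
            else np.full(n, risk12),
            0.0, 1.0,
        )
    p = np.where(groups == "substrate_alone", q1,
                 np.where(groups == "inhibitor_alone", q2, q12))
    outcome = rng.random(n) < p
    return pd.DataFrame(
        {"person_id": [f"S{i:07d}" for i in range(n)],
         "group": groups,
         "outcome": outcome,
         "sex": np.where(female > 0, "F", "M"),
         "age_at_anchor": age,
         "comed_count": np.zeros(n, dtype=int)}
    )
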