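"""Literature screening: retrieval template, sentence patterns, rule engine.

The screen has three layers, mirroring how in vitro CYP interaction evidence
is mined from abstracts:

1. **Information retrieval** (:func:`filter_abstract`): a term template —
   required categories (drug names, enzyme names, probe reagents, assay
   context, assay type) and prohibited terms (oncology vocabulary) — decides
   whether an abstract is screened at all.
2. **Pattern scanning** (:func:`scan_patterns`): six token-order patterns over
   drug (D), enzyme (E) and operator (O1 inhibit / O2 substrate-metabolise /
   O3 induce / INT interaction-verb) symbols, with negation flags:

   ======  ======================  =============================================
   tag     order                   example
   ======  ======================  =============================================
   DEO     D .. E .. O             "midazolam is a cyp3a4 substrate"
   DOE     D .. O .. E             "ketoconazole inhibits cyp3a4"
   EOD     E .. O .. D             "cyp3a4 is inhibited by ketoconazole"
   IDD1    INT between D and D     "no interaction between A and B"
   IDD2    INT D on D              "no impact of A on B"
   DID     D .. INT .. D           "A does not interact with B"
   ======  ======================  =============================================

   The slot-order permutations OED, ODE and EDO are also recognised, with the
   same operator semantics.
3. **Information extraction** (:func:`extract_invitro`): a deterministic rule
   engine standing in for manual curation — assertions are accepted only from
   human liver microsome/hepatocyte or recombinant CYP systems using an
   FDA-listed probe for the enzyme, and negated matches assert nothing.

In vivo study conclusions (:func:`conclude_invivo`) follow the published
decision rule: significance first (p < 0.05), fold-change > 2.0 as fallback
when no p-value is reported; pregnant/newborn studies are excluded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Mapping, Sequence

from .lexicon import (
    ALLOWED_SYSTEMS,
    ENZYME_ALIASES,
    EXPERIMENT_KEY_TERMS,
    EXPERIMENT_TYPE_TERMS,
    INT_TERMS,
    NEG_TERMS,
    O1_TERMS,
    O2_TERMS,
    O3_TERMS,
    PROHIBITED_TERMS,
    is_fda_probe,
    probe_terms,
)

logger = logging.getLogger(__name__)

PatternTag = Literal["DEO", "DOE", "EOD", "OED", "ODE", "EDO", "IDD1", "IDD2", "DID"]

#: default maximum number of intervening tokens between consecutive slots
MAX_GAP = 5


@dataclass(frozen=True)
class ScreenTemplate:
    """Required/prohibited term sets for the retrieval step."""

    drug_terms: frozenset[str]
    enzyme_terms: frozenset[str]
    probe_terms: frozenset[str]
    experiment_key_terms: frozenset[str]
    experiment_type_terms: frozenset[str]
    prohibited_terms: frozenset[str]

    def __post_init__(self) -> None:
        required = (
            self.drug_terms | self.enzyme_terms | self.probe_terms
            | self.experiment_key_terms | self.experiment_type_terms
        )
        if required & self.prohibited_terms:
            raise ValueError("required and prohibited term sets must be disjoint")

    def required_categories(self) -> dict[str, frozenset[str]]:
        return {
            "drug": self.drug_terms,
            "enzyme": self.enzyme_terms,
            "probe": self.probe_terms,
            "experiment_key": self.experiment_key_terms,
            "experiment_type": self.experiment_type_terms,
        }


def default_template(drug_names: Iterable[str]) -> ScreenTemplate:
    """Build the in vitro retrieval template around a drug dictionary."""
    return ScreenTemplate(
        drug_terms=frozenset(d.lower() for d in drug_names),
        enzyme_terms=frozenset(ENZYME_ALIASES),
        probe_terms=probe_terms(),
        experiment_key_terms=EXPERIMENT_KEY_TERMS,
        experiment_type_terms=EXPERIMENT_TYPE_TERMS,
        prohibited_terms=PROHIBITED_TERMS,
    )


@dataclass(frozen=True)
class PatternMatch:
    pattern_tag: str
    sentence_index: int
    drug_slots: tuple[str, ...]
    enzyme_slot: str  # canonical enzyme label, or "" for I-patterns
    operator: str  # one of O1, O2, O3, INT
    negated: bool

    def __post_init__(self) -> None:
        if self.pattern_tag in ("IDD1", "IDD2", "DID"):
            if len(self.drug_slots) < 2 or self.enzyme_slot:
                raise ValueError("I-patterns need >=2 drugs and no enzyme slot")
        else:
            if not self.enzyme_slot:
                raise ValueError(f"{self.pattern_tag} requires an enzyme slot")


@dataclass(frozen=True)
class InVitroEvidence:
    drug: str
    enzyme: str
    assertion: Literal["substrate", "inhibitor"]
    system: str
    probe_used: str
    source_id: str


@dataclass(frozen=True)
class InVivoEvidence:
    substrate: str
    inhibitor: str
    parameter: str = "AUCR"
    p_value: float | None = None
    fold_change: float | None = None
    pregnant: bool = False
    newborn: bool = False


# ---------------------------------------------------------------------------
# Tokenisation and dictionaries
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9][a-z0-9/\-']*")


def tokenize(sentence: str) -> list[str]:
    return _TOKEN_RE.findall(sentence.lower())


def _build_phrase_index(names: Mapping[str, str]) -> dict[tuple[str, ...], str]:
    """Map token tuples to canonical names (longest-match dictionaries)."""
    index: dict[tuple[str, ...], str] = {}
    for surface, canonical in names.items():
        index[tuple(tokenize(surface))] = canonical
    index.pop((), None)
    return index


def _normalize_dict(entries: Iterable[str] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(entries, Mapping):
        return {k.lower(): v for k, v in entries.items()}
    return {e.lower(): e.lower() for e in entries}


@dataclass
class _Sym:
    kind: str  # D, E, O1, O2, O3, INT, NEG, LIT, OTHER
    canonical: str
    pos: int  # slot position (index into symbol list)


def _symbolize(
    tokens: list[str],
    drug_index: dict[tuple[str, ...], str],
    enzyme_index: dict[tuple[str, ...], str],
) -> list[_Sym]:
    """Collapse dictionary phrases (longest match first) and tag symbols."""
    max_len = max(
        [len(k) for k in drug_index] + [len(k) for k in enzyme_index] + [1]
    )
    out: list[_Sym] = []
    i = 0
    while i < len(tokens):
        matched = False
        for L in range(min(max_len, len(tokens) - i), 0, -1):
            span = tuple(tokens[i : i + L])
            if span in drug_index:
                out.append(_Sym("D", drug_index[span], len(out)))
                i += L
                matched = True
                break
            if span in enzyme_index:
                out.append(_Sym("E", enzyme_index[span], len(out)))
                i += L
                matched = True
                break
        if matched:
            continue
        tok = tokens[i]
        if tok in O1_TERMS:
            kind, canon = "O1", tok
        elif tok in O2_TERMS:
            kind, canon = "O2", tok
        elif tok in O3_TERMS:
            kind, canon = "O3", tok
        elif tok in INT_TERMS:
            kind, canon = "INT", tok
        elif tok in NEG_TERMS:
            kind, canon = "NEG", tok
        elif tok in ("between", "and", "on", "by"):
            kind, canon = "LIT", tok
        else:
            kind, canon = "OTHER", tok
        out.append(_Sym(kind, canon, len(out)))
        i += 1
    return out


# ---------------------------------------------------------------------------
# Pattern scanning
# ---------------------------------------------------------------------------

_OP_KINDS = ("O1", "O2", "O3")

# Enzyme-bearing patterns as slot-kind orders; each slot is a set of kinds.
_ENZYME_PATTERNS: dict[str, tuple[str, ...]] = {
    "DEO": ("D", "E", "O"),
    "DOE": ("D", "O", "E"),
    "EOD": ("E", "O", "D"),
    "OED": ("O", "E", "D"),
    "ODE": ("O", "D", "E"),
    "EDO": ("E", "D", "O"),
}


def _find_sequences(
    syms: list[_Sym],
    kinds: tuple[str, ...],
    max_gap: int,
) -> list[list[_Sym]]:
    """Ordered occurrences of a kind sequence with bounded inter-slot gaps."""

    def matches(sym: _Sym, want: str) -> bool:
        if want == "O":
            return sym.kind in _OP_KINDS
        return sym.kind == want

    results: list[list[_Sym]] = []

    def extend(partial: list[_Sym], depth: int, start: int) -> None:
        if depth == len(kinds):
            results.append(partial)
            return
        limit = len(syms) if not partial else min(len(syms), start + max_gap + 1)
        for j in range(start, limit):
            if matches(syms[j], kinds[depth]):
                extend(partial + [syms[j]], depth + 1, j + 1)

    extend([], 0, 0)
    return results


def _negated_between(syms: list[_Sym], first: int, last: int, lookback: int = 2) -> bool:
    lo = max(0, first - lookback)
    return any(s.kind == "NEG" for s in syms[lo : last + 1])


def _absorb_drug_list(syms: list[_Sym], start_pos: int, stop_pos: int) -> tuple[str, ...]:
    """Collect a run of drug mentions (comma/'and'-separated) after a first D."""
    drugs = [syms[start_pos].canonical]
    j = start_pos + 1
    gap = 0
    while j < stop_pos and gap <= 2:
        if syms[j].kind == "D":
            drugs.append(syms[j].canonical)
            gap = 0
        elif syms[j].kind == "LIT" and syms[j].canonical == "and":
            pass
        else:
            gap += 1
        j += 1
    return tuple(dict.fromkeys(drugs))


def scan_patterns(
    sentence: str,
    drug_dict: Iterable[str] | Mapping[str, str],
    enzyme_dict: Iterable[str] | Mapping[str, str] | None = None,
    sentence_index: int = 0,
    max_gap: int = MAX_GAP,
) -> list[PatternMatch]:
    """Scan one sentence for DDI patterns.

    ``drug_dict`` maps surface forms to canonical drug names (or is a plain
    iterable of names); ``enzyme_dict`` defaults to the canonical CYP alias
    table. Matching is case-folded, dictionary longest-match, left-to-right in
    token order, with at most ``max_gap`` intervening tokens between
    consecutive slots. A <not>/<no> token between the first and last slot (or
    immediately before the first) flags the match as negated. Duplicate
    reports for the same (pattern, slot set) are suppressed.
    """
    drugs = _normalize_dict(drug_dict)
    if not drugs:
        raise ValueError("drug dictionary is empty")
    enzymes = _normalize_dict(enzyme_dict if enzyme_dict is not None else ENZYME_ALIASES)
    if not enzymes:
        raise ValueError("enzyme dictionary is empty")
    drug_index = _build_phrase_index(drugs)
    enzyme_index = _build_phrase_index(enzymes)
    syms = _symbolize(tokenize(sentence), drug_index, enzyme_index)

    matches: list[PatternMatch] = []
    seen: set[tuple] = set()

    def emit(tag, drug_slots, enzyme_slot, operator, first, last):
        key = (tag, tuple(sorted(set(drug_slots))), enzyme_slot)
        if key in seen:
            return
        seen.add(key)
        matches.append(
            PatternMatch(
                pattern_tag=tag,
                sentence_index=sentence_index,
                drug_slots=tuple(drug_slots),
                enzyme_slot=enzyme_slot,
                operator=operator,
                negated=_negated_between(syms, first, last),
            )
        )

    # enzyme-bearing patterns
    for tag, kinds in _ENZYME_PATTERNS.items():
        for seq in _find_sequences(syms, kinds, max_gap):
            slot = {k: s for k, s in zip(kinds, seq)}
            op = slot["O"]
            if tag == "EOD" and op.kind == "O2":
                continue  # EOD is defined over inhibit/induce operators
            d_sym = slot["D"]
            if tag == "DEO":
                drug_slots = _absorb_drug_list(syms, d_sym.pos, slot["E"].pos)
            else:
                drug_slots = (d_sym.canonical,)
            emit(tag, drug_slots, slot["E"].canonical, op.kind,
                 seq[0].pos, seq[-1].pos)

    # interaction patterns over two drugs
    for seq in _find_sequences(syms, ("INT", "D", "D"), max_gap):
        i_int, d1, d2 = seq
        between = any(
            s.kind == "LIT" and s.canonical == "between"
            for s in syms[i_int.pos + 1 : d1.pos]
        )
        linked_and = any(
            s.kind == "LIT" and s.canonical == "and"
            for s in syms[d1.pos + 1 : d2.pos]
        )
        linked_on = any(
            s.kind == "LIT" and s.canonical == "on"
            for s in syms[d1.pos + 1 : d2.pos]
        )
        if between and linked_and:
            emit("IDD1", (d1.canonical, d2.canonical), "", "INT",
                 i_int.pos, d2.pos)
        elif linked_on:
            emit("IDD2", (d1.canonical, d2.canonical), "", "INT",
                 i_int.pos, d2.pos)

    for seq in _find_sequences(syms, ("D", "INT", "D"), max_gap):
        d1, i_int, d2 = seq
        emit("DID", (d1.canonical, d2.canonical), "", "INT", d1.pos, d2.pos)

    return matches


def scan_abstract(
    abstract: Mapping,
    drug_dict: Iterable[str] | Mapping[str, str],
    enzyme_dict: Iterable[str] | Mapping[str, str] | None = None,
    max_gap: int = MAX_GAP,
) -> list[PatternMatch]:
    """Scan every sentence of an abstract; concatenates per-sentence matches."""
    out: list[PatternMatch] = []
    for i, sentence in enumerate(abstract.get("sentences", [])):
        out.extend(
            scan_patterns(sentence, drug_dict, enzyme_dict,
                          sentence_index=i, max_gap=max_gap)
        )
    return out


# ---------------------------------------------------------------------------
# Information retrieval
# ---------------------------------------------------------------------------

def filter_abstract(
    abstract: Mapping,
    template: ScreenTemplate,
) -> tuple[bool, dict[str, list[str]]]:
    """Apply the retrieval template to one abstract.

    Retained iff at least one term from *each* required category is present
    (case-insensitive) and no prohibited term occurs. Returns the decision and
    a per-category report of matched terms.
    """
    sentences = abstract.get("sentences", [])
    if not sentences:
        logger.warning("empty abstract %s not retained", abstract.get("id"))
        return False, {}
    tokens = set()
    text_tokens: list[str] = []
    for s in sentences:
        text_tokens.extend(tokenize(s))
    tokens = set(text_tokens)
    # multiword terms are checked on the joined token stream
    joined = " " + " ".join(text_tokens) + " "

    def present(term: str) -> bool:
        if " " in term:
            return f" {' '.join(tokenize(term))} " in joined
        return term in tokens

    report: dict[str, list[str]] = {}
    retained = True
    for category, terms in template.required_categories().items():
        hits = sorted(t for t in terms if present(t))
        report[category] = hits
        if not hits:
            retained = False
    banned = sorted(t for t in template.prohibited_terms if present(t))
    report["prohibited"] = banned
    if banned:
        retained = False
    return retained, report


def estimate_recall(
    retrieval: Callable[[Mapping], bool],
    positives: set[str],
    mixed_corpus: Sequence[Mapping],
) -> float:
    """Fraction of true-positive abstracts selected by a retrieval operation."""
    if not positives:
        raise ValueError("positives must be non-empty")
    corpus_ids = {a["id"] for a in mixed_corpus}
    if not positives <= corpus_ids:
        raise ValueError("positives must be a subset of the corpus ids")
    retrieved = {a["id"] for a in mixed_corpus if retrieval(a)}
    return len(retrieved & positives) / len(positives)


# ---------------------------------------------------------------------------
# Information extraction (in vitro rule engine)
# ---------------------------------------------------------------------------

def extract_invitro(
    matches: Sequence[PatternMatch],
    annotations: Mapping,
) -> list[InVitroEvidence]:
    """Turn pattern matches plus structured assay annotations into evidence.

    Acceptance rules: the assay system must be a human liver
    microsome/hepatocyte or recombinant CYP preparation; the probe used must
    be FDA-listed for the asserted enzyme; negated matches assert nothing.
    Substrate-operator (O2) matches yield substrate assertions; inhibition
    (O1) matches yield inhibitor assertions; induction (O3) and bare
    interaction (INT) matches carry no substrate/inhibitor assertion.
    """
    system = annotations.get("system")
    source_id = annotations.get("source_id", annotations.get("id", ""))
    if system is None:
        if matches:
            logger.warning("annotation for %s lacks an assay system; evidence skipped",
                           source_id or "<unknown>")
        return []
    probe = annotations.get("probe_used", "")
    evidence: list[InVitroEvidence] = []
    emitted: set[tuple] = set()
    if str(system).lower() not in ALLOWED_SYSTEMS:
        return []
    for m in matches:
        if m.negated or not m.enzyme_slot:
            continue
        if m.operator == "O2":
            assertion = "substrate"
        elif m.operator == "O1":
            assertion = "inhibitor"
        else:
            continue
        if not is_fda_probe(probe, m.enzyme_slot):
            continue
        for drug in m.drug_slots:
            key = (drug, m.enzyme_slot, assertion)
            if key in emitted:
                continue
            emitted.add(key)
            evidence.append(
                InVitroEvidence(
                    drug=drug,
                    enzyme=m.enzyme_slot,
                    assertion=assertion,
                    system=str(system).lower(),
                    probe_used=probe,
                    source_id=str(source_id),
                )
            )
    return evidence


# ---------------------------------------------------------------------------
# In vivo conclusions
# ---------------------------------------------------------------------------

def conclude_invivo(
    ev: InVivoEvidence,
    rule: Literal["significance_first", "conjunction"] = "significance_first",
) -> str:
    """Classify an in vivo DDI study as DDI / no-DDI / excluded / indeterminate.

    ``significance_first`` (default): DDI iff p < 0.05;
    when no p-value is reported, DDI iff the fold-change exceeds 2.0.
    ``conjunction``: DDI iff p < 0.05 *and* fold-change > 2.0 (the stricter
    reading used when summarising results).
    Studies in pregnant women or newborns are excluded outright.
    """
    if ev.pregnant or ev.newborn:
        return "excluded"
    if ev.p_value is None and ev.fold_change is None:
        return "indeterminate"
    if rule == "conjunction":
        if ev.p_value is not None and ev.fold_change is not None:
            return "DDI" if (ev.p_value < 0.05 and ev.fold_change > 2.0) else "no-DDI"
        return "no-DDI"
    if ev.p_value is not None:
        return "DDI" if ev.p_value < 0.05 else "no-DDI"
    return "DDI" if ev.fold_change > 2.0 else "no-DDI"
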