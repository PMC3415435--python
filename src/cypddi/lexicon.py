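"""Controlled vocabularies for CYP-mediated DDI screening.

Canonical enzyme labels, operator lexicons for the sentence patterns,
FDA-style probe substrates/inhibitors per enzyme, and term sets used by the
information-retrieval template. These are the field's standard reagent and
keyword lists; they are data, not algorithm.
"""

from __future__ import annotations

# Nine canonical labels; CYP3A4 and CYP3A5 are screened jointly.
CYP_ENZYMES: tuple[str, ...] = (
    "CYP1A2",
    "CYP2A6",
    "CYP2B6",
    "CYP2C8",
    "CYP2C9",
    "CYP2C19",
    "CYP2D6",
    "CYP2E1",
    "CYP3A4/5",
)

# Aliases mapping surface forms to canonical enzyme labels.
ENZYME_ALIASES: dict[str, str] = {
    "cyp3a4": "CYP3A4/5",
    "cyp3a5": "CYP3A4/5",
    "cyp3a": "CYP3A4/5",
    "cyp3a4/5": "CYP3A4/5",
    **{e.lower(): e for e in CYP_ENZYMES},
}

# Operator lexicons. O1: inhibition; O2: substrate/metabolism/catalysis;
# O3: induction; INT: interaction verbs/nouns.
O1_TERMS = frozenset(
    "inhibit inhibits inhibited inhibiting inhibition inhibitor inhibitors".split()
)
O2_TERMS = frozenset(
    "substrate substrates probe probes metabolized metabolised metabolize "
    "metabolizes metabolise metabolises catalyze catalyzes catalyzed "
    "catalyse catalyses catalysed".split()
)
O3_TERMS = frozenset(
    "induce induces induced inducing induction inducer inducers".split()
)
INT_TERMS = frozenset(
    "interaction interactions interact interacts interacted interfere "
    "interferes interference affect affects affected impact impacts".split()
)
NEG_TERMS = frozenset({"not", "no"})

# Selective probe reagents per enzyme (FDA-guidance style lists).
FDA_PROBE_SUBSTRATES: dict[str, tuple[str, ...]] = {
    "CYP1A2": ("phenacetin", "caffeine", "theophylline"),
    "CYP2A6": ("coumarin", "nicotine"),
    "CYP2B6": ("bupropion", "efavirenz"),
    "CYP2C8": ("paclitaxel", "amodiaquine"),
    "CYP2C9": ("tolbutamide", "diclofenac", "warfarin"),
    "CYP2C19": ("mephenytoin", "omeprazole"),
    "CYP2D6": ("dextromethorphan", "bufuralol", "debrisoquine"),
    "CYP2E1": ("chlorzoxazone",),
    "CYP3A4/5": ("midazolam", "testosterone", "nifedipine"),
}

FDA_PROBE_INHIBITORS: dict[str, tuple[str, ...]] = {
    "CYP1A2": ("furafylline", "fluvoxamine"),
    "CYP2A6": ("tranylcypromine", "methoxsalen"),
    "CYP2B6": ("ticlopidine", "clopidogrel"),
    "CYP2C8": ("montelukast", "quercetin", "gemfibrozil"),
    "CYP2C9": ("sulfaphenazole",),
    "CYP2C19": ("ticlopidine", "nootkatone"),
    "CYP2D6": ("quinidine", "paroxetine"),
    "CYP2E1": ("clomethiazole", "diethyldithiocarbamate"),
    "CYP3A4/5": ("ketoconazole", "itraconazole", "troleandomycin"),
}


def probe_terms() -> frozenset[str]:
    """All probe reagent names, lower-cased."""
    out: set[str] = set()
    for terms in FDA_PROBE_SUBSTRATES.values():
        out.update(t.lower() for t in terms)
    for terms in FDA_PROBE_INHIBITORS.values():
        out.update(t.lower() for t in terms)
    return frozenset(out)


def is_fda_probe(name: str, enzyme: str) -> bool:
    """True if ``name`` is a listed probe substrate or inhibitor of ``enzyme``."""
    n = name.lower()
    return n in {p.lower() for p in FDA_PROBE_SUBSTRATES.get(enzyme, ())} or n in {
        p.lower() for p in FDA_PROBE_INHIBITORS.get(enzyme, ())
    }


# Assay-context vocabulary for the retrieval template.
EXPERIMENT_KEY_TERMS = frozenset(
    "microsome microsomes hepatocyte hepatocytes recombinant supersomes "
    "incubation incubated cdna-expressed".split()
)
EXPERIMENT_TYPE_TERMS = frozenset(
    "ki km ic50 vmax kinetics kinetic clearance inhibition metabolism".split()
)
PROHIBITED_TERMS = frozenset(
    "cancer tumor tumour carcinoma chemotherapy oncology xenograft "
    "leukemia lymphoma".split()
)

# Accepted in vitro systems for the information-extraction criteria.
ALLOWED_SYSTEMS = frozenset(
    {"human liver microsome", "human hepatocyte", "recombinant cyp"}
)
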