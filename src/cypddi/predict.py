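"""From enzyme roles to predicted DDI pairs and their potency.

Substrates and inhibitors of the same CYP enzyme are paired to give the
predicted interactions; inhibition potency derives from the inhibition
constant (Ki, µM) — strong < 10, moderate 10–100, weak > 100 — and a pair's
DDI potency combines one drug's metabolism extent with the other's inhibition
potency on a shared enzyme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Potency = Literal["strong", "moderate", "weak", "none"]


@dataclass(frozen=True)
class EnzymeActivity:
    """A drug's role for one CYP enzyme."""

    drug: str
    enzyme: str
    is_substrate: bool
    is_inhibitor: bool
    metabolism_extent: Literal["major", "minor", "none"] = "none"
    ki_um: float | None = None

    def __post_init__(self) -> None:
        if self.metabolism_extent != "none" and not self.is_substrate:
            raise ValueError("metabolism extent implies substrate role")

    @property
    def potency_class(self) -> Potency:
        if not self.is_inhibitor or self.ki_um is None or np.isnan(self.ki_um):
            return "none"
        return classify_potency(self.ki_um)


@dataclass
class PredictedDDI:
    substrate_drug: str
    inhibitor_drug: str
    enzymes: set[str] = field(default_factory=set)
    pair_potency: str | None = None
    comed_count_in_emr: int | None = None

    def __post_init__(self) -> None:
        if self.substrate_drug == self.inhibitor_drug:
            raise ValueError("self-pairs are excluded")

    @property
    def unordered(self) -> tuple[str, str]:
        return tuple(sorted((self.substrate_drug, self.inhibitor_drug)))


def classify_potency(ki_um: float) -> Potency:
    """Bin an inhibition constant: <10 µM strong, 10–100 moderate, >100 weak.

    Boundary values (exactly 10 or 100 µM) fall in the moderate bin.
    """
    if ki_um is None or not ki_um > 0:
        raise ValueError("ki_um must be positive")
    if ki_um < 10:
        return "strong"
    if ki_um <= 100:
        return "moderate"
    return "weak"


def _activities_from_kb(kb: pd.DataFrame | Iterable[EnzymeActivity]) -> list[EnzymeActivity]:
    if isinstance(kb, pd.DataFrame):
        acts = []
        for row in kb.itertuples(index=False):
            role = getattr(row, "role", None)
            is_sub = role in ("substrate", "both") if role is not None else bool(
                getattr(row, "is_substrate")
            )
            is_inh = role in ("inhibitor", "both") if role is not None else bool(
                getattr(row, "is_inhibitor")
            )
            ki = getattr(row, "ki_um", None)
            ki = None if ki is None or (isinstance(ki, float) and np.isnan(ki)) else float(ki)
            extent = getattr(row, "extent", None) or getattr(row, "metabolism_extent", "none")
            if not is_sub:
                extent = "none"
            acts.append(
                EnzymeActivity(
                    drug=str(row.drug), enzyme=str(row.enzyme),
                    is_substrate=is_sub, is_inhibitor=is_inh,
                    metabolism_extent=extent, ki_um=ki,
                )
            )
        return acts
    return list(kb)


def predict_pairs(kb: pd.DataFrame | Iterable[EnzymeActivity]) -> list[PredictedDDI]:
    """Pair every substrate of an enzyme with every inhibitor of that enzyme.

    Directional (substrate, inhibitor) pairs with distinct drugs; pairs sharing
    several enzymes are merged into one record carrying the enzyme set. Output
    is sorted by (substrate, inhibitor).
    """
    acts = _activities_from_kb(kb)
    by_enzyme: dict[str, dict[str, list[str]]] = {}
    for a in acts:
        slot = by_enzyme.setdefault(a.enzyme, {"sub": [], "inh": []})
        if a.is_substrate:
            slot["sub"].append(a.drug)
        if a.is_inhibitor:
            slot["inh"].append(a.drug)
    merged: dict[tuple[str, str], set[str]] = {}
    for enzyme, slot in by_enzyme.items():
        for s in slot["sub"]:
            for i in slot["inh"]:
                if s == i:
                    continue
                merged.setdefault((s, i), set()).add(enzyme)
    return [
        PredictedDDI(substrate_drug=s, inhibitor_drug=i, enzymes=enzymes)
        for (s, i), enzymes in sorted(merged.items())
    ]


def unordered_pair_count(pairs: Iterable[PredictedDDI]) -> int:
    """Number of distinct unordered drug pairs among directional predictions."""
    return len({p.unordered for p in pairs})


def predict_pair_potency(
    pair: PredictedDDI,
    kb: pd.DataFrame | Iterable[EnzymeActivity],
    strong_rule: Literal["strict", "promote_minor"] = "strict",
) -> str:
    """Classify a predicted pair as a strong / moderate / weak DDI.

    Over every shared enzyme and both drug orderings: strong if one drug's
    major metabolism route meets the other drug's strong inhibition; moderate
    if major meets moderate inhibition, or minor meets strong inhibition.
    Otherwise weak. ``strong_rule="promote_minor"`` additionally promotes
    minor-metabolism + strong-inhibition to strong (an alternative reading of
    published pair classifications; the default follows the stated rule).
    Missing extent or potency information degrades to weak with a warning.
    """
    acts = _activities_from_kb(kb)
    idx: dict[tuple[str, str], EnzymeActivity] = {
        (a.drug, a.enzyme): a for a in acts
    }
    levels = {"weak": 0, "moderate": 1, "strong": 2}
    best = "weak"
    found_info = False
    for enzyme in sorted(pair.enzymes):
        for metab_drug, inhib_drug in (
            (pair.substrate_drug, pair.inhibitor_drug),
            (pair.inhibitor_drug, pair.substrate_drug),
        ):
            a_m = idx.get((metab_drug, enzyme))
            a_i = idx.get((inhib_drug, enzyme))
            if a_m is None or a_i is None:
                continue
            extent = a_m.metabolism_extent
            potency = a_i.potency_class
            if extent == "none" or potency == "none":
                continue
            found_info = True
            if extent == "major" and potency == "strong":
                verdict = "strong"
            elif extent == "minor" and potency == "strong":
                verdict = "strong" if strong_rule == "promote_minor" else "moderate"
            elif extent == "major" and potency == "moderate":
                verdict = "moderate"
            else:
                verdict = "weak"
            if levels[verdict] > levels[best]:
                best = verdict
    if not found_info:
        logger.warning(
            "pair (%s, %s): no extent/potency information on shared enzymes; weak",
            pair.substrate_drug, pair.inhibitor_drug,
        )
    return best


def crossref_emr(
    pairs: list[PredictedDDI],
    drug_exposure: pd.DataFrame,
    window_days: int = 30,
) -> list[PredictedDDI]:
    """Annotate predicted pairs with EMR co-medication counts.

    ``comed_count_in_emr`` is the number of patients with dispensings of both
    drugs at most ``window_days`` apart. Pairs never co-dispensed keep count 0
    and are excluded from downstream testing.
    """
    rx = drug_exposure.copy()
    rx["start_date"] = pd.to_datetime(rx["start_date"])
    vocab = set(rx["drug_name"].unique())
    by_drug = {d: g[["person_id", "start_date"]] for d, g in rx.groupby("drug_name")}
    for pair in pairs:
        a, b = pair.substrate_drug, pair.inhibitor_drug
        if a not in vocab or b not in vocab:
            logger.warning("pair (%s, %s): drug absent from EMR vocabulary", a, b)
            pair.comed_count_in_emr = 0
            continue
        m = by_drug[a].merge(by_drug[b], on="person_id", suffixes=("_a", "_b"))
        if m.empty:
            pair.comed_count_in_emr = 0
            continue
        close = (m["start_date_a"] - m["start_date_b"]).abs() <= pd.Timedelta(
            days=window_days
        )
        pair.comed_count_in_emr = int(m.loc[close, "person_id"].nunique())
    return pairs
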