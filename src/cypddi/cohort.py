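"""Exposure-window cohort construction from EMR tables.

For each candidate (substrate, inhibitor) pair, three exposure cohorts are
built. Cases are anchored at the myopathy diagnosis date: any pair drug
dispensed within the closed 30-day look-back window [anchor-30d, anchor]
counts as exposure, and the window content decides the group (substrate
alone / inhibitor alone / joint). Controls (persons never diagnosed with a
myopathy concept) are anchored at a dispensing: joint when the two drugs were
dispensed at most 30 days apart, otherwise the single-drug group. The
co-medication burden of an episode is the number of distinct drugs dispensed
in its window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_DAYS = 30
EXCLUSION_DAYS = 183  # "first 6 months of the database"

Group = Literal["substrate_alone", "inhibitor_alone", "joint"]

EPISODE_COLUMNS = [
    "person_id", "drug1", "drug2", "group", "anchor_date", "outcome",
    "age_at_anchor", "sex", "comed_count", "event_rank",
]


def default_myopathy_concepts() -> list[str]:
    """Myopathy concept names shipped with the package (editable text file)."""
    text = (
        resources.files("cypddi.data").joinpath("myopathy_concepts.txt").read_text()
    )
    return [
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@dataclass
class ExclusionLog:
    early_myopathy_persons: int = 0
    treatment_pair_excluded: bool = False
    episodes_removed: int = 0

    def as_dict(self) -> dict:
        return {
            "early_myopathy_persons": self.early_myopathy_persons,
            "treatment_pair_excluded": self.treatment_pair_excluded,
            "episodes_removed": self.episodes_removed,
        }


def _prepare(emr) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    person = emr.person.copy()
    rx = emr.drug_exposure.copy()
    cond = emr.condition_occurrence.copy()
    rx["start_date"] = pd.to_datetime(rx["start_date"], errors="coerce")
    cond["event_date"] = pd.to_datetime(cond["event_date"], errors="coerce")
    n_bad = int(cond["event_date"].isna().sum())
    if n_bad:
        logger.warning("%d condition rows had unparsable dates and were skipped", n_bad)
        cond = cond.dropna(subset=["event_date"])
    n_bad = int(rx["start_date"].isna().sum())
    if n_bad:
        logger.warning("%d dispensing rows had unparsable dates and were skipped", n_bad)
        rx = rx.dropna(subset=["start_date"])
    return person, rx, cond


def build_episodes(
    emr,
    pair: tuple[str, str],
    concept_set: Iterable[str] | None = None,
    mode: Literal["all_events", "first_event"] = "all_events",
    window_days: int = WINDOW_DAYS,
) -> pd.DataFrame:
    """Build exposure episodes for one (substrate, inhibitor) pair.

    Returns a DataFrame with one row per episode (columns
    :data:`EPISODE_COLUMNS`). Group labels per anchor are mutually exclusive.
    ``mode="first_event"`` keeps only each person's earliest myopathy anchor.
    Persons with a myopathy diagnosis but no pair drug in any look-back window
    contribute nothing (they are exposed-unanchored or unexposed cases, not
    controls).
    """
    drug1, drug2 = pair
    if drug1 == drug2:
        raise ValueError("pair drugs must be distinct")
    concepts = list(concept_set) if concept_set is not None else default_myopathy_concepts()
    if not concepts:
        raise ValueError("concept set must be non-empty")
    person, rx, cond = _prepare(emr)
    window = pd.Timedelta(days=window_days)

    concepts_lower = {c.lower() for c in concepts}
    myo = cond[cond["concept_name"].str.lower().isin(concepts_lower)]
    myo_persons = set(myo["person_id"].unique())

    rx_pair = rx[rx["drug_name"].isin([drug1, drug2])]

    records: list[dict] = []

    # --- case episodes: anchored at myopathy dates ---
    anchors = myo[["person_id", "event_date"]].drop_duplicates()
    if mode == "first_event":
        anchors = anchors.sort_values("event_date").groupby("person_id", as_index=False).first()
    cases = anchors.merge(rx_pair, on="person_id", how="inner")
    delta = cases["event_date"] - cases["start_date"]
    in_window = (delta >= pd.Timedelta(0)) & (delta <= window)
    cases = cases[in_window]
    if not cases.empty:
        flags = (
            cases.assign(
                has1=cases["drug_name"] == drug1,
                has2=cases["drug_name"] == drug2,
            )
            .groupby(["person_id", "event_date"])[["has1", "has2"]]
            .any()
            .reset_index()
        )
        first_anchor = flags.groupby("person_id")["event_date"].transform("min")
        for row, first in zip(flags.itertuples(index=False), first_anchor):
            if row.has1 and row.has2:
                group = "joint"
            elif row.has1:
                group = "substrate_alone"
            else:
                group = "inhibitor_alone"
            records.append(
                {"person_id": row.person_id, "anchor_date": row.event_date,
                 "group": group, "outcome": True,
                 "event_rank": "first" if row.event_date == first else "subsequent"}
            )

    # --- control episodes: persons with no myopathy concept at all ---
    rx_ctrl = rx_pair[~rx_pair["person_id"].isin(myo_persons)]
    d1 = rx_ctrl[rx_ctrl["drug_name"] == drug1]
    d2 = rx_ctrl[rx_ctrl["drug_name"] == drug2]
    joint = d1.merge(d2, on="person_id", suffixes=("_1", "_2"))
    joint_anchor: dict = {}
    if not joint.empty:
        gap = (joint["start_date_1"] - joint["start_date_2"]).abs()
        joint = joint[gap <= window]
        if not joint.empty:
            joint["anchor"] = joint[["start_date_1", "start_date_2"]].max(axis=1)
            joint_anchor = joint.groupby("person_id")["anchor"].min().to_dict()
    for pid, anchor in joint_anchor.items():
        records.append(
            {"person_id": pid, "anchor_date": anchor, "group": "joint",
             "outcome": False, "event_rank": "control"}
        )
    # without a joint overlap, a person with both drugs contributes substrate
    # exposure only ("otherwise only substrate exposure is defined")
    sub_solo = d1[~d1["person_id"].isin(joint_anchor)]
    inh_solo = d2[
        ~d2["person_id"].isin(joint_anchor)
        & ~d2["person_id"].isin(set(d1["person_id"]))
    ]
    for df, group in ((sub_solo, "substrate_alone"), (inh_solo, "inhibitor_alone")):
        if df.empty:
            continue
        first_disp = df.groupby("person_id")["start_date"].min()
        for pid, anchor in first_disp.items():
            records.append(
                {"person_id": pid, "anchor_date": anchor, "group": group,
                 "outcome": False, "event_rank": "control"}
            )

    episodes = pd.DataFrame(records)
    if episodes.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    episodes["drug1"] = drug1
    episodes["drug2"] = drug2
    episodes = episodes.merge(person[["person_id", "sex", "birth_year"]],
                              on="person_id", how="left")
    episodes["age_at_anchor"] = (
        episodes["anchor_date"].dt.year - episodes["birth_year"]
    ).astype(float)
    episodes["comed_count"] = _comed_counts(rx, episodes, window_days)
    episodes = episodes.sort_values(
        ["group", "person_id", "anchor_date"], kind="stable"
    ).reset_index(drop=True)
    return episodes[EPISODE_COLUMNS]


def _comed_counts(
    rx: pd.DataFrame,
    episodes: pd.DataFrame,
    window_days: int,
    include_index: bool = True,
    index_drugs: tuple[str, ...] = (),
) -> pd.Series:
    window = pd.Timedelta(days=window_days)
    merged = episodes.reset_index()[["index", "person_id", "anchor_date"]].merge(
        rx, on="person_id", how="left"
    )
    delta = merged["anchor_date"] - merged["start_date"]
    merged = merged[(delta >= pd.Timedelta(0)) & (delta <= window)]
    if not include_index and index_drugs:
        merged = merged[~merged["drug_name"].isin(index_drugs)]
    counts = merged.groupby("index")["drug_name"].nunique()
    return (
        counts.reindex(range(len(episodes)), fill_value=0).astype(int).values
    )


def count_comeds(
    emr,
    episode,
    window_days: int = WINDOW_DAYS,
    include_index: bool = True,
    index_drugs: tuple[str, ...] = (),
) -> int:
    """Distinct drugs dispensed in one episode's window.

    By default the index pair drugs are counted (total number of different
    medications ordered in the window); ``include_index=False`` with
    ``index_drugs`` removes them.
    """
    _, rx, _ = _prepare(emr)
    anchor = pd.Timestamp(episode["anchor_date"])
    window = pd.Timedelta(days=window_days)
    mask = (
        (rx["person_id"] == episode["person_id"])
        & (anchor - rx["start_date"] >= pd.Timedelta(0))
        & (anchor - rx["start_date"] <= window)
    )
    drugs = set(rx.loc[mask, "drug_name"])
    if not include_index:
        drugs -= set(index_drugs)
    return len(drugs)


def apply_exclusions(
    episodes: pd.DataFrame,
    db_start,
    treatment_drugs: Iterable[str] = (),
    conditions: pd.DataFrame | None = None,
    exclusion_days: int = EXCLUSION_DAYS,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the early-myopathy and myopathy-treatment-pair exclusions.

    Persons whose *first* myopathy event falls within ``exclusion_days`` of
    the database start are removed entirely (their prior history is
    unobservable). The first event is taken from the full condition table when
    given, else from the case anchors present in ``episodes``. If either pair
    drug is a myopathy-treatment drug, the whole pair is flagged excluded and
    an empty frame is returned (episodes remain valid for other pairs).
    """
    log = ExclusionLog()
    if episodes.empty:
        return episodes, log
    db_start = pd.Timestamp(db_start)
    cutoff = db_start + pd.Timedelta(days=exclusion_days)

    treatment = set(treatment_drugs)
    pair = {episodes["drug1"].iloc[0], episodes["drug2"].iloc[0]}
    if pair & treatment:
        log.treatment_pair_excluded = True
        log.episodes_removed = len(episodes)
        return episodes.iloc[0:0], log

    if conditions is not None:
        cond = conditions.copy()
        cond["event_date"] = pd.to_datetime(cond["event_date"])
        first = cond.groupby("person_id")["event_date"].min()
    else:
        case_rows = episodes[episodes["outcome"]]
        first = case_rows.groupby("person_id")["anchor_date"].min()
    early_persons = set(first[first < cutoff].index)
    keep = ~episodes["person_id"].isin(early_persons)
    log.early_myopathy_persons = len(
        early_persons & set(episodes["person_id"].unique())
    )
    log.episodes_removed = int((~keep).sum())
    return episodes[keep].reset_index(drop=True), log
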