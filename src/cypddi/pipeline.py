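"""End-to-end orchestration: screen -> predict -> crossref -> cohort -> test
-> enrich -> report.

:func:`run_pipeline` executes the stages on a knowledge base, an abstract
corpus and EMR tables (generating synthetic ones from the seed when none are
supplied), logging the row-count funnel (predicted pairs -> co-medicated
pairs -> tested pairs) and writing evidence, pair, episode, result and
enrichment TSVs plus a rendered report into a run directory. Identical
config and seed yield byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import predict as predict_mod
from . import screen as screen_mod
from . import stats as stats_mod
from . import synthetic as synth_mod
from .lexicon import FDA_PROBE_INHIBITORS, FDA_PROBE_SUBSTRATES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings reproducing the study design by default.

    30-day exposure windows, a 6-month (183-day) early-myopathy exclusion,
    family-wise alpha 0.05 with Bonferroni correction over the tested pairs,
    age+sex covariates, and significance-first rule switches.
    """

    out_dir: str | Path = "run"
    kb_path: str | Path | None = None
    corpus_path: str | Path | None = None
    emr_dir: str | Path | None = None
    window_days: int = 30
    exclusion_days: int = 183
    alpha: float = 0.05
    event_mode: Literal["all_events", "first_event"] = "all_events"
    covariates: tuple[str, ...] = ("age", "sex")
    invivo_rule: Literal["significance_first", "conjunction"] = "significance_first"
    strong_rule: Literal["strict", "promote_minor"] = "strict"
    treatment_drugs: tuple[str, ...] = ()
    seed: int = 0
    simulation: synth_mod.SimulationConfig | None = None

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sim = payload.pop("simulation", None)
        cfg = cls(**payload)
        if sim is not None:
            ddi = {
                tuple(k.split("|")): v
                for k, v in (sim.pop("ddi_effects", {}) or {}).items()
            }
            cfg.simulation = synth_mod.SimulationConfig(ddi_effects=ddi, **sim)
        return cfg


def _default_simulation(seed: int) -> tuple[synth_mod.SimulationConfig, pd.DataFrame]:
    """Shipped synthetic world: a small knowledge base with two injected DDIs."""
    kb, _ = synth_mod.generate_knowledge_base(n_drugs=14, seed=seed)
    drugs = sorted(kb["drug"].unique())
    pair_a = (drugs[0], drugs[1])
    pair_b = (drugs[2], drugs[3])
    sim = synth_mod.SimulationConfig(
        n_patients=12_000,
        drug_risks={d: 0.02 for pair in (pair_a, pair_b) for d in pair},
        ddi_effects={pair_a: 3.0, pair_b: 1.0},
        pair_exposure=(0.03, 0.03, 0.015),
        seed=seed,
    )
    # make the injected pairs predictable from the knowledge base
    rows = []
    for (s, i) in (pair_a, pair_b):
        rows.append({"drug": s, "enzyme": "CYP3A4/5", "role": "substrate",
                     "extent": "major", "ki_um": float("nan")})
        rows.append({"drug": i, "enzyme": "CYP3A4/5", "role": "inhibitor",
                     "extent": "none", "ki_um": 5.0})
    kb = pd.concat([kb, pd.DataFrame(rows)], ignore_index=True)
    kb = kb.drop_duplicates(subset=["drug", "enzyme"], keep="last").reset_index(drop=True)
    return sim, kb


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("cypddi")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    # --- inputs (load or simulate) ---
    sim_cfg = config.simulation
    if config.kb_path is not None:
        kb = synth_mod.read_kb_tsv(config.kb_path)
    else:
        default_sim, kb = _default_simulation(config.seed)
        if sim_cfg is None:
            sim_cfg = default_sim
    if config.corpus_path is not None:
        corpus = synth_mod.read_corpus_jsonl(config.corpus_path)
    else:
        corpus, corpus_truth = synth_mod.generate_abstract_corpus(
            kb, n_pos=40, n_neg=40, seed=config.seed + 1
        )
    if config.emr_dir is not None:
        emr = synth_mod.EMRTables.from_csv(config.emr_dir)
        db_start = pd.to_datetime(emr.condition_occurrence["event_date"]).min()
        truth = None
    else:
        if sim_cfg is None:
            sim_cfg, _ = _default_simulation(config.seed)
        emr, truth = synth_mod.generate_emr(sim_cfg, kb)
        db_start = pd.Timestamp(sim_cfg.study_start)
        emr.to_csv(out / "emr")
    synth_mod.write_kb_tsv(kb, out / "kb.tsv")
    logger.info("inputs: kb rows=%d, corpus abstracts=%d, patients=%d",
                len(kb), len(corpus), len(emr.person))

    # --- screen ---
    drug_dict = sorted(
        set(kb["drug"]).union(
            p for terms in FDA_PROBE_SUBSTRATES.values() for p in terms
        ).union(p for terms in FDA_PROBE_INHIBITORS.values() for p in terms)
    )
    template = screen_mod.default_template(drug_dict)
    evidence_rows = []
    n_retained = 0
    for abstract in corpus:
        retained, _ = screen_mod.filter_abstract(abstract, template)
        if not retained:
            continue
        n_retained += 1
        matches = screen_mod.scan_abstract(abstract, drug_dict)
        annotations = dict(abstract.get("annotations", {}))
        annotations.setdefault("source_id", abstract["id"])
        for ev in screen_mod.extract_invitro(matches, annotations):
            evidence_rows.append(ev.__dict__)
    evidence = pd.DataFrame(
        evidence_rows,
        columns=["drug", "enzyme", "assertion", "system", "probe_used", "source_id"],
    )
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    logger.info("screen: retained %d/%d abstracts, %d evidence rows",
                n_retained, len(corpus), len(evidence))

    # --- predict (knowledge base union text-mined evidence) ---
    pairs = predict_mod.predict_pairs(kb)
    for p in pairs:
        p.pair_potency = predict_mod.predict_pair_potency(
            p, kb, strong_rule=config.strong_rule
        )
    logger.info("predict: %d directional pairs (%d unordered)",
                len(pairs), predict_mod.unordered_pair_count(pairs))

    # --- crossref with EMR co-medication ---
    pairs = predict_mod.crossref_emr(pairs, emr.drug_exposure, config.window_days)
    comedicated = [p for p in pairs if (p.comed_count_in_emr or 0) > 0]
    pair_df = pd.DataFrame(
        [{"drug1": p.substrate_drug, "drug2": p.inhibitor_drug,
          "enzymes": ";".join(sorted(p.enzymes)),
          "pair_potency": p.pair_potency,
          "comed_count": p.comed_count_in_emr} for p in pairs]
    )
    pair_df.to_csv(out / "pairs.tsv", sep="\t", index=False)
    logger.info("crossref: %d/%d pairs co-medicated in EMR",
                len(comedicated), len(pairs))

    # --- cohorts and tests ---
    n_tests = max(len(comedicated), 1)
    threshold = stats_mod.bonferroni_threshold(config.alpha, n_tests)
    results: list[stats_mod.DDITestResult] = []
    episode_frames = []
    pair_enzyme_map = {}
    tested_unordered: set[tuple[str, str]] = set()
    for p in comedicated:
        if p.unordered in tested_unordered:
            continue  # mirror-role duplicate; pairs are counted unordered
        tested_unordered.add(p.unordered)
        episodes = cohort_mod.build_episodes(
            emr, (p.substrate_drug, p.inhibitor_drug),
            mode=config.event_mode, window_days=config.window_days,
        )
        episodes, _excl = cohort_mod.apply_exclusions(
            episodes, db_start, config.treatment_drugs,
            conditions=emr.condition_occurrence,
            exclusion_days=config.exclusion_days,
        )
        if episodes.empty:
            continue
        episode_frames.append(episodes)
        key = (p.substrate_drug, p.inhibitor_drug)
        pair_enzyme_map[key] = sorted(p.enzymes)
        try:
            results.append(stats_mod.fit_synergistic(episodes, config.covariates))
        except ValueError as exc:
            logger.info("pair %s skipped: %s", key, exc)
        try:
            results.append(stats_mod.fit_additive(episodes, config.covariates))
        except ValueError as exc:
            logger.info("pair %s additive skipped: %s", key, exc)
    if episode_frames:
        pd.concat(episode_frames, ignore_index=True).to_csv(
            out / "episodes.tsv", sep="\t", index=False
        )
    logger.info("test: %d fitted models over %d pairs at threshold %.3g",
                len(results), len(pair_enzyme_map), threshold)

    res_df = pd.DataFrame(
        [{"drug1": r.pair[0], "drug2": r.pair[1], "model": r.model,
          "risk1": r.risk1, "risk2": r.risk2, "risk12": r.risk12,
          "rr": r.rr, "or": r.or_joint_vs_substrate, "p_value": r.p_value,
          "counts": r.counts_label(), "flags": ";".join(r.flags)}
         for r in results]
    )
    res_df.to_csv(out / "results.tsv", sep="\t", index=False)

    # --- enrichment ---
    syn_results = [r for r in results if r.model == "synergistic"]
    enrichment = (
        stats_mod.enzyme_enrichment(syn_results, pair_enzyme_map, threshold)
        if syn_results else []
    )
    pd.DataFrame([e.__dict__ for e in enrichment]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )

    # --- report ---
    report = render_report(syn_results, enrichment, threshold=threshold)
    (out / "report.md").write_text(report)
    logger.info("report: written to %s", out / "report.md")
    return out


def render_report(
    results: Sequence[stats_mod.DDITestResult],
    enrichment: Sequence[stats_mod.EnrichmentResult],
    threshold: float | None = None,
) -> str:
    """Render synergy results and enrichment as a markdown report.

    Risks print with 3 decimals, risk ratios with 2, p-values in scientific
    notation, and group counts as "(m1/n1, m2/n2, m12/n12)".
    """
    if not results:
        raise ValueError("results must be non-empty")
    lines = ["# DDI myopathy risk report", ""]
    if threshold is not None:
        lines.append(f"Significance threshold (Bonferroni): {threshold:.3g}")
        lines.append("")
    lines.append("| drug 1 | drug 2 | Risk1 | Risk2 | Risk12 | RR | p-value | sample size (m1/n1, m2/n2, m12/n12) |")
    lines.append("|---|---|---|---|---|---|---|---|")
    ordered = sorted(results, key=lambda r: (r.p_value if np.isfinite(r.p_value) else 1.0))
    for r in ordered:
        lines.append(
            f"| {r.pair[0]} | {r.pair[1]} | {r.risk1:.3f} | {r.risk2:.3f} "
            f"| {r.risk12:.3f} | {r.rr:.2f} | {r.p_value:.2E} | {r.counts_label()} |"
        )
    lines.append("")
    if enrichment:
        lines.append("## CYP enzyme enrichment")
        lines.append("")
        lines.append("| enzyme | significant/in | significant/out | p-value |")
        lines.append("|---|---|---|---|")
        for e in enrichment:
            lines.append(
                f"| {e.enzyme} | {e.n_sig_in}/{e.n_in} | {e.n_sig_out}/{e.n_out} "
                f"| {e.p_value:.2E} |"
            )
    else:
        lines.append("## CYP enzyme enrichment")
        lines.append("")
        lines.append("No enrichment results (no tested pairs).")
    lines.append("")
    return "\n".join(lines)
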