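"""Retrieval template, pattern scanner, rule engine, and recall estimation."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

import cypddi
from cypddi.lexicon import probe_terms
from cypddi.screen import InVivoEvidence, ScreenTemplate

DRUGS = ["ketoconazole", "midazolam", "aspirin", "warfarin", "quinidine"]


class TestScanPatterns:
    @pytest.mark.parametrize(
        "sentence,tag,drugs,enzyme,negated",
        [
            ("ketoconazole inhibits CYP3A4", "DOE", ("ketoconazole",), "CYP3A4/5", False),
            ("midazolam is a CYP3A4 substrate", "DEO", ("midazolam",), "CYP3A4/5", False),
            ("CYP2D6 is inhibited by quinidine", "EOD", ("quinidine",), "CYP2D6", False),
            ("there is not interaction between aspirin and warfarin",
             "IDD1", ("aspirin", "warfarin"), "", True),
            ("no impact of ketoconazole on midazolam pharmacokinetics",
             "IDD2", ("ketoconazole", "midazolam"), "", True),
            ("aspirin does not interact with warfarin",
             "DID", ("aspirin", "warfarin"), "", True),
            ("midazolam was not a CYP3A4 substrate", "DEO", ("midazolam",),
             "CYP3A4/5", True),
        ],
    )
    def test_pattern_examples(self, sentence, tag, drugs, enzyme, negated):
        matches = cypddi.scan_patterns(sentence, DRUGS)
        hits = [m for m in matches if m.pattern_tag == tag]
        assert len(hits) == 1
        m = hits[0]
        assert set(drugs) <= set(m.drug_slots)
        assert m.enzyme_slot == enzyme
        assert m.negated is negated

    def test_unmatched_sentence_yields_empty_list(self):
        assert cypddi.scan_patterns("the weather was mild in march", DRUGS) == []

    def test_gap_limit_respected(self):
        far = ("ketoconazole " + "strongly very quite rather surprisingly much "
               "inhibits CYP3A4")
        assert cypddi.scan_patterns(far, DRUGS, max_gap=3) == []
        assert cypddi.scan_patterns(far, DRUGS, max_gap=8) != []

    def test_multi_drug_list_in_deo(self):
        s = "ketoconazole and midazolam are CYP3A4 substrates"
        matches = cypddi.scan_patterns(s, DRUGS)
        deo = [m for m in matches if m.pattern_tag == "DEO"][0]
        assert set(deo.drug_slots) == {"ketoconazole", "midazolam"}

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            cypddi.scan_patterns("anything", [])

    def test_scanner_recall_is_one_on_generated_corpus(self, small_kb, labelled_corpus):
        corpus, truth = labelled_corpus
        dd = sorted(set(small_kb["drug"]) | probe_terms())
        per_tag_truth: dict = {}
        per_tag_scan: dict = {}
        for abstract in corpus:
            label = truth.abstract_labels[abstract["id"]]
            matches = cypddi.scan_abstract(abstract, dd)
            if label["relevant"]:
                assert matches, f"positive abstract {abstract['id']} missed"
                tags = {m.pattern_tag for m in matches}
                assert label["pattern"] in tags
                per_tag_truth[label["pattern"]] = per_tag_truth.get(label["pattern"], 0) + 1
                for m in matches:
                    per_tag_scan[m.pattern_tag] = per_tag_scan.get(m.pattern_tag, 0) + 1
            else:
                assert matches == []
        assert per_tag_scan == per_tag_truth


class TestFilterAbstract:
    def _template(self):
        return cypddi.default_template(DRUGS)

    def _good_abstract(self):
        return {
            "id": "a1",
            "sentences": [
                "midazolam is a cyp3a4 substrate",
                "incubation used human liver microsome preparations",
                "apparent ki values were estimated",
            ],
        }

    def test_retained_with_all_categories(self):
        retained, report = cypddi.filter_abstract(self._good_abstract(), self._template())
        assert retained
        assert report["drug"] and report["enzyme"] and report["probe"]

    def test_prohibited_term_rejects(self):
        a = self._good_abstract()
        a["sentences"].append("findings relevant to carcinoma biology")
        retained, report = cypddi.filter_abstract(a, self._template())
        assert not retained
        assert "carcinoma" in report["prohibited"]

    def test_empty_abstract_not_retained(self):
        retained, _ = cypddi.filter_abstract({"id": "x", "sentences": []}, self._template())
        assert not retained

    def test_retained_set_covers_positives(self, small_kb, labelled_corpus):
        corpus, truth = labelled_corpus
        template = cypddi.default_template(sorted(set(small_kb["drug"]) | probe_terms()))
        retained = {a["id"] for a in corpus if cypddi.filter_abstract(a, template)[0]}
        positives = {k for k, v in truth.abstract_labels.items() if v["relevant"]}
        assert positives <= retained

    def test_monotone_in_template_terms(self, small_kb, labelled_corpus):
        """Adding prohibited terms or removing required terms never retains more."""
        corpus, _ = labelled_corpus
        base = cypddi.default_template(sorted(set(small_kb["drug"]) | probe_terms()))
        kept_base = {a["id"] for a in corpus if cypddi.filter_abstract(a, base)[0]}
        more_banned = ScreenTemplate(
            drug_terms=base.drug_terms, enzyme_terms=base.enzyme_terms,
            probe_terms=base.probe_terms,
            experiment_key_terms=base.experiment_key_terms,
            experiment_type_terms=base.experiment_type_terms,
            prohibited_terms=base.prohibited_terms | {"reference"},
        )
        kept_banned = {a["id"] for a in corpus if cypddi.filter_abstract(a, more_banned)[0]}
        assert kept_banned <= kept_base
        fewer_required = ScreenTemplate(
            drug_terms=base.drug_terms, enzyme_terms=base.enzyme_terms,
            probe_terms=base.probe_terms,
            experiment_key_terms=frozenset({"hepatocyte"}),  # drop the other terms
            experiment_type_terms=base.experiment_type_terms,
            prohibited_terms=base.prohibited_terms,
        )
        kept_fewer = {a["id"] for a in corpus if cypddi.filter_abstract(a, fewer_required)[0]}
        assert kept_fewer <= kept_base

    def test_required_prohibited_disjointness_enforced(self):
        with pytest.raises(ValueError):
            ScreenTemplate(
                drug_terms=frozenset({"drugx"}), enzyme_terms=frozenset({"cyp3a4"}),
                probe_terms=frozenset({"midazolam"}),
                experiment_key_terms=frozenset({"microsome"}),
                experiment_type_terms=frozenset({"ki"}),
                prohibited_terms=frozenset({"drugx"}),
            )


class TestExtractInvitro:
    def _doe_match(self, negated=False):
        return cypddi.PatternMatch(
            pattern_tag="DOE", sentence_index=0, drug_slots=("ketoconazole",),
            enzyme_slot="CYP2D6", operator="O1", negated=negated,
        )

    def test_inhibitor_evidence_from_valid_system_and_probe(self):
        ev = cypddi.extract_invitro(
            [self._doe_match()],
            {"system": "recombinant cyp", "probe_used": "dextromethorphan",
             "source_id": "a9"},
        )
        assert len(ev) == 1
        assert ev[0].assertion == "inhibitor"
        assert ev[0].enzyme == "CYP2D6"

    def test_non_human_system_rejected(self):
        ev = cypddi.extract_invitro(
            [self._doe_match()],
            {"system": "rat microsome", "probe_used": "dextromethorphan"},
        )
        assert ev == []

    def test_non_probe_rejected(self):
        ev = cypddi.extract_invitro(
            [self._doe_match()],
            {"system": "recombinant cyp", "probe_used": "obscurol"},
        )
        assert ev == []

    def test_negated_match_asserts_nothing(self):
        ev = cypddi.extract_invitro(
            [self._doe_match(negated=True)],
            {"system": "recombinant cyp", "probe_used": "dextromethorphan"},
        )
        assert ev == []

    def test_missing_system_warns_and_skips(self, caplog):
        with caplog.at_level(logging.WARNING, logger="cypddi.screen"):
            ev = cypddi.extract_invitro([self._doe_match()], {"source_id": "a1"})
        assert ev == []
        assert any("assay system" in r.message for r in caplog.records)

    def test_substrate_operator_yields_substrate(self):
        m = cypddi.PatternMatch(
            pattern_tag="DEO", sentence_index=0, drug_slots=("midazolam",),
            enzyme_slot="CYP3A4/5", operator="O2", negated=False,
        )
        ev = cypddi.extract_invitro(
            [m], {"system": "human hepatocyte", "probe_used": "ketoconazole"}
        )
        assert ev[0].assertion == "substrate"


class TestConcludeInvivo:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(p_value=0.03, fold_change=1.5), "DDI"),
            (dict(p_value=None, fold_change=2.5), "DDI"),
            (dict(p_value=0.2, fold_change=3.0), "no-DDI"),  # p present wins
            (dict(p_value=None, fold_change=1.5), "no-DDI"),
            (dict(p_value=0.001, pregnant=True), "excluded"),
            (dict(newborn=True), "excluded"),
            (dict(), "indeterminate"),
        ],
    )
    def test_significance_first_rule(self, kwargs, expected):
        ev = InVivoEvidence(substrate="a", inhibitor="b", **kwargs)
        assert cypddi.conclude_invivo(ev) == expected

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(p_value=0.03, fold_change=2.5), "DDI"),
            (dict(p_value=0.03, fold_change=1.5), "no-DDI"),
            (dict(p_value=None, fold_change=2.5), "no-DDI"),
        ],
    )
    def test_conjunction_rule(self, kwargs, expected):
        ev = InVivoEvidence(substrate="a", inhibitor="b", **kwargs)
        assert cypddi.conclude_invivo(ev, rule="conjunction") == expected

    @given(
        p=st.one_of(st.none(), st.floats(0, 1)),
        fold=st.one_of(st.none(), st.floats(0, 10)),
        preg=st.booleans(),
        newborn=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_outcomes_partition(self, p, fold, preg, newborn):
        ev = InVivoEvidence("a", "b", p_value=p, fold_change=fold,
                            pregnant=preg, newborn=newborn)
        out = cypddi.conclude_invivo(ev)
        assert out in {"DDI", "no-DDI", "excluded", "indeterminate"}
        if preg or newborn:
            assert out == "excluded"
        elif p is None and fold is None:
            assert out == "indeterminate"


class TestEstimateRecall:
    def test_counting(self, labelled_corpus):
        corpus, truth = labelled_corpus
        positives = {k for k, v in truth.abstract_labels.items() if v["relevant"]}
        assert cypddi.estimate_recall(lambda a: True, positives, corpus) == 1.0
        assert cypddi.estimate_recall(lambda a: False, positives, corpus) == 0.0

    def test_missing_three_of_hundred(self):
        corpus = [{"id": f"a{i}", "sentences": ["x"]} for i in range(120)]
        positives = {f"a{i}" for i in range(100)}
        missed = {"a0", "a1", "a2"}
        recall = cypddi.estimate_recall(
            lambda a: a["id"] not in missed, positives, corpus
        )
        assert recall == pytest.approx(0.97)

    def test_empty_positives_invalid(self):
        with pytest.raises(ValueError):
            cypddi.estimate_recall(lambda a: True, set(), [])

    def test_disabled_pattern_recall_matches_label_fraction(self, small_kb):
        """With one pattern family off, recall equals the surviving fraction."""
        corpus, truth = cypddi.generate_abstract_corpus(small_kb, 30, 0, seed=17)
        mixed, pos_ids = cypddi.spike_decoy_corpus(corpus, 40, seed=18)
        dd = sorted(set(small_kb["drug"]) | probe_terms())

        def retrieval_without_deo(abstract):
            return any(
                m.pattern_tag != "DEO" for m in cypddi.scan_abstract(abstract, dd)
            )

        recall = cypddi.estimate_recall(retrieval_without_deo, pos_ids, mixed)
        labels = truth.abstract_labels
        expect = sum(labels[i]["pattern"] != "DEO" for i in pos_ids) / len(pos_ids)
        assert recall == pytest.approx(expect)
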