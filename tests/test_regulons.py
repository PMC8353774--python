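"""Documented regulations, condition filtering, projection, core regulon."""

import pytest

from crossreg.homology import HomologyPair
from crossreg.regulons import (ConditionLabel, DocumentedRegulation, Reference,
                               RegulonPrediction, PredictedTarget,
                               VocabularyError, core_regulon, export_network,
                               filter_by_condition, load_regulations_form,
                               project_regulon)

HEADER = ("Transcription Factor\tTarget Gene\tStrain\t"
          "Supporting reference (PubMed ID)\tEvidence Code\tAssociation Type\t"
          "Experimental Evidence\tEnvironmental Condition\t"
          "Environmental condition Group\tEnvironmental condition sub-group")

VALID_ROW = ("Haa1", "TPO3", "S288C", "20195295", "Expression", "Indirect",
             "microarray", "acetic acid", "Stress", "Weak acid stress")


def write_form(tmp_path, rows, header=HEADER):
    path = tmp_path / "regs.tsv"
    path.write_text(header + "\n" + "".join("\t".join(r) + "\n" for r in rows))
    return path


def make_reg(tf, target, group="Stress", subgroup="Weak acid stress",
             pubmed=1000, species=""):
    return DocumentedRegulation(
        tf_name=tf, target_gene=target, strain="s",
        reference=Reference(pubmed_id=pubmed), evidence_code="Expression",
        association_type="Indirect", experimental_evidence="microarray",
        condition=ConditionLabel(raw="x", group=group, subgroup=subgroup),
        species=species)


class TestLoadRegulationsForm:
    def test_valid_haa1_row_accepted(self, tmp_path):
        records, errors = load_regulations_form(write_form(tmp_path, [VALID_ROW]))
        assert not errors and len(records) == 1
        assert records[0].tf_name == "Haa1"
        assert records[0].condition.subgroup == "Weak acid stress"

    def test_invalid_association_type_rejected(self, tmp_path):
        row = VALID_ROW[:5] + ("Maybe",) + VALID_ROW[6:]
        records, errors = load_regulations_form(write_form(tmp_path, [row]))
        assert not records and "Maybe" in errors[0]

    def test_exact_duplicate_not_double_counted(self, tmp_path):
        records, errors = load_regulations_form(
            write_form(tmp_path, [VALID_ROW, VALID_ROW]))
        assert not errors and len(records) == 1

    def test_unknown_target_rejected_with_line_number(self, tmp_path):
        records, errors = load_regulations_form(
            write_form(tmp_path, [VALID_ROW]),
            known_tfs={"Haa1"}, known_genes={"Haa1", "OTHER"})
        assert not records and "line 2" in errors[0] and "TPO3" in errors[0]

    def test_missing_column_is_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="missing required column"):
            load_regulations_form(write_form(tmp_path, [], header="Transcription Factor"))

    def test_bad_pubmed_id_rejected(self, tmp_path):
        row = VALID_ROW[:3] + ("not-a-pmid",) + VALID_ROW[4:]
        records, errors = load_regulations_form(write_form(tmp_path, [row]))
        assert not records and "PubMed" in errors[0]


class TestFilterByCondition:
    @pytest.fixture
    def regs(self):
        return ({make_reg("TF", f"w{i}", subgroup="Weak acid stress", pubmed=i + 1)
                 for i in range(3)}
                | {make_reg("TF", f"h{i}", subgroup="Heat Shock", pubmed=10 + i)
                   for i in range(2)})

    def test_subgroup_filter_selects_exactly_matching(self, regs):
        out = filter_by_condition(regs, "Stress", "Weak acid stress")
        assert {r.target_gene for r in out} == {"w0", "w1", "w2"}

    def test_group_level_filter_keeps_all_subgroups(self, regs):
        assert len(filter_by_condition(regs, "Stress")) == 5

    def test_empty_input_gives_empty_output(self):
        assert filter_by_condition(set(), "Stress") == set()

    def test_unknown_group_raises_vocabulary_error(self, regs):
        with pytest.raises(VocabularyError):
            filter_by_condition(regs, "Weather")


def pairs(*specs):
    return {HomologyPair.make(*s) for s in specs}


class TestProjectRegulon:
    def test_targets_mapped_through_homology_with_unmapped_counted(self):
        hom = pairs(("q", "xq", "s", "t"),
                    ("q", "x1", "s", "y1"), ("q", "x3", "s", "y3"))
        regs = [make_reg("t", y, species="s") for y in ("y1", "y2", "y3")]
        pred = project_regulon(("q", "xq"), "s", hom, regs)
        assert pred.target_genes() == {"x1", "x3"}
        assert pred.n_unmapped_targets == 1
        assert pred.source_tfs == ["t"]

    def test_multiple_homologous_source_tfs_union_their_targets(self):
        # the query regulator has two close homologs in the source species
        hom = pairs(("q", "xq", "s", "t1"), ("q", "xq", "s", "t2"),
                    ("q", "x9", "s", "y9"))
        regs = [make_reg("t2", "y9", species="s")]
        pred = project_regulon(("q", "xq"), "s", hom, regs)
        assert pred.target_genes() == {"x9"}
        assert {t.source_tf for t in pred.targets} == {"t2"}
        assert set(pred.source_tfs) == {"t1", "t2"}

    def test_condition_filter_can_empty_the_prediction(self):
        hom = pairs(("q", "xq", "s", "t"), ("q", "x1", "s", "y1"))
        regs = [make_reg("t", "y1", subgroup="Heat Shock", species="s")]
        pred = project_regulon(("q", "xq"), "s", hom, regs,
                               condition_filter=("Stress", "Weak acid stress"))
        assert pred.target_genes() == set()
        assert pred.status != "ok"

    def test_no_homolog_of_query_gives_empty_with_status(self):
        pred = project_regulon(("q", "xq"), "s", set(), [make_reg("t", "y")])
        assert pred.targets == [] and "no homolog" in pred.status

    def test_source_target_with_two_query_homologs_predicts_both(self):
        hom = pairs(("q", "xq", "s", "t"),
                    ("q", "x1a", "s", "y1"), ("q", "x1b", "s", "y1"))
        pred = project_regulon(("q", "xq"), "s", hom,
                               [make_reg("t", "y1", species="s")])
        assert pred.target_genes() == {"x1a", "x1b"}

    def test_provenance_traces_to_regulation_and_homology(self):
        hom = pairs(("q", "xq", "s", "t"), ("q", "x1", "s", "y1"))
        reg = make_reg("t", "y1", species="s")
        pred = project_regulon(("q", "xq"), "s", hom, [reg])
        (target,) = pred.targets
        assert reg in target.regulations
        assert frozenset(target.homology.key()) == frozenset(
            {("q", "x1"), ("s", "y1")})
        # removing either support breaks the edge
        assert project_regulon(("q", "xq"), "s", hom, []).target_genes() == set()
        assert project_regulon(("q", "xq"), "s", pairs(("q", "xq", "s", "t")),
                               [reg]).target_genes() == set()

    def test_adding_regulation_never_shrinks_prediction(self):
        hom = pairs(("q", "xq", "s", "t"),
                    ("q", "x1", "s", "y1"), ("q", "x2", "s", "y2"))
        base = [make_reg("t", "y1", species="s")]
        more = base + [make_reg("t", "y2", species="s", pubmed=2)]
        small = project_regulon(("q", "xq"), "s", hom, base).target_genes()
        large = project_regulon(("q", "xq"), "s", hom, more).target_genes()
        assert small <= large

    def test_min_synteny_level_restricts_pairs(self):
        hom = {HomologyPair.make("q", "xq", "s", "t", synteny_level=3),
               HomologyPair.make("q", "x1", "s", "y1", synteny_level=0)}
        pred = project_regulon(("q", "xq"), "s", hom,
                               [make_reg("t", "y1", species="s")],
                               min_synteny_level=1)
        assert pred.target_genes() == set()


def prediction(source, targets, query="q"):
    p = RegulonPrediction(query_species=query, query_gene="xq",
                          source_species=source)
    hom = HomologyPair.make("q", "x", source, "y")
    p.targets = [PredictedTarget(t, "y", hom, (), "tf") for t in targets]
    return p


class TestCoreRegulon:
    def test_three_way_intersection_and_venn(self):
        core = core_regulon([prediction("s1", {"x1", "x2", "x5"}),
                             prediction("s2", {"x2", "x5"}),
                             prediction("s3", {"x2"})])
        assert core.core == {"x2"}
        assert core.venn["s1&s2&s3"] == 1
        assert core.venn["s1&s2"] == 1  # x5, exclusive of s3
        assert core.venn["s1"] == 1  # x1

    def test_disjoint_sets_have_empty_core(self):
        core = core_regulon([prediction("s1", {"a"}), prediction("s2", {"b"})])
        assert core.core == set()
        assert core.venn["s1&s2"] == 0

    def test_identical_sets_have_no_exclusive_regions(self):
        core = core_regulon([prediction("s1", {"a", "b"}),
                             prediction("s2", {"a", "b"})])
        assert core.core == {"a", "b"}
        assert core.venn["s1"] == core.venn["s2"] == 0
        assert core.venn["s1&s2"] == 2

    def test_fewer_than_two_predictions_rejected(self):
        with pytest.raises(ValueError):
            core_regulon([prediction("s1", {"a"})])

    def test_intersection_is_order_invariant(self):
        preds = [prediction("s1", {"a", "b"}), prediction("s2", {"b", "c"}),
                 prediction("s3", {"b"})]
        assert core_regulon(preds).core == core_regulon(preds[::-1]).core


class TestExportNetwork:
    def test_tsv_has_one_edge_per_target(self, tmp_path):
        pred = prediction("s1", {"x1", "x2"})
        path = export_network(pred, tmp_path / "net.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 3  # header + 2 edges

    def test_empty_prediction_writes_header_only(self, tmp_path):
        path = export_network(prediction("s1", set()), tmp_path / "net.tsv")
        assert len(path.read_text().splitlines()) == 1

    def test_export_is_deterministic(self, tmp_path):
        pred = prediction("s1", {"x3", "x1", "x2"})
        a = export_network(pred, tmp_path / "a.tsv").read_bytes()
        b = export_network(pred, tmp_path / "b.tsv").read_bytes()
        assert a == b

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            export_network(prediction("s1", set()), tmp_path / "x", fmt="xml")


class TestPlantedRegulonRecovery:
    def test_projection_recovers_planted_images_and_core(self, projection_bundle):
        from crossreg.regulons import load_regulations_form
        from crossreg.synthetic import truth_homology_pairs

        b = projection_bundle
        hom = truth_homology_pairs(b.truths.values())
        query = b.species_names[0]
        qmap = b.truths[query].ortholog_map
        tf_q = qmap[b.config.planted_regulon.tf_index]

        def image(src_genes, src):
            inv = {v: k for k, v in b.truths[src].ortholog_map.items()}
            return {qmap[inv[g]] for g in src_genes}

        preds = []
        for src in b.species_names[1:]:
            regs, errors = load_regulations_form(b.regulation_paths[src],
                                                 species=src)
            assert not errors
            pred = project_regulon((query, tf_q), src, hom, regs)
            assert pred.target_genes() == image(b.regulon_truth[src]["all"], src)
            preds.append(pred)
        core = core_regulon(preds)
        expected_core = {qmap[i] for i in b.config.planted_regulon.core_targets}
        assert core.core == expected_core

    def test_condition_filter_recovers_planted_subset(self, projection_bundle):
        from crossreg.regulons import load_regulations_form
        from crossreg.synthetic import truth_homology_pairs

        b = projection_bundle
        hom = truth_homology_pairs(b.truths.values())
        query = b.species_names[0]
        qmap = b.truths[query].ortholog_map
        tf_q = qmap[b.config.planted_regulon.tf_index]
        src = b.species_names[1]
        regs, _ = load_regulations_form(b.regulation_paths[src], species=src)
        pred = project_regulon((query, tf_q), src, hom, regs,
                               condition_filter=("Stress", "Weak acid stress"))
        expected = {qmap[i] for i in b.config.planted_regulon.core_targets}
        assert pred.target_genes() == expected
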