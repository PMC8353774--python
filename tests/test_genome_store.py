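"""Genome store: GenBank parsing, promoter extraction, neighbours, GO."""

import pytest

from crossreg.genome import (emit_genbank, extract_all_promoters,
                             extract_promoter, load_go, neighbors,
                             parse_genbank, revcomp)

from conftest import build_genome

# independent complement table, used instead of the package's revcomp
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq):
    return "".join(COMPLEMENT[c] for c in reversed(seq))


class TestParseGenbank:
    def test_forward_cds_coordinates_converted_to_zero_based(self, write_genbank):
        path = write_genbank("one.gb", "CTG1", "A" * 60, [("21..35", "G1")])
        genome = parse_genbank(path, "sp")
        assert len(genome.contigs) == 1 and len(genome.genes) == 1
        gene = genome.genes["G1"]
        assert (gene.start, gene.end, gene.strand) == (20, 35, "forward")

    def test_complement_notation_gives_reverse_strand(self, write_genbank):
        path = write_genbank("rev.gb", "CTG1", "A" * 60,
                             [("complement(5..19)", "G1")])
        gene = parse_genbank(path, "sp").genes["G1"]
        assert (gene.start, gene.end, gene.strand) == (4, 19, "reverse")

    def test_zero_cds_gives_empty_gene_set_with_warning(self, write_genbank):
        path = write_genbank("empty.gb", "CTG1", "A" * 60, [])
        genome = parse_genbank(path, "sp")
        assert genome.genes == {}
        assert any("no CDS" in w for w in genome.warnings)

    def test_cds_outside_contig_is_skipped_and_counted(self, write_genbank):
        path = write_genbank("bad.gb", "CTG1", "A" * 30,
                             [("10..24", "OK"), ("25..90", "BAD")])
        genome = parse_genbank(path, "sp")
        assert "OK" in genome.genes and "BAD" not in genome.genes

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_genbank(tmp_path / "nope.gb", "sp")

    def test_ambiguity_codes_mapped_to_n(self, write_genbank):
        path = write_genbank("amb.gb", "CTG1", "ACGT" + "RYSW" + "A" * 52, [])
        genome = parse_genbank(path, "sp")
        assert genome.contigs[0].sequence[4:8] == "NNNN"
        assert any("ambiguity" in w for w in genome.warnings)


class TestRoundTrip:
    def test_emit_then_parse_preserves_coordinates_and_proteins(self, tmp_path):
        genome = build_genome(
            contigs=[("C1", "ATG" + "GCT" * 8 + "TAA" + "ACGT" * 10
                      + "TTACATCGA" * 3)],
            genes=[dict(gene_id="F1", contig_id="C1", start=0, end=30,
                        strand="forward", aa="MAAAAAAAA"),
                   dict(gene_id="R1", contig_id="C1", start=40, end=58,
                        strand="reverse", aa="MXXXXX")])
        path = emit_genbank(genome, tmp_path / "rt.gb")
        back = parse_genbank(path, "toy")
        for gid in genome.genes:
            a, b = genome.genes[gid], back.genes[gid]
            assert (a.start, a.end, a.strand) == (b.start, b.end, b.strand)
            assert a.protein.aa_sequence == b.protein.aa_sequence

    def test_reverse_strand_serialized_with_complement(self, tmp_path):
        genome = build_genome(contigs=[("C1", "A" * 50)],
                              genes=[dict(gene_id="R1", contig_id="C1",
                                          start=9, end=30, strand="reverse")])
        text = emit_genbank(genome, tmp_path / "c.gb").read_text()
        assert "complement(10..30)" in text

    def test_origin_lines_wrap_at_60_bases(self, tmp_path):
        genome = build_genome(contigs=[("C1", "ACGT" * 40)])
        lines = emit_genbank(genome, tmp_path / "w.gb").read_text().splitlines()
        origin = [l for l in lines if l and l.split()[0].isdigit()]
        assert all(sum(len(b) for b in l.split()[1:]) <= 60 for l in origin)
        assert origin[1].split()[0] == "61"

    def test_emission_is_deterministic(self, tmp_path):
        genome = build_genome(contigs=[("C1", "ACGT" * 30)],
                              genes=[dict(gene_id="G1", contig_id="C1",
                                          start=20, end=50, strand="forward")])
        a = emit_genbank(genome, tmp_path / "a.gb").read_bytes()
        b = emit_genbank(genome, tmp_path / "b.gb").read_bytes()
        assert a == b


class TestExtractPromoter:
    def test_forward_gene_truncated_at_contig_start(self):
        genome = build_genome(contigs=[("C1", "AAAACCCCGGGGTTTTAAAA")],
                              genes=[dict(gene_id="G1", contig_id="C1",
                                          start=16, end=20, strand="forward")])
        p = extract_promoter(genome, "G1", 1000)
        assert p.sequence == "AAAACCCCGGGGTTTT"
        assert p.actual_length == 16 and p.truncated

    def test_reverse_gene_promoter_is_reverse_complement_downstream(self):
        genome = build_genome(contigs=[("C1", "AAAACCCCGGGGTTTT")],
                              genes=[dict(gene_id="G1", contig_id="C1",
                                          start=0, end=4, strand="reverse")])
        p = extract_promoter(genome, "G1", 1000)
        assert p.sequence == naive_revcomp("CCCCGGGGTTTT") == "AAAACCCCGGGG"
        assert p.truncated

    def test_gene_at_contig_start_has_empty_promoter(self):
        genome = build_genome(contigs=[("C1", "ATGAAATAA" + "A" * 10)],
                              genes=[dict(gene_id="G1", contig_id="C1",
                                          start=0, end=9, strand="forward")])
        p = extract_promoter(genome, "G1", 1000)
        assert p.sequence == "" and p.actual_length == 0 and p.truncated

    def test_unknown_gene_raises_lookup_error(self):
        genome = build_genome(contigs=[("C1", "ACGT")])
        with pytest.raises(KeyError):
            extract_promoter(genome, "nope")

    def test_promoter_never_overlaps_own_gene_body(self, small_bundle):
        for genome in small_bundle.genomes.values():
            for gid, gene in genome.genes.items():
                p = extract_promoter(genome, gid, 1000)
                contig = genome.contig(gene.contig_id)
                if gene.strand == "forward":
                    assert contig.sequence[gene.start - p.actual_length:gene.start] \
                        == p.sequence
                # promoter span ends exactly at the gene start: no overlap
                assert p.actual_length == min(1000, gene.start) or \
                    gene.strand == "reverse"

    def test_promoter_length_is_min_of_request_and_available(self):
        genome = build_genome(contigs=[("C1", "ACGTACGTACGTACGTACGT")],
                              genes=[dict(gene_id="G1", contig_id="C1",
                                          start=12, end=20, strand="forward")])
        for req in (5, 12, 50):
            p = extract_promoter(genome, "G1", req)
            assert p.actual_length == min(req, 12)
            assert p.truncated == (p.actual_length < req)

    def test_reverse_promoter_matches_independent_complement_table(self):
        contig = "ATTGCCGGAATTCCGGTTAA"
        genome = build_genome(contigs=[("C1", contig)],
                              genes=[dict(gene_id="G1", contig_id="C1",
                                          start=0, end=6, strand="reverse")])
        p = extract_promoter(genome, "G1", 8)
        assert p.sequence == naive_revcomp(contig[6:14])


class TestExtractAllPromoters:
    def test_one_promoter_per_gene_in_sorted_order(self, small_bundle):
        genome = small_bundle.genomes["sp01"]
        promoters = extract_all_promoters(genome, 1000)
        assert len(promoters) == len(genome.genes)
        assert [p.gene_id for p in promoters] == sorted(genome.genes)
        assert promoters == extract_all_promoters(genome, 1000)

    def test_empty_genome_yields_empty_collection(self):
        genome = build_genome(contigs=[("C1", "ACGT")])
        assert extract_all_promoters(genome) == []


class TestNeighbors:
    def _ladder(self, n=10, per_contig=None):
        per_contig = per_contig or n
        contigs, genes = [], []
        for c in range((n + per_contig - 1) // per_contig):
            cid = f"C{c + 1}"
            contigs.append((cid, "A" * (20 * per_contig)))
            for i in range(per_contig):
                k = c * per_contig + i
                if k >= n:
                    break
                genes.append(dict(gene_id=f"g{k + 1}", contig_id=cid,
                                  start=20 * i + 5, end=20 * i + 15,
                                  strand="forward"))
        return build_genome(contigs=contigs, genes=genes)

    def test_interior_gene_window(self):
        genome = self._ladder(10)
        assert neighbors(genome, "g5", 2) == (["g4", "g3"], ["g6", "g7"])

    def test_contig_start_truncates_upstream(self):
        genome = self._ladder(10)
        assert neighbors(genome, "g1", 3) == ([], ["g2", "g3", "g4"])

    def test_window_never_crosses_contigs(self):
        genome = self._ladder(10, per_contig=5)
        up, down = neighbors(genome, "g5", 15)
        assert up == ["g4", "g3", "g2", "g1"] and down == []

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            neighbors(self._ladder(3), "nope", 1)


class TestLoadGO:
    @pytest.fixture
    def genome(self):
        return build_genome(contigs=[("C1", "A" * 100)],
                            genes=[dict(gene_id="G1", contig_id="C1", start=10,
                                        end=20, strand="forward"),
                                   dict(gene_id="G2", contig_id="C1", start=30,
                                        end=40, strand="forward")])

    def _write(self, tmp_path, terms, annotations):
        t = tmp_path / "terms.tsv"
        a = tmp_path / "ann.tsv"
        t.write_text("go_id\tname\tontology\tparent_ids\n" +
                     "".join("\t".join(r) + "\n" for r in terms))
        a.write_text("gene_id\tgo_id\n" +
                     "".join("\t".join(r) + "\n" for r in annotations))
        return t, a

    def test_valid_rows_loaded(self, tmp_path, genome):
        t, a = self._write(tmp_path,
                           [("GO:1", "root", "biological process", ""),
                            ("GO:2", "child", "biological process", "GO:1")],
                           [("G1", "GO:1"), ("G2", "GO:2")])
        report = load_go(t, a, genome)
        assert report.n_annotations == 2 and not report.errors

    def test_unknown_gene_rejected_with_line_number(self, tmp_path, genome):
        t, a = self._write(tmp_path,
                           [("GO:1", "root", "molecular function", "")],
                           [("GHOST", "GO:1")])
        report = load_go(t, a, genome)
        assert report.n_annotations == 0
        assert any(":2:" in e and "GHOST" in e for e in report.errors)

    def test_two_node_cycle_rejects_load(self, tmp_path, genome):
        t, a = self._write(tmp_path,
                           [("GO:1", "a", "cellular component", "GO:2"),
                            ("GO:2", "b", "cellular component", "GO:1")],
                           [])
        with pytest.raises(ValueError, match="cycle"):
            load_go(t, a, genome)


def test_revcomp_agrees_with_independent_table():
    for seq in ("", "A", "ACGTN", "GGCGAGGGG", "TTACGGAT"):
        assert revcomp(seq) == naive_revcomp(seq)
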