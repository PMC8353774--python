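import textwrap

import pytest

from crossreg.genome import Contig, GeneRecord, ProteinRecord, SpeciesGenome
from crossreg.synthetic import FixtureConfig, generate_bundle


def build_genome(species="toy", contigs=(), genes=()):
    """Assemble a SpeciesGenome from (contig_id, seq) and GeneRecord kwargs."""
    g = SpeciesGenome(species, strain="test")
    for cid, seq in contigs:
        g.add_contig(Contig(cid, seq))
    for kw in genes:
        kw = dict(kw)
        aa = kw.pop("aa", None)
        if aa:
            kw["protein"] = ProteinRecord(kw["gene_id"], aa)
        g.add_gene(GeneRecord(**kw))
    return g


def genbank_text(locus_id, sequence, features):
    """Hand-written GenBank flat-file text (independent of the package writer).

    ``features`` is a list of (location_string, locus_tag) CDS features using
    GenBank's native 1-based inclusive coordinates.
    """
    lines = [
        f"LOCUS       {locus_id:<16}{len(sequence):>5} bp    DNA     linear   "
        "UNA 01-JAN-1980",
        f"DEFINITION  test record {locus_id}.",
        f"ACCESSION   {locus_id}",
        f"VERSION     {locus_id}",
        "FEATURES             Location/Qualifiers",
    ]
    for location, locus_tag in features:
        lines.append(f"     CDS             {location}")
        lines.append(f'                     /locus_tag="{locus_tag}"')
    lines.append("ORIGIN")
    seq = sequence.lower()
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_genbank(tmp_path):
    def _write(name, locus_id, sequence, features):
        path = tmp_path / name
        path.write_text(genbank_text(locus_id, sequence, features))
        return path
    return _write


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """3 species x 40 genes at low divergence, with planted sites and regulon."""
    out = tmp_path_factory.mktemp("bundle3")
    config = FixtureConfig(n_species=3, n_genes=40, genes_per_contig=20, seed=7)
    return generate_bundle(config, out)


@pytest.fixture(scope="session")
def projection_bundle(tmp_path_factory):
    """4 species (1 query + 3 sources) with a planted 6-gene core regulon."""
    out = tmp_path_factory.mktemp("bundle4")
    config = FixtureConfig(n_species=4, n_genes=40, genes_per_contig=20, seed=11)
    return generate_bundle(config, out)
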