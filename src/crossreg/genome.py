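"""Gene-centric genome store: GenBank parsing, promoter extraction, neighbors, GO.

The data model is centred on the ORF/gene: each :class:`GeneRecord` belongs to a
:class:`Contig` of a :class:`SpeciesGenome`, optionally carries a translated
protein, and has a promoter defined as the fixed-length window immediately
upstream of its START codon on the coding strand.

Internal coordinates are 0-based half-open throughout; GenBank input/output
converts to and from the format's 1-based inclusive convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD = "forward"
REVERSE = "reverse"


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _sanitize_dna(seq: str) -> tuple[str, int]:
    """Uppercase and map ambiguity codes other than N to N.

    Returns the cleaned sequence and the number of replaced characters.
    """
    seq = seq.upper()
    if set(seq) <= set("ACGTN"):
        return seq, 0
    cleaned = []
    replaced = 0
    for c in seq:
        if c in "ACGTN":
            cleaned.append(c)
        else:
            cleaned.append("N")
            replaced += 1
    return "".join(cleaned), replaced


@dataclass
class Contig:
    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    protein_name: str
    aa_sequence: str


@dataclass
class GeneRecord:
    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # FORWARD or REVERSE
    standard_name: Optional[str] = None
    description: Optional[str] = None
    protein: Optional[ProteinRecord] = None
    external_ref: Optional[str] = None


@dataclass
class Promoter:
    gene_id: str
    sequence: str
    requested_length: int
    truncated: bool

    @property
    def actual_length(self) -> int:
        return len(self.sequence)


@dataclass
class GOTerm:
    go_id: str
    name: str
    ontology: str  # molecular function | biological process | cellular component
    parent_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GOAnnotation:
    gene_id: str
    go_id: str


GO_ONTOLOGIES = {"molecular function", "biological process", "cellular component"}


class SpeciesGenome:
    """An annotated genome: ordered contigs plus genes indexed by locus tag."""

    def __init__(self, species_name: str, strain: str = ""):
        self.species_name = species_name
        self.strain = strain
        self.contigs: list[Contig] = []
        self.genes: dict[str, GeneRecord] = {}
        self.go_terms: dict[str, GOTerm] = {}
        self.go_annotations: list[GOAnnotation] = []
        self.skipped_records = 0
        self.warnings: list[str] = []
        self._order_cache: dict[str, list[str]] | None = None

    # -- construction -------------------------------------------------------

    def add_contig(self, contig: Contig) -> None:
        if any(c.contig_id == contig.contig_id for c in self.contigs):
            raise ValueError(f"duplicate contig id {contig.contig_id!r}")
        self.contigs.append(contig)
        self._order_cache = None

    def add_gene(self, gene: GeneRecord) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id!r}")
        contig = self.contig(gene.contig_id)
        if not (0 <= gene.start < gene.end <= contig.length):
            raise ValueError(
                f"gene {gene.gene_id!r} coordinates [{gene.start},{gene.end}) "
                f"outside contig {gene.contig_id!r} of length {contig.length}"
            )
        self.genes[gene.gene_id] = gene
        self._order_cache = None

    # -- lookup -------------------------------------------------------------

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(f"unknown contig {contig_id!r}")

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(
                f"unknown gene {gene_id!r} in {self.species_name}"
            ) from None

    def genes_on_contig(self, contig_id: str) -> list[str]:
        """Gene ids on a contig, totally ordered by (start, end)."""
        if self._order_cache is None:
            cache: dict[str, list[str]] = {c.contig_id: [] for c in self.contigs}
            for gid, g in self.genes.items():
                cache[g.contig_id].append(gid)
            for cid in cache:
                cache[cid].sort(key=lambda gid: (self.genes[gid].start, self.genes[gid].end))
            self._order_cache = cache
        return list(self._order_cache[contig_id])

    def proteome(self) -> dict[str, str]:
        """gene_id -> amino-acid sequence, for genes with a protein."""
        return {
            gid: g.protein.aa_sequence
            for gid, g in sorted(self.genes.items())
            if g.protein is not None and g.protein.aa_sequence
        }


# ---------------------------------------------------------------------------
# GenBank input/output
# ---------------------------------------------------------------------------


def _cds_features(record: SeqRecord) -> Iterable[SeqFeature]:
    return (f for f in record.features if f.type == "CDS")


def parse_genbank(path: str | Path, species_name: str, strain: str = "") -> SpeciesGenome:
    """Parse a (multi-record) GenBank flat file into a :class:`SpeciesGenome`.

    One contig per LOCUS record, one gene per CDS feature.  GenBank's 1-based
    inclusive coordinates become 0-based half-open; ``complement(...)``
    locations become reverse-strand genes.  The protein sequence is taken from
    the ``translation`` qualifier, or translated from the CDS when absent.
    Records failing validation are skipped and counted, with a logged reason.

    When a locus tag carries several CDS features (isoforms), the longest CDS
    is kept; ties break to the leftmost start.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GenBank file not found: {path}")
    genome = SpeciesGenome(species_name, strain)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    # candidate CDSs per locus tag, across the whole file
    candidates: dict[str, list[tuple[str, int, int, int, SeqFeature, str]]] = {}
    for record in records:
        seq, replaced = _sanitize_dna(str(record.seq))
        if replaced:
            genome.warnings.append(
                f"contig {record.id}: {replaced} ambiguity characters mapped to N"
            )
        genome.add_contig(Contig(contig_id=record.id, sequence=seq))
        for feat in _cds_features(record):
            locus_tag = feat.qualifiers.get("locus_tag", [None])[0]
            if locus_tag is None:
                genome.skipped_records += 1
                logger.warning("CDS without locus_tag skipped on %s", record.id)
                continue
            try:
                start = int(feat.location.start)
                end = int(feat.location.end)
                strand = REVERSE if feat.location.strand == -1 else FORWARD
            except (TypeError, AttributeError):
                genome.skipped_records += 1
                logger.warning("CDS %s: unresolvable location, skipped", locus_tag)
                continue
            if not (0 <= start < end <= len(seq)):
                genome.skipped_records += 1
                logger.warning(
                    "CDS %s: coordinates [%d,%d) outside contig %s (%d bp), skipped",
                    locus_tag, start, end, record.id, len(seq),
                )
                continue
            candidates.setdefault(locus_tag, []).append(
                (record.id, start, end, -1 if strand == REVERSE else 1, feat, seq)
            )
    for locus_tag, cands in candidates.items():
        # longest CDS wins; ties to the leftmost start
        cands.sort(key=lambda c: (-(c[2] - c[1]), c[1]))
        contig_id, start, end, istrand, feat, contig_seq = cands[0]
        strand = REVERSE if istrand == -1 else FORWARD
        aa = feat.qualifiers.get("translation", [None])[0]
        if aa is None:
            cds = contig_seq[start:end]
            if strand == REVERSE:
                cds = revcomp(cds)
            aa = str(Seq(cds).translate(to_stop=True))
        aa = aa.rstrip("*")
        protein = None
        if aa:
            pname = feat.qualifiers.get("product", [locus_tag])[0]
            protein = ProteinRecord(protein_name=pname, aa_sequence=aa)
        gene = GeneRecord(
            gene_id=locus_tag,
            contig_id=contig_id,
            start=start,
            end=end,
            strand=strand,
            standard_name=feat.qualifiers.get("gene", [None])[0],
            description=feat.qualifiers.get("product", [None])[0],
            protein=protein,
            external_ref=feat.qualifiers.get("db_xref", [None])[0],
        )
        genome.add_gene(gene)
    if not genome.genes:
        genome.warnings.append("no CDS features found: genome has an empty gene set")
        logger.warning("no CDS features in %s", path)
    return genome


def emit_genbank(genome: SpeciesGenome, path: str | Path) -> Path:
    """Write a genome as a standards-conforming GenBank flat file.

    CDS features carry ``locus_tag`` and ``translation`` qualifiers, with
    1-based inclusive coordinates and ``complement()`` for the reverse strand.
    A fixed LOCUS date is used so output is byte-identical across runs.
    """
    path = Path(path)
    records = []
    for contig in genome.contigs:
        record = SeqRecord(
            Seq(contig.sequence),
            id=contig.contig_id,
            name=contig.contig_id[:16],
            description=f"{genome.species_name} {genome.strain}".strip(),
        )
        record.annotations["molecule_type"] = "DNA"
        record.annotations["topology"] = "linear"
        record.annotations["date"] = "01-JAN-1980"
        record.annotations["organism"] = genome.species_name
        for gid in genome.genes_on_contig(contig.contig_id):
            gene = genome.genes[gid]
            strand = -1 if gene.strand == REVERSE else 1
            loc = SimpleLocation(gene.start, gene.end, strand=strand)
            qualifiers: dict[str, list[str]] = {"locus_tag": [gene.gene_id]}
            if gene.standard_name:
                qualifiers["gene"] = [gene.standard_name]
            if gene.description:
                qualifiers["product"] = [gene.description]
            if gene.protein is not None:
                qualifiers["translation"] = [gene.protein.aa_sequence]
            qualifiers["codon_start"] = ["1"]
            record.features.append(SeqFeature(loc, type="gene",
                                              qualifiers={"locus_tag": [gene.gene_id]}))
            record.features.append(SeqFeature(loc, type="CDS", qualifiers=qualifiers))
        records.append(record)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "genbank")
    return path


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------


def extract_promoter(genome: SpeciesGenome, gene_id: str, length: int = 1000) -> Promoter:
    """The ``length`` bases immediately upstream of a gene's START codon.

    The promoter is read 5'→3' on the gene's coding strand and ends just
    before the START codon: for a forward gene it is the slice preceding
    ``start``; for a reverse gene, the reverse complement of the slice
    following ``end``.  Truncated at contig boundaries.
    """
    gene = genome.gene(gene_id)
    contig = genome.contig(gene.contig_id)
    if gene.strand == FORWARD:
        lo = max(0, gene.start - length)
        seq = contig.sequence[lo:gene.start]
    else:
        hi = min(contig.length, gene.end + length)
        seq = revcomp(contig.sequence[gene.end:hi])
    return Promoter(
        gene_id=gene_id,
        sequence=seq,
        requested_length=length,
        truncated=len(seq) < length,
    )


def extract_all_promoters(genome: SpeciesGenome, length: int = 1000) -> list[Promoter]:
    """One promoter per gene, in deterministic gene_id order."""
    return [extract_promoter(genome, gid, length) for gid in sorted(genome.genes)]


# ---------------------------------------------------------------------------
# Neighbourhoods
# ---------------------------------------------------------------------------


def neighbors(genome: SpeciesGenome, gene_id: str, k: int) -> tuple[list[str], list[str]]:
    """Up to ``k`` genes on each side of a locus, by increasing distance.

    Restricted to the gene's own contig; windows never cross contig
    boundaries.  Returns (toward-contig-start, toward-contig-end).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gene = genome.gene(gene_id)
    order = genome.genes_on_contig(gene.contig_id)
    i = order.index(gene_id)
    upstream = [order[j] for j in range(i - 1, max(-1, i - 1 - k), -1)]
    downstream = [order[j] for j in range(i + 1, min(len(order), i + 1 + k))]
    return upstream, downstream


# ---------------------------------------------------------------------------
# Gene Ontology
# ---------------------------------------------------------------------------


@dataclass
class GOLoadReport:
    n_terms: int = 0
    n_annotations: int = 0
    errors: list[str] = field(default_factory=list)


def load_go(terms_table: str | Path, annotations_table: str | Path,
            genome: SpeciesGenome) -> GOLoadReport:
    """Load GO terms and gene↔term annotations from TSV tables.

    The terms table has columns ``go_id, name, ontology, parent_ids``
    (parent_ids comma-separated, may be empty) covering all three ontologies;
    the annotations table has ``gene_id, go_id``.  Annotations naming unknown
    genes or terms are rejected row by row with line numbers; a cyclic term
    hierarchy rejects the whole load.
    """
    import csv

    import networkx as nx

    report = GOLoadReport()
    terms: dict[str, GOTerm] = {}
    with open(terms_table) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader.fieldnames, ["go_id", "name", "ontology", "parent_ids"],
                         str(terms_table))
        for lineno, row in enumerate(reader, start=2):
            ontology = row["ontology"].strip().lower()
            if ontology not in GO_ONTOLOGIES:
                report.errors.append(
                    f"{terms_table}:{lineno}: invalid ontology {row['ontology']!r}")
                continue
            parents = frozenset(p.strip() for p in row["parent_ids"].split(",") if p.strip())
            if row["go_id"] in parents:
                raise ValueError(
                    f"{terms_table}:{lineno}: term {row['go_id']!r} is its own parent")
            terms[row["go_id"]] = GOTerm(row["go_id"], row["name"], ontology, parents)
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for term in terms.values():
        for parent in term.parent_ids:
            if parent in terms:
                graph.add_edge(term.go_id, parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("GO term hierarchy contains a cycle; load rejected")
    genome.go_terms.update(terms)
    report.n_terms = len(terms)
    with open(annotations_table) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader.fieldnames, ["gene_id", "go_id"], str(annotations_table))
        for lineno, row in enumerate(reader, start=2):
            gid, go_id = row["gene_id"].strip(), row["go_id"].strip()
            if gid not in genome.genes:
                report.errors.append(
                    f"{annotations_table}:{lineno}: unknown gene {gid!r}")
                continue
            if go_id not in genome.go_terms:
                report.errors.append(
                    f"{annotations_table}:{lineno}: unknown GO term {go_id!r}")
                continue
            genome.go_annotations.append(GOAnnotation(gid, go_id))
            report.n_annotations += 1
    return report


def _require_columns(fieldnames, required, source: str) -> None:
    missing = [c for c in required if fieldnames is None or c not in fieldnames]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# FASTA export
# ---------------------------------------------------------------------------


def write_promoters_fasta(genome: SpeciesGenome, path: str | Path,
                          length: int = 1000) -> Path:
    """Promoters as FASTA, one record per gene, header ``species|gene_id``."""
    path = Path(path)
    with open(path, "w") as fh:
        for promoter in extract_all_promoters(genome, length):
            fh.write(f">{genome.species_name}|{promoter.gene_id}\n")
            fh.write(promoter.sequence + "\n")
    return path


def write_proteome_fasta(genome: SpeciesGenome, path: str | Path) -> Path:
    """Protein sequences as FASTA, header ``species|gene_id``."""
    path = Path(path)
    with open(path, "w") as fh:
        for gid, aa in genome.proteome().items():
            fh.write(f">{genome.species_name}|{gid}\n")
            fh.write(aa + "\n")
    return path
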