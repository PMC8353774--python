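"""Embedded single-file relational store for the gene-centric data model.

An sqlite3 database mirroring the platform's relational schema: species,
contigs, ORF/genes with proteins and promoters, TF binding sites, documented
regulations with references and condition labels, homology pairs, potential
regulations and GO tables — without a database-server dependency.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Iterable, Optional

from .binding_sites import BindingSite, PotentialRegulation, PotentialRegulationReport
from .genome import (Contig, GeneRecord, ProteinRecord, SpeciesGenome,
                     extract_all_promoters)
from .homology import HomologyPair
from .regulons import ConditionLabel, DocumentedRegulation, Reference

_SCHEMA = """
CREATE TABLE IF NOT EXISTS species (
    name TEXT PRIMARY KEY, strain TEXT
);
CREATE TABLE IF NOT EXISTS contig (
    species TEXT NOT NULL REFERENCES species(name),
    contig_id TEXT NOT NULL,
    sequence TEXT NOT NULL,
    length INTEGER NOT NULL,
    PRIMARY KEY (species, contig_id)
);
CREATE TABLE IF NOT EXISTS gene (
    species TEXT NOT NULL REFERENCES species(name),
    gene_id TEXT NOT NULL,
    standard_name TEXT, contig_id TEXT NOT NULL,
    start INTEGER NOT NULL, end INTEGER NOT NULL, strand TEXT NOT NULL,
    description TEXT, external_ref TEXT,
    PRIMARY KEY (species, gene_id)
);
CREATE TABLE IF NOT EXISTS protein (
    species TEXT NOT NULL, gene_id TEXT NOT NULL,
    protein_name TEXT, aa_sequence TEXT NOT NULL,
    PRIMARY KEY (species, gene_id)
);
CREATE TABLE IF NOT EXISTS promoter (
    species TEXT NOT NULL, gene_id TEXT NOT NULL,
    sequence TEXT NOT NULL, requested_length INTEGER NOT NULL,
    truncated INTEGER NOT NULL,
    PRIMARY KEY (species, gene_id)
);
CREATE TABLE IF NOT EXISTS tfbs (
    tf_name TEXT NOT NULL, tf_species TEXT, consensus TEXT NOT NULL,
    strain TEXT, pubmed_id INTEGER, evidence_code TEXT,
    experimental_evidence TEXT, condition_raw TEXT,
    condition_group TEXT, condition_subgroup TEXT
);
CREATE TABLE IF NOT EXISTS regulation (
    species TEXT, tf_name TEXT NOT NULL, target_gene TEXT NOT NULL,
    strain TEXT, pubmed_id INTEGER NOT NULL, evidence_code TEXT,
    association_type TEXT, experimental_evidence TEXT,
    condition_raw TEXT, condition_group TEXT, condition_subgroup TEXT
);
CREATE TABLE IF NOT EXISTS reference (
    pubmed_id INTEGER PRIMARY KEY,
    title TEXT, authors TEXT, journal TEXT, year INTEGER
);
CREATE TABLE IF NOT EXISTS homology (
    species_a TEXT, gene_a TEXT, species_b TEXT, gene_b TEXT,
    score_ab REAL, score_ba REAL, synteny_level INTEGER,
    PRIMARY KEY (species_a, gene_a, species_b, gene_b)
);
CREATE TABLE IF NOT EXISTS potential_regulation (
    tf_name TEXT, tf_species TEXT, target_gene TEXT, target_species TEXT,
    n_occurrences INTEGER,
    PRIMARY KEY (tf_name, tf_species, target_gene, target_species)
);
CREATE TABLE IF NOT EXISTS go_term (
    go_id TEXT PRIMARY KEY, name TEXT, ontology TEXT, parent_ids TEXT
);
CREATE TABLE IF NOT EXISTS go_annotation (
    species TEXT, gene_id TEXT, go_id TEXT REFERENCES go_term(go_id)
);
"""


class GenomeStore:
    """sqlite-backed persistence for genomes and derived results."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._conn = sqlite3.connect(str(self.path))
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "GenomeStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- genomes ------------------------------------------------------------

    def save_genome(self, genome: SpeciesGenome, promoter_length: int = 1000) -> None:
        """Insert or replace a genome, with promoters extracted on ingest."""
        cur = self._conn.cursor()
        name = genome.species_name
        cur.execute("INSERT OR REPLACE INTO species VALUES (?, ?)",
                    (name, genome.strain))
        for table in ("contig", "gene", "protein", "promoter"):
            cur.execute(f"DELETE FROM {table} WHERE species = ?", (name,))
        for c in genome.contigs:
            cur.execute("INSERT INTO contig VALUES (?, ?, ?, ?)",
                        (name, c.contig_id, c.sequence, c.length))
        for gid in sorted(genome.genes):
            g = genome.genes[gid]
            cur.execute(
                "INSERT INTO gene VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (name, g.gene_id, g.standard_name, g.contig_id, g.start,
                 g.end, g.strand, g.description, g.external_ref))
            if g.protein is not None:
                cur.execute("INSERT INTO protein VALUES (?, ?, ?, ?)",
                            (name, g.gene_id, g.protein.protein_name,
                             g.protein.aa_sequence))
        for p in extract_all_promoters(genome, promoter_length):
            cur.execute("INSERT INTO promoter VALUES (?, ?, ?, ?, ?)",
                        (name, p.gene_id, p.sequence, p.requested_length,
                         int(p.truncated)))
        self._conn.commit()

    def list_species(self) -> list[str]:
        rows = self._conn.execute("SELECT name FROM species ORDER BY name")
        return [r[0] for r in rows]

    def load_genome(self, species: str) -> SpeciesGenome:
        row = self._conn.execute(
            "SELECT strain FROM species WHERE name = ?", (species,)).fetchone()
        if row is None:
            raise KeyError(f"species {species!r} not in store")
        genome = SpeciesGenome(species, strain=row[0] or "")
        for cid, seq in self._conn.execute(
                "SELECT contig_id, sequence FROM contig WHERE species = ? "
                "ORDER BY contig_id", (species,)):
            genome.add_contig(Contig(cid, seq))
        proteins = {gid: (pname, aa) for gid, pname, aa in self._conn.execute(
            "SELECT gene_id, protein_name, aa_sequence FROM protein "
            "WHERE species = ?", (species,))}
        for gid, sname, cid, start, end, strand, desc, ext in self._conn.execute(
                "SELECT gene_id, standard_name, contig_id, start, end, strand,"
                " description, external_ref FROM gene WHERE species = ? "
                "ORDER BY gene_id", (species,)):
            protein = None
            if gid in proteins:
                protein = ProteinRecord(proteins[gid][0] or gid, proteins[gid][1])
            genome.add_gene(GeneRecord(gene_id=gid, standard_name=sname,
                                       contig_id=cid, start=start, end=end,
                                       strand=strand, description=desc,
                                       protein=protein, external_ref=ext))
        return genome

    def load_promoters(self, species: str) -> dict[str, str]:
        return {gid: seq for gid, seq in self._conn.execute(
            "SELECT gene_id, sequence FROM promoter WHERE species = ? "
            "ORDER BY gene_id", (species,))}

    # -- homology -----------------------------------------------------------

    def save_homology(self, pairs: Iterable[HomologyPair]) -> int:
        cur = self._conn.cursor()
        cur.execute("DELETE FROM homology")
        n = 0
        for p in sorted(pairs):
            cur.execute("INSERT OR REPLACE INTO homology VALUES (?,?,?,?,?,?,?)",
                        (p.species_a, p.gene_a, p.species_b, p.gene_b,
                         p.score_ab, p.score_ba, p.synteny_level))
            n += 1
        self._conn.commit()
        return n

    def load_homology(self) -> list[HomologyPair]:
        return [HomologyPair.make(*row[:4], float(row[4]), float(row[5]), row[6])
                for row in self._conn.execute(
                    "SELECT * FROM homology ORDER BY species_a, gene_a, "
                    "species_b, gene_b")]

    # -- documented data ----------------------------------------------------

    def save_regulations(self, regs: Iterable[DocumentedRegulation]) -> int:
        cur = self._conn.cursor()
        n = 0
        for r in regs:
            cur.execute("INSERT INTO regulation VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                        (r.species, r.tf_name, r.target_gene, r.strain,
                         r.reference.pubmed_id, r.evidence_code,
                         r.association_type, r.experimental_evidence,
                         r.condition.raw, r.condition.group,
                         r.condition.subgroup))
            cur.execute("INSERT OR IGNORE INTO reference (pubmed_id) VALUES (?)",
                        (r.reference.pubmed_id,))
            n += 1
        self._conn.commit()
        return n

    def load_regulations(self, species: Optional[str] = None
                         ) -> list[DocumentedRegulation]:
        sql = ("SELECT species, tf_name, target_gene, strain, pubmed_id, "
               "evidence_code, association_type, experimental_evidence, "
               "condition_raw, condition_group, condition_subgroup "
               "FROM regulation")
        args: tuple = ()
        if species is not None:
            sql += " WHERE species = ?"
            args = (species,)
        out = []
        seen = set()
        for row in self._conn.execute(sql + " ORDER BY tf_name, target_gene", args):
            reg = DocumentedRegulation(
                species=row[0] or "", tf_name=row[1], target_gene=row[2],
                strain=row[3] or "", reference=Reference(pubmed_id=row[4]),
                evidence_code=row[5], association_type=row[6],
                experimental_evidence=row[7] or "",
                condition=ConditionLabel(raw=row[8] or "", group=row[9] or "",
                                         subgroup=row[10] or ""))
            if reg.dedup_key() not in seen:
                seen.add(reg.dedup_key())
                out.append(reg)
        return out

    def save_tfbs(self, sites: Iterable[BindingSite]) -> int:
        cur = self._conn.cursor()
        n = 0
        for s in sites:
            cur.execute("INSERT INTO tfbs VALUES (?,?,?,?,?,?,?,?,?,?)",
                        (s.tf_name, s.tf_species, s.consensus, s.strain,
                         s.pubmed_id, s.evidence_code, s.experimental_evidence,
                         s.condition, s.condition_group, s.condition_subgroup))
            n += 1
        self._conn.commit()
        return n

    def load_tfbs(self) -> list[BindingSite]:
        return [BindingSite(tf_name=r[0], tf_species=r[1] or "", consensus=r[2],
                            strain=r[3] or "", pubmed_id=r[4],
                            evidence_code=r[5] or "N/A",
                            experimental_evidence=r[6] or "", condition=r[7] or "",
                            condition_group=r[8] or "",
                            condition_subgroup=r[9] or "")
                for r in self._conn.execute(
                    "SELECT * FROM tfbs ORDER BY tf_name, consensus")]

    # -- potential regulations ---------------------------------------------

    def save_potential_regulations(self, report: PotentialRegulationReport) -> int:
        cur = self._conn.cursor()
        cur.execute("DELETE FROM potential_regulation")
        n = 0
        for r in sorted(report.regulations,
                        key=lambda r: (r.tf_species, r.tf_name,
                                       r.target_species, r.target_gene)):
            cur.execute("INSERT INTO potential_regulation VALUES (?,?,?,?,?)",
                        (r.tf_name, r.tf_species, r.target_gene,
                         r.target_species, r.n_occurrences))
            n += 1
        self._conn.commit()
        return n

    def load_potential_regulations(self) -> PotentialRegulationReport:
        report = PotentialRegulationReport()
        for row in self._conn.execute("SELECT * FROM potential_regulation"):
            report.regulations.add(PotentialRegulation(*row))
        return report
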