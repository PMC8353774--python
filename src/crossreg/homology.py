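"""Tolerance-relaxed reciprocal-best-score homology with synteny strength.

For each unordered species pair, proteomes are aligned all-against-all, hits
are filtered at an E-value threshold (default 1e-5), and each protein keeps
every subject scoring within a relative tolerance (default 10%) of its best
hit, so alignments with a score almost identical to the best are not lost.
Gene pairs that satisfy this relaxed-best relation in both directions are the
homolog pairs.  Each pair is then assigned a synteny "strength" level in
{0,1,2,3} by counting homologous gene pairs among the neighbours of the two
loci (15 neighbours in each direction by default; levels require a minimum of
1, 2 or 3 neighbours in common).
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

from .genome import SpeciesGenome, neighbors, write_proteome_fasta

DEFAULT_EVALUE = 1e-5
DEFAULT_TOLERANCE = 0.10
DEFAULT_WINDOW = 15
# minimum shared-neighbour counts defining synteny levels 1, 2, 3
DEFAULT_MIN_COMMON = (1, 2, 3)


@dataclass(frozen=True)
class ScoreEntry:
    query_id: str
    subject_id: str
    score: float
    e_value: float


@dataclass
class ScoreTable:
    query_species: str
    subject_species: str
    entries: list[ScoreEntry] = field(default_factory=list)

    def by_query(self) -> dict[str, list[ScoreEntry]]:
        out: dict[str, list[ScoreEntry]] = {}
        for e in self.entries:
            out.setdefault(e.query_id, []).append(e)
        return out

    def transposed(self) -> "ScoreTable":
        """Swap query/subject roles (valid for symmetric scoring backends)."""
        return ScoreTable(
            query_species=self.subject_species,
            subject_species=self.query_species,
            entries=[ScoreEntry(e.subject_id, e.query_id, e.score, e.e_value)
                     for e in self.entries],
        )


@dataclass(frozen=True, order=True)
class HomologyPair:
    """An unordered homolog pair, normalised lexicographically by (species, gene)."""

    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    score_ab: float = 0.0
    score_ba: float = 0.0
    synteny_level: int = 0

    @staticmethod
    def make(species_a: str, gene_a: str, species_b: str, gene_b: str,
             score_ab: float = 0.0, score_ba: float = 0.0,
             synteny_level: int = 0) -> "HomologyPair":
        if (species_b, gene_b) < (species_a, gene_a):
            species_a, gene_a, species_b, gene_b = species_b, gene_b, species_a, gene_a
            score_ab, score_ba = score_ba, score_ab
        return HomologyPair(species_a, gene_a, species_b, gene_b,
                            score_ab, score_ba, synteny_level)

    def key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return ((self.species_a, self.gene_a), (self.species_b, self.gene_b))


def pair_index(pairs: Iterable[HomologyPair]) -> set[frozenset[tuple[str, str]]]:
    """Membership index over unordered (species, gene) endpoint pairs."""
    return {frozenset(p.key()) for p in pairs}


# ---------------------------------------------------------------------------
# Scoring backends
# ---------------------------------------------------------------------------

# Karlin-Altschul parameters for gapped BLOSUM62 with gap open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041


class BuiltinAligner:
    """Smith-Waterman protein scoring: BLOSUM62, gap open 11, extend 1.

    E-values use a Karlin-Altschul style approximation
    ``E = K * m * n * exp(-lambda * S)`` with fixed gapped BLOSUM62
    parameters.  Deterministic, score-symmetric.
    """

    symmetric = True
    name = "builtin-sw"

    def __init__(self) -> None:
        from Bio.Align import PairwiseAligner, substitution_matrices

        self._aligner = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-11.0,
            extend_gap_score=-1.0,
        )

    def score(self, a: str, b: str) -> float:
        return float(self._aligner.score(a, b))

    @staticmethod
    def e_value(score: float, m: int, n: int) -> float:
        return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)

    def score_all(self, proteome_q: Mapping[str, str],
                  proteome_s: Mapping[str, str],
                  evalue_threshold: float) -> list[ScoreEntry]:
        entries = []
        for qid in sorted(proteome_q):
            q = proteome_q[qid]
            for sid in sorted(proteome_s):
                s = proteome_s[sid]
                score = self.score(q, s)
                if score <= 0:
                    continue
                ev = self.e_value(score, len(q), len(s))
                if ev <= evalue_threshold:
                    entries.append(ScoreEntry(qid, sid, score, ev))
        return entries


class BlastBackend:
    """Adapter over an external ``blastp`` binary (tabular output, bit scores)."""

    symmetric = False
    name = "blastp"

    def __init__(self, blastp: str = "blastp", makeblastdb: str = "makeblastdb"):
        if shutil.which(blastp) is None or shutil.which(makeblastdb) is None:
            raise RuntimeError(
                "external blastp/makeblastdb not found on PATH; "
                "use the built-in aligner backend instead"
            )
        self._blastp = blastp
        self._makeblastdb = makeblastdb

    def score_all(self, proteome_q: Mapping[str, str],
                  proteome_s: Mapping[str, str],
                  evalue_threshold: float) -> list[ScoreEntry]:
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            qf, sf = tmp / "q.faa", tmp / "s.faa"
            for f, prot in ((qf, proteome_q), (sf, proteome_s)):
                with open(f, "w") as fh:
                    for gid in sorted(prot):
                        fh.write(f">{gid}\n{prot[gid]}\n")
            subprocess.run(
                [self._makeblastdb, "-in", str(sf), "-dbtype", "prot"],
                check=True, capture_output=True,
            )
            res = subprocess.run(
                [self._blastp, "-query", str(qf), "-db", str(sf),
                 "-evalue", str(evalue_threshold),
                 "-outfmt", "6 qseqid sseqid bitscore evalue"],
                check=True, capture_output=True, text=True,
            )
        best: dict[tuple[str, str], ScoreEntry] = {}
        for line in res.stdout.splitlines():
            qid, sid, bits, ev = line.split("\t")
            entry = ScoreEntry(qid, sid, float(bits), float(ev))
            key = (qid, sid)
            if key not in best or entry.score > best[key].score:
                best[key] = entry
        return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def score_proteomes(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
                    backend=None, *, species_a: str = "a", species_b: str = "b",
                    evalue_threshold: float = DEFAULT_EVALUE) -> ScoreTable:
    """All-against-all protein scoring of proteome_a (queries) vs proteome_b."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    if backend is None:
        backend = BuiltinAligner()
    entries = backend.score_all(proteome_a, proteome_b, evalue_threshold)
    return ScoreTable(species_a, species_b, entries)


def best_hits(table: ScoreTable,
              tolerance: float = DEFAULT_TOLERANCE) -> dict[str, set[str]]:
    """Per query, every subject scoring within ``tolerance`` of its best hit.

    A subject is kept when its score is >= (1 - tolerance) times the query's
    maximum score, so near-ties with the best alignment are not lost.
    Queries with no entries are absent from the mapping.
    """
    if not (0 <= tolerance < 1):
        raise ValueError("tolerance must be in [0, 1)")
    hits: dict[str, set[str]] = {}
    for qid, entries in table.by_query().items():
        top = max(e.score for e in entries)
        cutoff = (1.0 - tolerance) * top
        hits[qid] = {e.subject_id for e in entries if e.score >= cutoff}
    return hits


def reciprocal_pairs(hits_ab: Mapping[str, set[str]],
                     hits_ba: Mapping[str, set[str]],
                     *, species_a: str = "a", species_b: str = "b",
                     scores_ab: Optional[Mapping[tuple[str, str], float]] = None,
                     scores_ba: Optional[Mapping[tuple[str, str], float]] = None
                     ) -> set[HomologyPair]:
    """Pairs (a, b) with b a relaxed-best hit of a AND a a relaxed-best hit of b."""
    scores_ab = scores_ab or {}
    scores_ba = scores_ba or {}
    pairs = set()
    for a, subjects in hits_ab.items():
        for b in subjects:
            if a in hits_ba.get(b, ()):  # reciprocity
                pairs.add(HomologyPair.make(
                    species_a, a, species_b, b,
                    score_ab=scores_ab.get((a, b), 0.0),
                    score_ba=scores_ba.get((b, a), 0.0),
                ))
    return pairs


def synteny_level(pair: HomologyPair, genome_a: SpeciesGenome,
                  genome_b: SpeciesGenome,
                  all_pairs: Iterable[HomologyPair] | set[frozenset],
                  window: int = DEFAULT_WINDOW,
                  min_common: tuple[int, int, int] = DEFAULT_MIN_COMMON) -> int:
    """Synteny strength of a homolog pair from shared homologous neighbours.

    The two neighbourhoods (``window`` genes each direction, both sides
    pooled) are matched one-to-one: neighbours x of gene_a and y of gene_b are
    matchable when (x, y) is itself a homolog pair.  The size of a maximum
    bipartite matching is the number of neighbour genes in common; the level
    is the highest of 1, 2, 3 whose minimum count is met, else 0.
    """
    index = all_pairs if isinstance(all_pairs, set) and all(
        isinstance(x, frozenset) for x in all_pairs) else pair_index(all_pairs)
    (sp_a, g_a), (sp_b, g_b) = pair.key()
    ga = genome_a if genome_a.species_name == sp_a else genome_b
    gb = genome_b if ga is genome_a else genome_a
    up_a, down_a = neighbors(ga, g_a, window)
    up_b, down_b = neighbors(gb, g_b, window)
    w_a, w_b = up_a + down_a, up_b + down_b
    graph = nx.Graph()
    left = [("A", x) for x in w_a]
    graph.add_nodes_from(left, bipartite=0)
    graph.add_nodes_from(("B", y) for y in w_b)
    for x in w_a:
        for y in w_b:
            if frozenset(((sp_a, x), (sp_b, y))) in index:
                graph.add_edge(("A", x), ("B", y))
    matching = nx.bipartite.maximum_matching(graph, top_nodes=left)
    common = len(matching) // 2
    lvl1, lvl2, lvl3 = min_common
    if common >= lvl3:
        return 3
    if common >= lvl2:
        return 2
    if common >= lvl1:
        return 1
    return 0


def compute_homology(genomes: list[SpeciesGenome], *, backend=None,
                     evalue_threshold: float = DEFAULT_EVALUE,
                     tolerance: float = DEFAULT_TOLERANCE,
                     window: int = DEFAULT_WINDOW,
                     min_common: tuple[int, int, int] = DEFAULT_MIN_COMMON,
                     reciprocal_mode: str = "symmetric") -> list[HomologyPair]:
    """Full homology computation over every unordered species pair.

    ``reciprocal_mode`` controls the reverse direction: ``"symmetric"``
    (default) applies the score tolerance in both directions;
    ``"strict_reverse"`` requires strict (tie-inclusive) best in the reverse.
    Output is sorted deterministically; intra-species self-comparison is
    excluded.  Synteny levels are assigned afterwards over the complete
    cross-species pair set.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two species to compute homology")
    names = [g.species_name for g in genomes]
    if len(set(names)) != len(names):
        raise ValueError("species names must be unique")
    if reciprocal_mode not in ("symmetric", "strict_reverse"):
        raise ValueError(f"unknown reciprocal_mode {reciprocal_mode!r}")
    if backend is None:
        backend = BuiltinAligner()
    by_name = {g.species_name: g for g in genomes}
    all_pairs: set[HomologyPair] = set()
    ordered = sorted(names)
    for i, sa in enumerate(ordered):
        for sb in ordered[i + 1:]:
            pa, pb = by_name[sa].proteome(), by_name[sb].proteome()
            table_ab = score_proteomes(pa, pb, backend, species_a=sa,
                                       species_b=sb,
                                       evalue_threshold=evalue_threshold)
            if getattr(backend, "symmetric", False):
                table_ba = table_ab.transposed()
            else:
                table_ba = score_proteomes(pb, pa, backend, species_a=sb,
                                           species_b=sa,
                                           evalue_threshold=evalue_threshold)
            reverse_tol = tolerance if reciprocal_mode == "symmetric" else 0.0
            hits_ab = best_hits(table_ab, tolerance)
            hits_ba = best_hits(table_ba, reverse_tol)
            scores_ab = {(e.query_id, e.subject_id): e.score for e in table_ab.entries}
            scores_ba = {(e.query_id, e.subject_id): e.score for e in table_ba.entries}
            all_pairs |= reciprocal_pairs(hits_ab, hits_ba, species_a=sa,
                                          species_b=sb, scores_ab=scores_ab,
                                          scores_ba=scores_ba)
    index = pair_index(all_pairs)
    levelled = []
    for pair in sorted(all_pairs):
        level = synteny_level(pair, by_name[pair.species_a],
                              by_name[pair.species_b], index,
                              window=window, min_common=min_common)
        levelled.append(replace(pair, synteny_level=level))
    return sorted(levelled)


def write_homology_tsv(pairs: Iterable[HomologyPair], path: str | Path) -> Path:
    """Homolog pairs as a deterministic TSV."""
    path = Path(path)
    cols = ["species_a", "gene_a", "species_b", "gene_b",
            "score_ab", "score_ba", "synteny_level"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in sorted(pairs):
            fh.write(f"{p.species_a}\t{p.gene_a}\t{p.species_b}\t{p.gene_b}\t"
                     f"{p.score_ab:g}\t{p.score_ba:g}\t{p.synteny_level}\n")
    return path


def read_homology_tsv(path: str | Path) -> list[HomologyPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("species_a"):
            raise ValueError(f"{path}: not a homology TSV")
        for line in fh:
            sa, ga, sb, gb, sab, sba, lvl = line.rstrip("\n").split("\t")
            pairs.append(HomologyPair.make(sa, ga, sb, gb, float(sab),
                                           float(sba), int(lvl)))
    return pairs
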