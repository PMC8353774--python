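"""Seeded synthetic multi-species datasets with recorded ground truth.

Generates an ancestor genome of alternating promoter+CDS blocks, plants
concrete instances of IUPAC motifs in chosen promoters, derives descendant
species by per-base promoter mutation, synonymously-biased CDS mutation and
adjacent-gene swaps, and emits documented-regulation forms with a controlled
cross-species core.  Every planted fact (ortholog map, per-promoter edit
counts, motif placements and retention, regulon membership) is recorded in
truth tables so downstream stages can be scored without re-deriving ground
truth.

Background sequence is i.i.d. uniform over ACGT, which makes chance motif
hits analytically predictable (≈ (L-k+1)·4^-k expected hits of a k-mer per
promoter and strand).  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio.Seq import Seq

from .genome import (Contig, GeneRecord, ProteinRecord, SpeciesGenome,
                     emit_genbank, extract_promoter, revcomp)
from .binding_sites import unfold_iupac
from .homology import HomologyPair
from .regulons import REGULATIONS_FORM_COLUMNS

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]


@dataclass
class PlantedRegulon:
    """A regulon planted identically (core) plus species-specific extras."""

    tf_index: int = 0
    core_targets: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    extras: dict[str, tuple[int, ...]] = field(default_factory=dict)
    core_condition: tuple[str, str, str] = ("acetic acid", "Stress", "Weak acid stress")
    extra_condition: tuple[str, str, str] = ("heat shock 37C", "Stress", "Heat Shock")


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic datasets.

    Defaults model the comparative setting the package targets: a handful of
    yeast-like species at low divergence, 1000 bp promoters, ~300 bp coding
    sequences, and a shared planted regulon with a six-gene core.
    """

    n_species: int = 3
    n_genes: int = 200
    genes_per_contig: int = 50
    promoter_length: int = 1000
    cds_length: int = 300  # includes start and stop codons; multiple of 3
    substitution_rate: float = 0.02
    indel_rate: float = 0.001
    rearrangement_swaps: int = 3
    planted_motifs: tuple[tuple[str, float], ...] = (("GGCGAGGGG", 0.25),
                                                     ("SMGGSG", 0.25))
    planted_regulon: PlantedRegulon = field(default_factory=PlantedRegulon)
    seed: int = 0

    def __post_init__(self):
        if self.cds_length % 3 or self.cds_length < 9:
            raise ValueError("cds_length must be a multiple of 3, >= 9")
        if self.n_genes % self.genes_per_contig:
            raise ValueError("n_genes must be a multiple of genes_per_contig")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("mutation rates must be in [0, 1]")
        for motif, frac in self.planted_motifs:
            if not 0 <= frac <= 1:
                raise ValueError("planted motif fractions must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    gene_index: int  # ancestor gene index
    motif: str  # the IUPAC consensus planted
    concrete: str  # the concrete instance written into the promoter
    offset: int  # 0-based within the promoter
    strand: str  # "forward" | "reverse"


@dataclass
class SpeciesTruth:
    species_name: str
    ortholog_map: dict[int, str]  # ancestor gene index -> derived gene_id
    promoter_substitutions: dict[str, int] = field(default_factory=dict)
    promoter_indels: dict[str, int] = field(default_factory=dict)
    swaps: list[tuple[str, int]] = field(default_factory=list)
    retained_sites: list[PlantedSite] = field(default_factory=list)
    lost_sites: list[PlantedSite] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Ancestor
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_interior = length // 3 - 2
    interior = "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS),
                                                        size=n_interior))
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + interior + stop


def _gene_id(prefix: str, index: int) -> str:
    return f"{prefix}_{index:04d}"


def generate_ancestor(config: FixtureConfig,
                      species_name: str = "ancestor",
                      prefix: str = "ANC") -> SpeciesGenome:
    """Ancestor genome: contigs of alternating promoter and CDS blocks.

    Every gene is on the forward strand with exactly ``promoter_length``
    dedicated upstream bases; CDSs begin with ATG, contain no in-frame stop
    and end with a stop codon; proteins are obtained by translation.
    """
    rng = np.random.default_rng([config.seed, 101])
    genome = SpeciesGenome(species_name, strain="synthetic")
    n_contigs = config.n_genes // config.genes_per_contig
    gi = 0
    for ci in range(n_contigs):
        parts = []
        genes = []
        pos = 0
        for _ in range(config.genes_per_contig):
            promoter = _random_dna(rng, config.promoter_length)
            cds = _random_cds(rng, config.cds_length)
            parts.append(promoter + cds)
            start = pos + config.promoter_length
            genes.append((gi, start, start + config.cds_length))
            pos += config.promoter_length + config.cds_length
            gi += 1
        contig_id = f"{prefix}_contig{ci + 1}"
        genome.add_contig(Contig(contig_id, "".join(parts)))
        for index, start, end in genes:
            gid = _gene_id(prefix, index)
            seq = genome.contig(contig_id).sequence[start:end]
            aa = str(Seq(seq).translate()).rstrip("*")
            genome.add_gene(GeneRecord(
                gene_id=gid, contig_id=contig_id, start=start, end=end,
                strand="forward", description=f"synthetic protein {index}",
                protein=ProteinRecord(protein_name=gid, aa_sequence=aa)))
    return genome


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    gene_index: int
    motif: str
    offset: Optional[int] = None  # drawn uniformly when None
    strand: str = "forward"


def make_placement_plan(config: FixtureConfig,
                        rng: Optional[np.random.Generator] = None) -> list[Placement]:
    """Choose, per motif, a seeded random fraction of promoters to plant in."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 202])
    plan = []
    for motif, fraction in config.planted_motifs:
        n = int(round(fraction * config.n_genes))
        chosen = rng.choice(config.n_genes, size=n, replace=False)
        for gene_index in sorted(int(i) for i in chosen):
            strand = "forward" if rng.random() < 0.5 else "reverse"
            plan.append(Placement(gene_index, motif, None, strand))
    return plan


def plant_sites(genome: SpeciesGenome, plan: Iterable[Placement],
                promoter_length: int, seed: int,
                prefix: str = "ANC") -> list[PlantedSite]:
    """Write concrete motif instances into promoters at recorded positions.

    Each placement draws a concrete sequence from the motif's IUPAC expansion
    and overwrites the background at the chosen offset (reverse-strand plants
    write the reverse complement).  Offset collisions with previously planted
    sites in the same promoter are re-drawn with bounded retries.  The genome
    is modified in place; the planted-occurrence table is returned.
    """
    rng = np.random.default_rng([seed, 303])
    planted: list[PlantedSite] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for placement in plan:
        gid = _gene_id(prefix, placement.gene_index)
        gene = genome.gene(gid)
        if gene.start < promoter_length:
            raise ValueError(f"gene {gid} lacks a full promoter to plant in")
        expansions = sorted(unfold_iupac(placement.motif))
        concrete = expansions[rng.integers(0, len(expansions))]
        k = len(concrete)
        if k > promoter_length:
            raise ValueError(f"motif {placement.motif!r} longer than promoter")
        spans = occupied.setdefault(placement.gene_index, [])
        offset = placement.offset
        if offset is None:
            for _ in range(100):
                cand = int(rng.integers(0, promoter_length - k + 1))
                if all(cand + k <= lo or cand >= hi for lo, hi in spans):
                    offset = cand
                    break
            else:
                raise RuntimeError(
                    f"could not place {placement.motif!r} in promoter of {gid} "
                    f"without collision after 100 retries")
        else:
            if any(offset + k > lo and offset < hi for lo, hi in spans):
                raise RuntimeError(f"explicit offset {offset} collides in {gid}")
        spans.append((offset, offset + k))
        written = concrete if placement.strand == "forward" else revcomp(concrete)
        contig = genome.contig(gene.contig_id)
        pstart = gene.start - promoter_length
        pos = pstart + offset
        contig.sequence = (contig.sequence[:pos] + written +
                           contig.sequence[pos + k:])
        planted.append(PlantedSite(placement.gene_index, placement.motif,
                                   concrete, offset, placement.strand))
    return planted


# ---------------------------------------------------------------------------
# Derivation
# ---------------------------------------------------------------------------


def _mutate_promoter(seq: str, rng: np.random.Generator,
                     sub_rate: float, indel_rate: float) -> tuple[str, int, int]:
    """Per-base substitution and indel process; returns (seq, n_subs, n_indels)."""
    chars = list(seq)
    n_subs = 0
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for i in hits:
            old = chars[i]
            choices = [b for b in "ACGT" if b != old]
            chars[i] = choices[rng.integers(0, 3)]
        n_subs = len(hits)
    n_indels = 0
    if indel_rate > 0:
        out = []
        for c in chars:
            r = rng.random()
            if r < indel_rate / 2:  # deletion
                n_indels += 1
                continue
            if r < indel_rate:  # insertion before the base
                out.append(str(_BASES[rng.integers(0, 4)]))
                n_indels += 1
            out.append(c)
        chars = out
    return "".join(chars), n_subs, n_indels


def _mutate_cds(cds: str, rng: np.random.Generator, sub_rate: float) -> str:
    """Third-codon-position substitutions, avoiding stop creation.

    The ATG start and the final stop codon are preserved so the translated
    protein stays alignable at low divergence.
    """
    if sub_rate <= 0:
        return cds
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i in range(1, len(codons) - 1):
        if rng.random() < sub_rate * 3:  # one mutable position per codon
            codon = codons[i]
            choices = [b for b in "ACGT"
                       if b != codon[2] and codon[:2] + b not in _STOPS]
            if choices:
                codons[i] = codon[:2] + choices[rng.integers(0, len(choices))]
    return "".join(codons)


def derive_species(ancestor: SpeciesGenome, config: FixtureConfig,
                   species_name: str, prefix: str, species_index: int = 1,
                   substitution_rate: Optional[float] = None,
                   indel_rate: Optional[float] = None,
                   planted: Optional[list[PlantedSite]] = None,
                   ancestor_prefix: str = "ANC",
                   ) -> tuple[SpeciesGenome, SpeciesTruth]:
    """Derive a descendant species from the ancestor, with truth tables.

    Promoters receive the per-base substitution/indel process; CDSs are
    mutated at third codon positions only; ``rearrangement_swaps`` adjacent
    gene blocks are swapped per genome.  The truth table records the ortholog
    map (ancestor index → derived gene id), per-promoter edit counts, the
    swap positions, and which planted motif instances survived mutation.
    """
    sub_rate = config.substitution_rate if substitution_rate is None else substitution_rate
    ind_rate = config.indel_rate if indel_rate is None else indel_rate
    rng = np.random.default_rng([config.seed, 404, species_index])
    L = config.promoter_length
    truth = SpeciesTruth(species_name=species_name, ortholog_map={})
    genome = SpeciesGenome(species_name, strain=f"syn{species_index}")
    planted_by_gene: dict[int, list[PlantedSite]] = {}
    for site in planted or []:
        planted_by_gene.setdefault(site.gene_index, []).append(site)

    n_contigs = len(ancestor.contigs)
    swaps_per_contig = [config.rearrangement_swaps // n_contigs] * n_contigs
    for i in range(config.rearrangement_swaps % n_contigs):
        swaps_per_contig[i] += 1
    for contig_no, contig in enumerate(ancestor.contigs):
        order = ancestor.genes_on_contig(contig.contig_id)
        units = []  # (ancestor_index, promoter, cds)
        for gid in order:
            gene = ancestor.genes[gid]
            index = int(gid.rsplit("_", 1)[1])
            promoter = contig.sequence[gene.start - L:gene.start]
            cds = contig.sequence[gene.start:gene.end]
            new_promoter, n_subs, n_ind = _mutate_promoter(promoter, rng,
                                                           sub_rate, ind_rate)
            new_cds = _mutate_cds(cds, rng, sub_rate)
            new_gid = _gene_id(prefix, index)
            truth.ortholog_map[index] = new_gid
            truth.promoter_substitutions[new_gid] = n_subs
            truth.promoter_indels[new_gid] = n_ind
            units.append((index, new_promoter, new_cds))
        units_order = list(range(len(units)))
        new_contig_id = contig.contig_id.replace(ancestor_prefix, prefix, 1)
        for _ in range(swaps_per_contig[contig_no]):
            if len(units_order) < 2:
                break
            j = int(rng.integers(0, len(units_order) - 1))
            units_order[j], units_order[j + 1] = units_order[j + 1], units_order[j]
            truth.swaps.append((new_contig_id, j))
        seq_parts = []
        coords = []
        pos = 0
        for slot in units_order:
            index, promoter, cds = units[slot]
            seq_parts.append(promoter + cds)
            coords.append((index, pos + len(promoter), pos + len(promoter) + len(cds)))
            pos += len(promoter) + len(cds)
        genome.add_contig(Contig(new_contig_id, "".join(seq_parts)))
        for index, start, end in coords:
            gid = _gene_id(prefix, index)
            cds_seq = genome.contig(new_contig_id).sequence[start:end]
            aa = str(Seq(cds_seq).translate()).rstrip("*")
            genome.add_gene(GeneRecord(
                gene_id=gid, contig_id=new_contig_id, start=start, end=end,
                strand="forward", description=f"synthetic protein {index}",
                protein=ProteinRecord(protein_name=gid, aa_sequence=aa)))

    for index, sites in planted_by_gene.items():
        gid = truth.ortholog_map[index]
        prom = extract_promoter(genome, gid, L).sequence
        for site in sites:
            text = site.concrete if site.strand == "forward" else revcomp(site.concrete)
            if text in prom:
                truth.retained_sites.append(site)
            else:
                truth.lost_sites.append(site)
    return genome, truth


def truth_homology_pairs(truths: Iterable[SpeciesTruth]) -> set[HomologyPair]:
    """Planted ortholog pairs across all species, from the truth maps."""
    truths = list(truths)
    pairs = set()
    for i, ta in enumerate(truths):
        for tb in truths[i + 1:]:
            for index, ga in ta.ortholog_map.items():
                if index in tb.ortholog_map:
                    pairs.add(HomologyPair.make(ta.species_name, ga,
                                                tb.species_name,
                                                tb.ortholog_map[index]))
    return pairs


# ---------------------------------------------------------------------------
# Documented-regulation forms
# ---------------------------------------------------------------------------


def generate_regulations(regulon: PlantedRegulon,
                         truths: dict[str, SpeciesTruth],
                         out_dir: str | Path, seed: int,
                         ) -> tuple[dict[str, Path], dict[str, dict[str, set[str]]]]:
    """Emit per-species documented-regulation TSVs with a controlled core.

    The core target set appears in every species (labelled with the core
    condition, e.g. weak acid stress); species-specific extras carry the
    extra condition.  Returns the paths and a truth table
    ``species → {"all": target gene ids, "core": ..., "core_condition": ...}``.
    PubMed IDs are synthetic and deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth: dict[str, dict[str, set[str]]] = {}
    for species in sorted(truths):
        st = truths[species]
        tf_gene = st.ortholog_map[regulon.tf_index]
        rows = []
        all_targets, core_targets = set(), set()
        raw_c, group_c, sub_c = regulon.core_condition
        raw_e, group_e, sub_e = regulon.extra_condition
        for index in regulon.core_targets:
            tgt = st.ortholog_map[index]
            rows.append((tf_gene, tgt, "synthetic", str(20000000 + index),
                         "Expression", "Indirect", "microarray",
                         raw_c, group_c, sub_c))
            all_targets.add(tgt)
            core_targets.add(tgt)
        for index in regulon.extras.get(species, ()):
            tgt = st.ortholog_map[index]
            rows.append((tf_gene, tgt, "synthetic", str(21000000 + index),
                         "Expression", "Indirect", "microarray",
                         raw_e, group_e, sub_e))
            all_targets.add(tgt)
        path = out_dir / f"regulations_{species}.tsv"
        with open(path, "w") as fh:
            fh.write("\t".join(REGULATIONS_FORM_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths[species] = path
        truth[species] = {"all": all_targets, "core": core_targets,
                          "core_condition": core_targets}
    return paths, truth


def write_tfbs_form(motifs: Iterable[str], tf_gene: str, path: str | Path,
                    condition: tuple[str, str, str] = ("acetic acid", "Stress",
                                                       "Weak acid stress")) -> Path:
    """A TFBS submission form assigning IUPAC consensi to one TF."""
    from .binding_sites import TFBS_FORM_COLUMNS

    path = Path(path)
    raw, group, sub = condition
    with open(path, "w") as fh:
        fh.write("\t".join(TFBS_FORM_COLUMNS) + "\n")
        for i, motif in enumerate(motifs):
            fh.write("\t".join([tf_gene, motif, "synthetic",
                                str(22000000 + i), "DNA Binding",
                                "EMSA", raw, group, sub]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Whole bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    config: FixtureConfig
    ancestor: SpeciesGenome
    genomes: dict[str, SpeciesGenome]
    truths: dict[str, SpeciesTruth]
    planted_sites: list[PlantedSite]
    genbank_paths: dict[str, Path] = field(default_factory=dict)
    regulation_paths: dict[str, Path] = field(default_factory=dict)
    regulon_truth: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    tfbs_path: Optional[Path] = None

    @property
    def species_names(self) -> list[str]:
        return sorted(self.genomes)


def generate_bundle(config: FixtureConfig,
                    out_dir: Optional[str | Path] = None) -> FixtureBundle:
    """Ancestor + planted sites + derived species (+ files when out_dir given).

    Species are named ``sp01..spNN`` with gene prefixes ``SP1..``; the first
    species serves as the reference/query by convention.  When the planted
    regulon has no per-species extras configured, deterministic extras are
    assigned to every species except the first (the query species, which has
    no documented data of its own — the cross-species projection setting).
    """
    ancestor = generate_ancestor(config)
    plan = make_placement_plan(config)
    planted = plant_sites(ancestor, plan, config.promoter_length, config.seed)
    names = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    regulon = config.planted_regulon
    if not regulon.extras and config.n_species >= 2:
        extras = {}
        base = max([regulon.tf_index, *regulon.core_targets]) + 1
        for i, name in enumerate(names[1:]):
            lo = base + 3 * i
            extras[name] = tuple(j for j in range(lo, lo + 3)
                                 if j < config.n_genes)
        regulon = replace(regulon, extras=extras)
    genomes: dict[str, SpeciesGenome] = {}
    truths: dict[str, SpeciesTruth] = {}
    for i, name in enumerate(names):
        genome, truth = derive_species(
            ancestor, config, name, prefix=f"SP{i + 1}", species_index=i + 1,
            planted=planted)
        genomes[name] = genome
        truths[name] = truth
    bundle = FixtureBundle(config=config, ancestor=ancestor, genomes=genomes,
                           truths=truths, planted_sites=planted)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, genome in genomes.items():
            path = out_dir / f"{name}.gbff"
            emit_genbank(genome, path)
            bundle.genbank_paths[name] = path
        source_truths = {n: truths[n] for n in names[1:]} if len(names) > 1 \
            else dict(truths)
        bundle.regulation_paths, bundle.regulon_truth = generate_regulations(
            regulon, source_truths, out_dir, config.seed)
        motifs = [m for m, _ in config.planted_motifs]
        tf_gene = truths[names[0]].ortholog_map[regulon.tf_index]
        bundle.tfbs_path = write_tfbs_form(motifs, tf_gene,
                                           out_dir / "tfbs_form.tsv")
        _write_truth_json(bundle, out_dir / "truth.json")
    return bundle


def _write_truth_json(bundle: FixtureBundle, path: Path) -> None:
    payload = {
        "species": bundle.species_names,
        "seed": bundle.config.seed,
        "ortholog_maps": {n: {str(k): v for k, v in t.ortholog_map.items()}
                          for n, t in bundle.truths.items()},
        "planted_sites": [
            {"gene_index": s.gene_index, "motif": s.motif,
             "concrete": s.concrete, "offset": s.offset, "strand": s.strand}
            for s in bundle.planted_sites],
        "promoter_substitutions": {n: t.promoter_substitutions
                                   for n, t in bundle.truths.items()},
        "regulon_truth": {n: {k: sorted(v) for k, v in d.items()}
                          for n, d in bundle.regulon_truth.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
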