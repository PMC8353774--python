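"""Documented regulations and cross-species regulon projection.

A documented regulation is a literature-curated TF→target edge with a PubMed
reference, evidence code, association type and environmental-condition label.
Given homology between a query species and a source species, a source TF's
documented regulon is projected into the query species: every source gene
homologous to the query gene contributes its documented targets, and each
target is mapped to its query-species homolog(s), with full provenance.  The
core regulon is the intersection of the projections from several source
species — the evolutionarily conserved target set.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .binding_sites import EVIDENCE_CODES
from .homology import HomologyPair

ASSOCIATION_TYPES = {"Direct", "Indirect", "N/A"}

#: Default environmental-condition vocabulary: 13 groups, each with sub-groups.
#: The named stress sub-groups are the ones exercised by the Haa1 case; the
#: remaining groups are a configurable placeholder taxonomy users replace with
#: their own table.
DEFAULT_CONDITION_VOCABULARY: dict[str, set[str]] = {
    "Stress": {"Weak acid stress", "Heat Shock", "Oxidative stress",
               "Osmotic stress", "Other"},
    "Carbon source": {"Glucose", "Xylose", "Glycerol", "Other"},
    "Nitrogen source": {"Rich", "Limited", "Other"},
    "Oxygen availability": {"Aerobic", "Anaerobic", "Hypoxic", "Other"},
    "Nutrient starvation": {"Carbon", "Nitrogen", "Phosphate", "Other"},
    "Temperature": {"Low", "High", "Shift", "Other"},
    "pH": {"Acidic", "Alkaline", "Shift", "Other"},
    "Chemical agents": {"Drugs", "Solvents", "Other"},
    "Metal ions": {"Excess", "Depletion", "Other"},
    "Osmotic balance": {"Hyperosmotic", "Hypoosmotic", "Other"},
    "Cell cycle": {"G1", "S", "G2/M", "Other"},
    "Development": {"Sporulation", "Filamentation", "Mating", "Other"},
    "Unstressed": {"Exponential growth", "Stationary phase", "Other"},
}


class VocabularyError(ValueError):
    pass


@dataclass(frozen=True)
class Reference:
    pubmed_id: int
    title: str = ""
    authors: str = ""
    journal: str = ""
    year: Optional[int] = None

    def __post_init__(self):
        if self.pubmed_id <= 0:
            raise ValueError("pubmed_id must be a positive integer")


@dataclass(frozen=True)
class ConditionLabel:
    raw: str
    group: str
    subgroup: str = ""


@dataclass(frozen=True)
class DocumentedRegulation:
    tf_name: str
    target_gene: str
    strain: str
    reference: Reference
    evidence_code: str
    association_type: str
    experimental_evidence: str
    condition: ConditionLabel
    species: str = ""

    def dedup_key(self):
        return (self.tf_name, self.target_gene, self.reference.pubmed_id,
                self.condition)


@dataclass(frozen=True)
class PredictedTarget:
    """One query-species target with its projection provenance."""

    gene_id: str  # query-species gene
    source_target: str  # the documented target in the source species
    homology: HomologyPair  # pair linking source_target to gene_id
    regulations: tuple[DocumentedRegulation, ...]  # supporting documented edges
    source_tf: str  # the source-species TF whose regulon was projected


@dataclass
class RegulonPrediction:
    query_species: str
    query_gene: str
    source_species: str
    source_tfs: list[str] = field(default_factory=list)
    targets: list[PredictedTarget] = field(default_factory=list)
    n_unmapped_targets: int = 0
    status: str = "ok"

    def target_genes(self) -> set[str]:
        return {t.gene_id for t in self.targets}


# ---------------------------------------------------------------------------
# Loading the documented-regulations form
# ---------------------------------------------------------------------------

REGULATIONS_FORM_COLUMNS = [
    "Transcription Factor", "Target Gene", "Strain",
    "Supporting reference (PubMed ID)", "Evidence Code", "Association Type",
    "Experimental Evidence", "Environmental Condition",
    "Environmental condition Group", "Environmental condition sub-group",
]


def load_regulations_form(
        path: str | Path, *,
        known_tfs: Optional[Iterable[str]] = None,
        known_genes: Optional[Iterable[str]] = None,
        vocabulary: Optional[Mapping[str, set[str]]] = None,
        species: str = "") -> tuple[list[DocumentedRegulation], list[str]]:
    """Load and validate the documented-regulations form (tab-separated).

    Validations: all fields present, TF and target known to the store (when
    the known sets are given), PubMed ID numeric, evidence code and
    association type in their vocabularies, condition group/sub-group in the
    condition vocabulary.  Exact duplicates (same TF, target, reference and
    condition) are collapsed.  Per-row failures are reported with line
    numbers; a missing column is fatal.
    """
    vocab = dict(vocabulary) if vocabulary is not None else DEFAULT_CONDITION_VOCABULARY
    tfs = set(known_tfs) if known_tfs is not None else None
    genes = set(known_genes) if known_genes is not None else None
    records: list[DocumentedRegulation] = []
    seen = set()
    errors: list[str] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in REGULATIONS_FORM_COLUMNS
                   if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            tf = row["Transcription Factor"].strip()
            target = row["Target Gene"].strip()
            if not tf or not target:
                errors.append(f"line {lineno}: missing TF or target gene")
                continue
            if tfs is not None and tf not in tfs:
                errors.append(f"line {lineno}: unknown transcription factor {tf!r}")
                continue
            if genes is not None and target not in genes:
                errors.append(f"line {lineno}: unknown target gene {target!r}")
                continue
            try:
                pubmed = int(row["Supporting reference (PubMed ID)"].strip())
                if pubmed <= 0:
                    raise ValueError
            except ValueError:
                errors.append(f"line {lineno}: invalid PubMed ID "
                              f"{row['Supporting reference (PubMed ID)']!r}")
                continue
            evidence = row["Evidence Code"].strip()
            if evidence not in EVIDENCE_CODES:
                errors.append(f"line {lineno}: evidence code {evidence!r} "
                              f"not in {sorted(EVIDENCE_CODES)}")
                continue
            assoc = row["Association Type"].strip()
            if assoc not in ASSOCIATION_TYPES:
                errors.append(f"line {lineno}: association type {assoc!r} "
                              f"not in {sorted(ASSOCIATION_TYPES)}")
                continue
            group = row["Environmental condition Group"].strip()
            subgroup = row["Environmental condition sub-group"].strip()
            if group not in vocab:
                errors.append(f"line {lineno}: unknown condition group {group!r}")
                continue
            if subgroup and subgroup not in vocab[group]:
                errors.append(f"line {lineno}: unknown sub-group {subgroup!r} "
                              f"of group {group!r}")
                continue
            reg = DocumentedRegulation(
                tf_name=tf, target_gene=target, strain=row["Strain"].strip(),
                reference=Reference(pubmed_id=pubmed),
                evidence_code=evidence, association_type=assoc,
                experimental_evidence=row["Experimental Evidence"].strip(),
                condition=ConditionLabel(
                    raw=row["Environmental Condition"].strip(),
                    group=group, subgroup=subgroup),
                species=species,
            )
            if reg.dedup_key() in seen:
                continue  # exact duplicate: idempotent load
            seen.add(reg.dedup_key())
            records.append(reg)
    return records, errors


def filter_by_condition(regulations: Iterable[DocumentedRegulation],
                        group: str, subgroup: Optional[str] = None,
                        vocabulary: Optional[Mapping[str, set[str]]] = None
                        ) -> set[DocumentedRegulation]:
    """Regulations whose condition matches a group (and sub-group, if given).

    Filtering uses the pre-assigned group/sub-group labels, never the raw
    condition strings.
    """
    vocab = dict(vocabulary) if vocabulary is not None else DEFAULT_CONDITION_VOCABULARY
    if group not in vocab:
        raise VocabularyError(f"unknown condition group {group!r}")
    if subgroup is not None and subgroup not in vocab[group]:
        raise VocabularyError(f"unknown sub-group {subgroup!r} of group {group!r}")
    return {r for r in regulations
            if r.condition.group == group
            and (subgroup is None or r.condition.subgroup == subgroup)}


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def _homologs_of(gene: tuple[str, str], other_species: str,
                 homology: Iterable[HomologyPair],
                 min_synteny_level: int = 0) -> list[tuple[str, HomologyPair]]:
    """Genes of ``other_species`` homologous to ``gene``, with their pairs."""
    species, gene_id = gene
    out = []
    for pair in homology:
        if pair.synteny_level < min_synteny_level:
            continue
        ends = dict(pair.key())
        if ends.get(species) == gene_id and other_species in ends \
                and other_species != species:
            out.append((ends[other_species], pair))
        # a species pair may also appear with reversed roles in the key dict
    return sorted(out)


def project_regulon(query_gene: tuple[str, str], source_species: str,
                    homology: Iterable[HomologyPair],
                    regulations: Iterable[DocumentedRegulation],
                    condition_filter: Optional[tuple[str, Optional[str]]] = None,
                    min_synteny_level: int = 0,
                    vocabulary: Optional[Mapping[str, set[str]]] = None
                    ) -> RegulonPrediction:
    """Project a source species' documented regulons onto a query gene.

    All source-species genes homologous to the query gene are treated as
    candidate TFs (several may qualify, as with the two close homologs a query
    regulator can have in one source species); the union of their documented
    targets — optionally restricted to an environmental-condition group or
    sub-group — is mapped through homology into the query species.  Targets
    with no query-species homolog are dropped but counted.  Every predicted
    target keeps full provenance: the source target, the homolog pair used,
    and the supporting documented regulations.
    """
    query_species, query_gene_id = query_gene
    homology = list(homology)
    prediction = RegulonPrediction(query_species=query_species,
                                   query_gene=query_gene_id,
                                   source_species=source_species)
    source_tfs = _homologs_of(query_gene, source_species, homology,
                              min_synteny_level)
    if not source_tfs:
        prediction.status = (f"no homolog of {query_species}/{query_gene_id} "
                             f"found in {source_species}")
        return prediction
    prediction.source_tfs = [tf for tf, _ in source_tfs]
    regs = [r for r in regulations
            if (not r.species or r.species == source_species)]
    if condition_filter is not None:
        group, subgroup = condition_filter
        allowed = filter_by_condition(regs, group, subgroup, vocabulary)
        regs = [r for r in regs if r in allowed]
    by_tf: dict[str, list[DocumentedRegulation]] = {}
    for r in regs:
        by_tf.setdefault(r.tf_name, []).append(r)
    seen_unmapped = set()
    for source_tf, _pair in source_tfs:
        by_target: dict[str, list[DocumentedRegulation]] = {}
        for r in by_tf.get(source_tf, []):
            by_target.setdefault(r.target_gene, []).append(r)
        for source_target in sorted(by_target):
            images = _homologs_of((source_species, source_target),
                                  query_species, homology, min_synteny_level)
            if not images:
                seen_unmapped.add((source_tf, source_target))
                continue
            for image_gene, pair in images:
                prediction.targets.append(PredictedTarget(
                    gene_id=image_gene,
                    source_target=source_target,
                    homology=pair,
                    regulations=tuple(sorted(
                        by_target[source_target],
                        key=lambda r: (r.reference.pubmed_id, r.condition.raw))),
                    source_tf=source_tf,
                ))
    prediction.n_unmapped_targets = len(seen_unmapped)
    if not prediction.targets:
        prediction.status = (
            f"homologous TF(s) {prediction.source_tfs} found in "
            f"{source_species} but no documented target could be projected")
    return prediction


# ---------------------------------------------------------------------------
# Core regulon and Venn regions
# ---------------------------------------------------------------------------


@dataclass
class CoreRegulon:
    core: set[str]
    venn: dict[str, int]  # region label ("A", "A&B", ...) -> exclusive count
    labels: list[str]


def core_regulon(predictions: list[RegulonPrediction]) -> CoreRegulon:
    """Intersection of predicted target sets, with exclusive Venn-region counts.

    Requires at least two predictions over the same query species.  Region
    labels join the source-species names of the member sets with ``&``; each
    count is exclusive (targets in exactly that combination of sets).
    """
    if len(predictions) < 2:
        raise ValueError("core_regulon needs at least two predictions")
    species = {p.query_species for p in predictions}
    if len(species) != 1:
        raise ValueError("predictions must share the same query species")
    labels = []
    for i, p in enumerate(predictions):
        label = p.source_species if p.source_species not in labels \
            else f"{p.source_species}#{i}"
        labels.append(label)
    sets = [p.target_genes() for p in predictions]
    core = set.intersection(*sets)
    venn: dict[str, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), r):
            inside = set.intersection(*(sets[i] for i in combo))
            outside = set().union(*(sets[i] for i in range(len(sets))
                                    if i not in combo)) if len(combo) < len(sets) else set()
            region = inside - outside
            venn["&".join(labels[i] for i in combo)] = len(region)
    return CoreRegulon(core=core, venn=venn, labels=labels)


def write_venn_json(core: CoreRegulon, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "labels": core.labels,
        "core": sorted(core.core),
        "core_size": len(core.core),
        "regions": {k: core.venn[k] for k in sorted(core.venn)},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

NETWORK_COLUMNS = ["source_tf", "source_species", "target_gene", "query_species",
                   "source_target", "evidence_codes", "association_types",
                   "conditions", "pubmed_ids"]


def export_network(prediction: RegulonPrediction, path: str | Path,
                   fmt: str = "tsv") -> Path:
    """Deterministic edge-list export of a projected regulon.

    ``tsv`` writes one TF→target edge per line with provenance columns;
    ``json`` writes the same content as a structured document.
    """
    path = Path(path)
    rows = []
    for t in sorted(prediction.targets,
                    key=lambda t: (t.source_tf, t.gene_id, t.source_target)):
        rows.append({
            "source_tf": t.source_tf,
            "source_species": prediction.source_species,
            "target_gene": t.gene_id,
            "query_species": prediction.query_species,
            "source_target": t.source_target,
            "evidence_codes": ";".join(sorted({r.evidence_code for r in t.regulations})),
            "association_types": ";".join(sorted({r.association_type
                                                  for r in t.regulations})),
            "conditions": ";".join(sorted({f"{r.condition.group}/{r.condition.subgroup}"
                                           for r in t.regulations})),
            "pubmed_ids": ";".join(str(p) for p in sorted(
                {r.reference.pubmed_id for r in t.regulations})),
        })
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(NETWORK_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(row[c] for c in NETWORK_COLUMNS) + "\n")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump({"query_gene": prediction.query_gene,
                       "query_species": prediction.query_species,
                       "source_species": prediction.source_species,
                       "source_tfs": prediction.source_tfs,
                       "status": prediction.status,
                       "edges": rows}, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (use 'tsv' or 'json')")
    return path


def load_pubmed_metadata(references: Iterable[Reference],
                         metadata_path: str | Path) -> list[Reference]:
    """Enrich references from a user-supplied JSON file keyed by PubMed ID.

    No network access: metadata absent from the file is left empty.
    """
    with open(metadata_path) as fh:
        meta = json.load(fh)
    out = []
    for ref in references:
        m = meta.get(str(ref.pubmed_id), {})
        out.append(Reference(pubmed_id=ref.pubmed_id,
                             title=m.get("title", ref.title),
                             authors=m.get("authors", ref.authors),
                             journal=m.get("journal", ref.journal),
                             year=m.get("year", ref.year)))
    return out
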