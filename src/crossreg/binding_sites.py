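"""IUPAC TF binding-site consensi: unfolding, exact promoter scanning, and
precomputation of potential regulations.

Binding sites are stored as IUPAC consensus strings (e.g. the Haa1 minimal
motif ``SMGGSG``).  Because the matcher only allows exact matches, each
consensus is first unfolded into the Cartesian set of concrete (non-degenerate)
sequences it denotes, and every exact occurrence of any of those sequences in a
promoter is reported.  A potential regulation is the TF→gene edge created
whenever at least one binding site of the TF occurs at least once in the gene's
promoter.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from math import prod
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .genome import Promoter, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

EVIDENCE_CODES = {"DNA Binding", "Expression", "Prediction", "N/A"}

DEFAULT_UNFOLD_CAP = 65536


class ExpansionCapError(ValueError):
    """Raised when an IUPAC expansion would exceed the configured cap."""

    def __init__(self, consensus: str, cardinality: int, cap: int):
        self.consensus = consensus
        self.cardinality = cardinality
        self.cap = cap
        super().__init__(
            f"consensus {consensus!r} unfolds to {cardinality} sequences, "
            f"exceeding the cap of {cap}"
        )


def validate_iupac(consensus: str) -> str:
    """Uppercase and validate an IUPAC consensus; returns the cleaned string."""
    if not consensus:
        raise ValueError("consensus must be non-empty")
    consensus = consensus.upper()
    for i, c in enumerate(consensus):
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC character {c!r} at position {i}")
    return consensus


def unfold_cardinality(consensus: str) -> int:
    """Number of concrete sequences an IUPAC consensus denotes."""
    return prod(len(IUPAC[c]) for c in validate_iupac(consensus))


def unfold_iupac(consensus: str, cap: int = DEFAULT_UNFOLD_CAP) -> set[str]:
    """Cartesian expansion of an IUPAC consensus into concrete sequences.

    The cardinality equals the product of the per-symbol degeneracies; an
    expansion larger than ``cap`` is refused before materialisation.
    """
    consensus = validate_iupac(consensus)
    if cap < 1:
        raise ValueError("cap must be >= 1")
    card = unfold_cardinality(consensus)
    if card > cap:
        raise ExpansionCapError(consensus, card, cap)
    return {"".join(p) for p in itertools.product(*(IUPAC[c] for c in consensus))}


def iupac_matches(consensus: str, concrete: str) -> bool:
    """Position-wise IUPAC compatibility of a concrete sequence with a consensus."""
    return len(consensus) == len(concrete) and all(
        b in IUPAC[a] for a, b in zip(consensus.upper(), concrete.upper()))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SiteOccurrence:
    offset: int  # 0-based within the promoter
    strand: str  # "forward" | "reverse"
    matched: str  # the concrete site text as given (not the promoter slice)
    tf_name: str = ""
    gene_id: str = ""


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)  # overlapping occurrences included


def scan_promoter(promoter_sequence: str, sites: Iterable[str],
                  strands: str = "both", *, tf_name: str = "",
                  gene_id: str = "") -> list[SiteOccurrence]:
    """Every exact occurrence of every concrete site in a promoter.

    Matching is case-insensitive and exact; overlapping occurrences are all
    reported.  ``strands="both"`` additionally reports reverse-strand hits,
    found by matching each site's reverse complement against the promoter;
    for those, the promoter slice at the reported offset equals the reverse
    complement of ``matched``.  An N in the promoter never matches (an
    unknown base is not evidence of a site).  Output is sorted by offset.
    """
    if strands not in ("both", "forward-only"):
        raise ValueError(f"strands must be 'both' or 'forward-only', got {strands!r}")
    promoter = promoter_sequence.upper()
    occurrences: list[SiteOccurrence] = []
    for site in sorted(set(s.upper() for s in sites)):
        if not site:
            continue
        if any(c not in "ACGT" for c in site):
            raise ValueError(f"site {site!r} is not concrete DNA; unfold it first")
        for off in _find_all(promoter, site):
            occurrences.append(SiteOccurrence(off, "forward", site, tf_name, gene_id))
        if strands == "both":
            rc = revcomp(site)
            for off in _find_all(promoter, rc):
                occurrences.append(SiteOccurrence(off, "reverse", site, tf_name, gene_id))
    return sorted(occurrences)


# ---------------------------------------------------------------------------
# TFBS library and potential regulations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingSite:
    tf_name: str
    consensus: str
    strain: str = ""
    tf_species: str = ""
    pubmed_id: Optional[int] = None
    evidence_code: str = "N/A"
    experimental_evidence: str = ""
    condition: str = ""
    condition_group: str = ""
    condition_subgroup: str = ""


@dataclass(frozen=True)
class PotentialRegulation:
    tf_name: str
    tf_species: str
    target_gene: str
    target_species: str
    n_occurrences: int


@dataclass
class PotentialRegulationReport:
    regulations: set[PotentialRegulation] = field(default_factory=set)
    site_errors: list[str] = field(default_factory=list)

    def for_target(self, target_species: str, target_gene: str) -> set[str]:
        """Distinct TF names with a potential regulation on a target gene."""
        return {r.tf_name for r in self.regulations
                if r.target_species == target_species
                and r.target_gene == target_gene}


def compute_potential_regulations(
        tfbs_library: Iterable[BindingSite],
        promoters: Mapping[str, Mapping[str, "Promoter | str"]],
        strands: str = "both",
        cap: int = DEFAULT_UNFOLD_CAP) -> PotentialRegulationReport:
    """Scan every TF's unfolded sites against every species' promoters.

    ``promoters`` maps species name → {gene_id → Promoter or sequence}.
    Cross-species scans are included: a TF of one species is searched in the
    promoters of all species.  Occurrences are aggregated per (TF, target
    gene); one edge is emitted whenever the count is at least one.  Per-site
    expansion-cap failures are recorded and skipped, not fatal.
    """
    report = PotentialRegulationReport()
    # unfolded site set per TF (sites pooled across the TF's consensi)
    tf_sites: dict[tuple[str, str], set[str]] = {}
    for site in tfbs_library:
        key = (site.tf_name, site.tf_species)
        try:
            tf_sites.setdefault(key, set()).update(unfold_iupac(site.consensus, cap))
        except ValueError as exc:
            report.site_errors.append(f"{site.tf_name}/{site.consensus}: {exc}")
    counts: dict[tuple[str, str, str, str], int] = {}
    for species in sorted(promoters):
        for gene_id in sorted(promoters[species]):
            prom = promoters[species][gene_id]
            seq = prom.sequence if isinstance(prom, Promoter) else prom
            for (tf, tf_species), sites in sorted(tf_sites.items()):
                hits = scan_promoter(seq, sites, strands,
                                     tf_name=tf, gene_id=gene_id)
                if hits:
                    counts[(tf, tf_species, gene_id, species)] = len(hits)
    for (tf, tf_species, gene, species), n in counts.items():
        report.regulations.add(
            PotentialRegulation(tf, tf_species, gene, species, n))
    return report


# ---------------------------------------------------------------------------
# Form loading
# ---------------------------------------------------------------------------

TFBS_FORM_COLUMNS = [
    "Transcription Factor", "Consensus", "Strain",
    "Supporting reference (PubMed ID)", "Evidence Code",
    "Experimental Evidence", "Environmental Condition",
    "Environmental condition Group", "Environmental condition sub-group",
]


def load_tfbs_form(path: str | Path, *,
                   known_tfs: Optional[Iterable[str]] = None,
                   tf_species: str = "") -> tuple[list[BindingSite], list[str]]:
    """Load the TFBS submission form (tab-separated, one header line).

    Each row is validated: the TF must exist in the store when ``known_tfs``
    is given, the consensus must be valid IUPAC, the PubMed ID numeric, and
    the evidence code in the controlled vocabulary.  Valid rows are returned;
    invalid rows are reported with line numbers.  A missing required column
    is fatal.
    """
    known = set(known_tfs) if known_tfs is not None else None
    records: list[BindingSite] = []
    errors: list[str] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in TFBS_FORM_COLUMNS
                   if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            tf = row["Transcription Factor"].strip()
            if not tf:
                errors.append(f"line {lineno}: missing Transcription Factor")
                continue
            if known is not None and tf not in known:
                errors.append(f"line {lineno}: unknown transcription factor {tf!r}")
                continue
            try:
                consensus = validate_iupac(row["Consensus"].strip())
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            pubmed_raw = row["Supporting reference (PubMed ID)"].strip()
            try:
                pubmed = int(pubmed_raw)
                if pubmed <= 0:
                    raise ValueError
            except ValueError:
                errors.append(f"line {lineno}: invalid PubMed ID {pubmed_raw!r}")
                continue
            evidence = row["Evidence Code"].strip()
            if evidence not in EVIDENCE_CODES:
                errors.append(
                    f"line {lineno}: evidence code {evidence!r} not in "
                    f"{sorted(EVIDENCE_CODES)}")
                continue
            records.append(BindingSite(
                tf_name=tf,
                consensus=consensus,
                strain=row["Strain"].strip(),
                tf_species=tf_species,
                pubmed_id=pubmed,
                evidence_code=evidence,
                experimental_evidence=row["Experimental Evidence"].strip(),
                condition=row["Environmental Condition"].strip(),
                condition_group=row["Environmental condition Group"].strip(),
                condition_subgroup=row["Environmental condition sub-group"].strip(),
            ))
    return records, errors


def write_potential_regulations_tsv(report: PotentialRegulationReport,
                                    path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("tf_name\ttf_species\ttarget_gene\ttarget_species\tn_occurrences\n")
        for r in sorted(report.regulations,
                        key=lambda r: (r.tf_species, r.tf_name,
                                       r.target_species, r.target_gene)):
            fh.write(f"{r.tf_name}\t{r.tf_species}\t{r.target_gene}\t"
                     f"{r.target_species}\t{r.n_occurrences}\n")
    return path


def write_occurrences_bed(occurrences: Iterable[SiteOccurrence],
                          path: str | Path, promoter_name: str = "promoter") -> Path:
    """Occurrences as BED-like 0-based intervals relative to promoter start."""
    path = Path(path)
    with open(path, "w") as fh:
        for occ in sorted(occurrences):
            strand = "+" if occ.strand == "forward" else "-"
            fh.write(f"{promoter_name}\t{occ.offset}\t{occ.offset + len(occ.matched)}\t"
                     f"{occ.tf_name or occ.matched}\t0\t{strand}\n")
    return path
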