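"""Whole-genome comparative analyses of promoter conservation.

Two analyses over homologous gene pairs, with one species fixed as the
comparison basis: (1) promoter divergence — the Levenshtein edit distance
between the promoters (default 1000 bp upstream of the START codon) of each
homolog pair, summarised as a per-species distribution; (2) TFBS conservation
— for each pair, the number of distinct TFs predicted (from the reference
species' binding-site library) on both promoters, relative to those predicted
only on the reference promoter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .binding_sites import PotentialRegulationReport
from .genome import Promoter
from .homology import HomologyPair


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass(frozen=True)
class DivergenceRecord:
    pair: HomologyPair
    distance: int
    length_reference: int
    reference_truncated: bool = False
    other_truncated: bool = False


@dataclass(frozen=True)
class ConservationFraction:
    pair: HomologyPair
    n_common: int
    n_reference_only: int

    @property
    def defined(self) -> bool:
        return self.n_reference_only > 0

    @property
    def fraction(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.n_common / self.n_reference_only


def _promoter_seq(p: "Promoter | str") -> tuple[str, bool]:
    if isinstance(p, Promoter):
        return p.sequence, p.truncated
    return p, False


def _pairs_between(homology: Iterable[HomologyPair], species_x: str,
                   species_y: str) -> list[HomologyPair]:
    out = []
    for pair in homology:
        species = {pair.species_a, pair.species_b}
        if species == {species_x, species_y}:
            out.append(pair)
    return sorted(out)


def promoter_divergence(reference_species: str, other_species: str,
                        homology: Iterable[HomologyPair],
                        promoters: Mapping[str, Mapping[str, "Promoter | str"]],
                        ) -> tuple[list[DivergenceRecord], dict[str, float]]:
    """Levenshtein distance between the promoters of every homolog pair.

    ``promoters`` maps species → {gene_id → promoter}.  Each homolog pair
    between the two species contributes one record (a reference gene with
    several homologs contributes one record per pair).  Truncated promoters
    are compared as-is, with flags carried into the records.  Returns the
    records and a five-number-plus-mean summary of the distances.
    """
    records = []
    for pair in _pairs_between(homology, reference_species, other_species):
        ends = dict(pair.key())
        ref_gene, other_gene = ends[reference_species], ends[other_species]
        try:
            ref_p = promoters[reference_species][ref_gene]
            oth_p = promoters[other_species][other_gene]
        except KeyError as exc:
            raise KeyError(f"missing promoter for homolog pair {pair}: {exc}")
        ref_seq, ref_trunc = _promoter_seq(ref_p)
        oth_seq, oth_trunc = _promoter_seq(oth_p)
        records.append(DivergenceRecord(
            pair=pair, distance=levenshtein(ref_seq, oth_seq),
            length_reference=len(ref_seq),
            reference_truncated=ref_trunc, other_truncated=oth_trunc))
    summary = summarize([r.distance for r in records])
    return records, summary


def tfbs_conservation_fraction(pair: HomologyPair,
                               potential_regs: PotentialRegulationReport,
                               reference_species: str) -> ConservationFraction:
    """Common vs reference-only TFs predicted on a homolog pair's promoters.

    ``potential_regs`` must have been computed with the reference species'
    binding-site library scanned against both species (the reference TFBSs
    searched in the promoters of homologous genes).  Counts are of DISTINCT
    TFs, not individual site occurrences.  The fraction ``common /
    reference_only`` is undefined when no TF is exclusive to the reference
    promoter.
    """
    ends = dict(pair.key())
    if reference_species not in ends:
        raise ValueError(f"pair {pair} does not involve {reference_species}")
    other_species = next(s for s in ends if s != reference_species)
    s_ref = potential_regs.for_target(reference_species, ends[reference_species])
    s_other = potential_regs.for_target(other_species, ends[other_species])
    return ConservationFraction(
        pair=pair,
        n_common=len(s_ref & s_other),
        n_reference_only=len(s_ref - s_other),
    )


def tfbs_conservation(reference_species: str, other_species: str,
                      homology: Iterable[HomologyPair],
                      potential_regs: PotentialRegulationReport,
                      ) -> tuple[list[ConservationFraction], dict[str, float], int]:
    """Conservation fractions for all homolog pairs between two species.

    Pairs with an undefined fraction are excluded from the summary; their
    count is returned alongside.
    """
    fractions = [tfbs_conservation_fraction(p, potential_regs, reference_species)
                 for p in _pairs_between(homology, reference_species, other_species)]
    defined = [f.fraction for f in fractions if f.defined]
    return fractions, summarize(defined), sum(1 for f in fractions if not f.defined)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize(values: Sequence[float]) -> dict[str, float]:
    """Five-number summary plus mean; ``{"n": 0}`` for an empty list."""
    if len(values) == 0:
        return {"n": 0}
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "q1": float(np.percentile(arr, 25)),
        "median": float(np.median(arr)),
        "q3": float(np.percentile(arr, 75)),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
    }


def distribution_report(values_by_label: Mapping[str, Sequence[float]],
                        plot_path: Optional[str | Path] = None) -> pd.DataFrame:
    """Per-label summary table (and optional boxplot rendering).

    Labels are reported in sorted order; a label with no values gets an
    ``n=0`` row.  When ``plot_path`` is given, a boxplot of the non-empty
    labels is rendered there.
    """
    rows = []
    for label in sorted(values_by_label):
        row = {"label": label, **summarize(values_by_label[label])}
        rows.append(row)
    table = pd.DataFrame(rows, columns=["label", "n", "min", "q1", "median",
                                        "q3", "max", "mean"])
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        nonempty = {k: list(v) for k, v in sorted(values_by_label.items()) if len(v)}
        fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(nonempty)), 4))
        if nonempty:
            ax.boxplot(list(nonempty.values()), tick_labels=list(nonempty))
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return table


def write_divergence_tsv(records: Iterable[DivergenceRecord],
                         path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("species_a\tgene_a\tspecies_b\tgene_b\tdistance\t"
                 "length_reference\treference_truncated\tother_truncated\n")
        for r in sorted(records, key=lambda r: r.pair):
            p = r.pair
            fh.write(f"{p.species_a}\t{p.gene_a}\t{p.species_b}\t{p.gene_b}\t"
                     f"{r.distance}\t{r.length_reference}\t"
                     f"{int(r.reference_truncated)}\t{int(r.other_truncated)}\n")
    return path


def write_fractions_tsv(fractions: Iterable[ConservationFraction],
                        path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("species_a\tgene_a\tspecies_b\tgene_b\t"
                 "n_common\tn_reference_only\tfraction\tdefined\n")
        for f in sorted(fractions, key=lambda f: f.pair):
            p = f.pair
            frac = f"{f.fraction:g}" if f.defined else "NA"
            fh.write(f"{p.species_a}\t{p.gene_a}\t{p.species_b}\t{p.gene_b}\t"
                     f"{f.n_common}\t{f.n_reference_only}\t{frac}\t{int(f.defined)}\n")
    return path
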