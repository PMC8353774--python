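# Methods

This note documents the algorithms, parameter choices and numerical
conventions behind `crossreg`, and the modeling decisions taken where the
problem statement admits more than one reasonable reading.

## Coordinates and sequences

Internally all coordinates are 0-based half-open on the forward strand of a
contig; GenBank's 1-based inclusive positions are converted on parse and
emit. Ambiguous nucleotide letters in input sequences are normalized to `N`.
A gene's promoter is the fixed-length window (default `promoter_length =
1000` bp) immediately upstream of its START codon on the coding strand: for
a forward gene, `contig[start-L : start]`; for a reverse gene, the reverse
complement of `contig[end : end+L]`. Windows truncated by a contig edge are
flagged and kept at their natural (shorter) length. A fixed window is a
deliberate simplification — real promoters vary in extent — but makes the
scan statistics uniform and comparable across genes and species.

## Homology

- **Scoring.** The built-in backend uses Biopython's `PairwiseAligner` in
  local mode with BLOSUM62, gap open −11 and gap extension −1 (the classic
  BLASTP parameterization). Because the scoring scheme is symmetric,
  `S(a,b) = S(b,a)` and the reverse-direction score table is obtained by
  transposition rather than recomputation, halving the cost. An adapter for
  an external `blastp` is provided for large genomes but is optional and
  never exercised by the tests.
- **Significance.** Scores are converted to E-values with the ungapped
  Karlin–Altschul formula `E = K·m·n·exp(−λ·S)` using λ = 0.267, K = 0.041
  (the standard gapped BLOSUM62 parameters); entries with `E > 1e-5` are
  discarded. This is an approximation — exact gapped statistics require
  simulation — but only its monotone ordering matters here.
- **Relaxed reciprocal best hits.** Subject `b` is a relaxed best hit of
  query `a` when `S(a,b) ≥ (1 − t)·max_b' S(a,b')` with tolerance
  `t = 0.10`. A pair is accepted when the relation holds in both
  directions. The default mode applies the tolerance symmetrically; a
  `strict_reverse` mode (tie-inclusive strict best in the reverse
  direction) is available, and strict-reverse pairs are provably a subset
  of symmetric ones. Symmetric tolerance was chosen as the default because
  the asymmetric variant makes the result depend on which species is called
  "query", which the rest of the pipeline treats as arbitrary.
- **Multiple homologs.** Tolerance deliberately admits many-to-many pairs
  (paralog pairs from duplications). Downstream consumers must not assume
  one-to-one maps; regulon projection in particular takes the union over
  all homolog candidates.
- **Synteny.** For a homolog pair, the ±`window = 15` neighboring genes of
  each member on its contig are pooled (both sides together; fewer near
  contig edges). Neighbors `x` of one side and `y` of the other are
  matchable when `(x, y)` is itself a homolog pair; the size of a maximum
  bipartite matching (computed with networkx, never double-counting a
  neighbor) is the number of neighbors in common. Levels 1/2/3 require
  ≥ 1/≥ 2/≥ 3 common neighbors (`min_common = (1, 2, 3)`); level sets are
  nested by construction.

## Binding-site scanning

An IUPAC consensus is validated and unfolded by Cartesian expansion into
concrete sequences; the count equals the product of per-symbol degeneracies
and is refused above a cap (default 65536) with an error that names the
would-be cardinality. Scanning is exact, case-insensitive substring search
of each unfolded sequence against the promoter (forward strand) and of its
reverse complement (reverse-strand hits), reporting all overlapping
occurrences; `N` in a promoter matches nothing. Potential regulations
aggregate occurrences per (TF, target gene): one edge with an occurrence
count, independent of promoter iteration order. Per-site unfolding errors
are collected, not fatal.

## Documented regulations and projection

Curation forms are TSVs with fixed required columns. Loading validates
IUPAC consensus strings (TFBS form), evidence codes (`DNA Binding`,
`Expression`, `Prediction`, `N/A`), association types (`Direct`,
`Indirect`, `N/A`), positive PubMed ids, known TF/gene names when a genome
is available, and condition labels against a configurable two-level
vocabulary (group / subgroup); errors carry line numbers, and exact
duplicate rows (same TF, target, reference, condition) collapse to one
record.

Projection of source species `S` onto query gene `q`: every `S`-homolog of
`q` is a candidate TF; the projected regulon is the union over candidates
of their documented targets, each mapped through the homology relation to
query-species genes (targets with no homolog are counted as unmapped, not
silently dropped). Condition filtering restricts the documented records
before mapping. An optional minimum synteny level restricts which homology
edges are trusted. The core regulon over several sources is the
intersection of projected target sets; exclusive Venn region counts are
reported alongside.

## Conservation

Promoter divergence between homologs is the Levenshtein distance (edlib
bindings; an independent quadratic dynamic-programming oracle is kept in
the tests). Distances are summarized by a five-number summary plus mean.
TFBS conservation for a homolog pair is `n_common / n_reference_only` over
the *distinct* TFs predicted on the two promoters — occurrence counts are
ignored so a TF with many sites does not dominate — and is undefined
(reported, not fabricated) when no TF is exclusive to the reference
promoter.

## Synthetic data generator

The generator produces an ancestor genome (all-forward genes, contigs of
`promoter + CDS` blocks, i.i.d. uniform background, CDSs with a START, no
internal STOPs and a terminal STOP) and evolves each descendant species
independently with:

- per-base promoter substitutions (rate 0.02 by default) and indels
  (0.001),
- CDS mutations confined to third codon positions and never creating a
  STOP, so proteins stay highly alignable at low divergence,
- a fixed number of adjacent-gene swaps per genome (local rearrangement),
- planted motif instances (defaults: `GGCGAGGGG` and the degenerate
  `SMGGSG`) written into ancestor promoters at recorded offsets/strands
  with collision retry, and
- a planted regulon: one TF, a 6-gene core shared by every species plus
  species-specific extra targets, with distinct condition labels for core
  (`Stress / Weak acid stress`) vs extras.

Every stochastic step draws from `numpy.random.default_rng([seed, stream,
index])`, so outputs are reproducible and byte-identical across runs.
Truth tables record the ortholog map, per-promoter edit counts, swap
positions, surviving vs lost planted sites, and the planted regulon —
enabling recall/exactness checks with no circularity (the tests compare
pipeline output against the generator's bookkeeping, not against the
pipeline).

What the generator does *not* emulate: gene gain/loss, horizontal
transfer, large-scale rearrangement, reverse-strand genes, intergenic
regions beyond the promoter window, codon-usage bias, or realistic motif
positional bias. It is a test harness, not an evolution simulator;
quantities derived from it characterize the pipeline, not biology.

## Determinism and persistence

Genomes, homology, forms and scan results persist in an embedded SQLite
store. All artifact writers sort their rows, the GenBank emitter uses a
fixed LOCUS date, and the run manifest contains no timestamps — only the
configuration echo, stage counts and SHA-256 checksums — so repeated runs
with the same inputs are byte-identical.

## Limitations

- E-values use ungapped Karlin–Altschul statistics with gapped scores;
  absolute values are approximate.
- Exact-match scanning has no mismatch or PWM model; degenerate motifs
  must be expressible in IUPAC.
- Fixed-length promoters ignore UTR annotation and operon structure.
- Projection inherits every curation error of the source species and
  treats all homolog candidates equally regardless of score margin.
- The conservation fraction is sensitive to the choice of reference
  species and undefined for pairs without reference-exclusive TFs.
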