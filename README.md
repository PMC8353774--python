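# crossreg

Cross-species transcription-regulation inference for microbes with little or
no curated regulatory data.

## The problem

Curated regulatory networks (TF → target-gene associations backed by
literature evidence) exist for a handful of model species. For everything
else, the practical route is comparative: map genes of a poorly studied
species onto a well-annotated relative through sequence homology, then carry
the documented regulations and binding-site knowledge across that map.
`crossreg` implements this pipeline end to end:

1. **Genome store** — parse GenBank flat files into an embedded relational
   store (SQLite); extract fixed-length promoters (default 1000 bp upstream
   of the START codon, on the coding strand); gene neighborhoods; GO
   annotations.
2. **Homology** — tolerance-relaxed reciprocal best-score protein pairs with
   a synteny strength level per pair.
3. **Binding sites** — IUPAC consensus unfolding and exact both-strand
   promoter scanning, giving *potential regulations* (TF → gene edges
   supported by ≥ 1 exact binding-site occurrence in the gene's promoter).
4. **Regulons** — validated loading of documented-regulation forms,
   environmental-condition filtering, projection of a documented regulon
   from one or more source species onto a query gene, and the *core
   regulon* (intersection across sources, with Venn region counts).
5. **Conservation** — promoter edit-distance divergence between homologs
   and the fraction of predicted TF regulators conserved across species.
6. **Synthetic fixtures** — a seeded generator that evolves descendant
   genomes from a common ancestor with known (planted) orthology, binding
   sites and regulons, so every stage can be tested against ground truth.

## Model and conventions

**Homology.** For proteomes $A$ and $B$, all-against-all local alignment
scores $S(a,b)$ (BLOSUM62, gap open −11, extend −1) are converted to
E-values via the Karlin–Altschul approximation
$E = K\,m\,n\,e^{-\lambda S}$ ($\lambda = 0.267$, $K = 0.041$) and filtered
at $E \le 10^{-5}$. $b$ is a *relaxed best hit* of $a$ when
$S(a,b) \ge (1-t)\max_{b'} S(a,b')$ with tolerance $t = 0.10$; a pair is
homologous when each side is a relaxed best hit of the other. Near-ties are
therefore kept instead of being discarded by a strict best-hit rule.
Synteny strength pools the ±15 neighboring genes of each member, counts
homologous neighbor pairs by maximum bipartite matching, and assigns level
1/2/3 at ≥ 1/≥ 2/≥ 3 common neighbors.

**Binding sites.** An IUPAC consensus $c_1\dots c_k$ unfolds into
$\prod_i |\,\mathrm{IUPAC}(c_i)\,|$ concrete sequences (capped, default
65536). Scanning is exact substring matching of every unfolded sequence
against the promoter and its reverse complement; overlapping occurrences
are all reported and `N` in a promoter never matches.

**Projection.** For query gene $q$, every source-species homolog of $q$ is
a candidate TF (gene duplications give several); the projected regulon is
the union over candidates of their documented targets mapped through the
homology relation, with full provenance (source TF, source target, evidence
codes, conditions, PubMed ids). The core regulon across $n$ sources is the
intersection of the projected target sets.

**Conservation.** Promoter divergence is the Levenshtein distance between
the promoters of a homolog pair. TFBS conservation for a pair is
`n_common / n_reference_only` over the *distinct* TFs predicted on each
promoter (undefined when no TF is reference-exclusive).

## Worked example

```python
from crossreg import (FixtureConfig, generate_bundle, compute_homology,
                      unfold_iupac, scan_promoter, extract_promoter,
                      load_regulations_form, project_regulon, core_regulon,
                      truth_homology_pairs)

bundle = generate_bundle(FixtureConfig(n_species=3, n_genes=40,
                                       genes_per_contig=20, seed=7), "bundle/")

# 1. exact homologs with synteny levels
pairs = compute_homology([bundle.genomes[n] for n in bundle.species_names])
print(f"{len(pairs)} homolog pairs")
p = sorted(pairs, key=lambda p: p.gene_a)[0]
print(f"example: {p.species_a}:{p.gene_a} <-> {p.species_b}:{p.gene_b} "
      f"(synteny level {p.synteny_level})")

# 2. binding-site scan of a promoter
sites = unfold_iupac("SMGGSG")
print(f"SMGGSG unfolds to {len(sites)} sequences")
promoter = extract_promoter(bundle.genomes["sp01"], "SP1_0001", 1000)
hits = scan_promoter(promoter.sequence, sites, "both")
print(f"{len(hits)} occurrences in the SP1_0001 promoter; first: {hits[0]}")

# 3. cross-species regulon projection
hom = truth_homology_pairs(bundle.truths.values())
tf = bundle.truths["sp01"].ortholog_map[0]
preds = []
for src in ("sp02", "sp03"):
    regs, _ = load_regulations_form(bundle.regulation_paths[src], species=src)
    pred = project_regulon(("sp01", tf), src, hom, regs)
    preds.append(pred)
    print(f"{src}: {len(pred.target_genes())} projected targets for {tf}")
print(f"core regulon: {sorted(core_regulon(preds).core)}")
```

Output:

```
120 homolog pairs
example: sp01:SP1_0000 <-> sp02:SP2_0000 (synteny level 3)
SMGGSG unfolds to 8 sequences
9 occurrences in the SP1_0001 promoter; first: SiteOccurrence(offset=129, strand='reverse', matched='CCGGGG', tf_name='', gene_id='')
sp02: 9 projected targets for SP1_0000
sp03: 9 projected targets for SP1_0000
core regulon: ['SP1_0001', 'SP1_0002', 'SP1_0003', 'SP1_0004', 'SP1_0005', 'SP1_0006']
```

## Command line

```sh
crossreg fixtures --out bundle --n-species 3 --n-genes 40 --seed 7
crossreg ingest -c bundle/pipeline.yaml
crossreg load-tfbs -c bundle/pipeline.yaml --species sp01 bundle/tfbs_form.tsv
crossreg load-regulations -c bundle/pipeline.yaml --species sp02 bundle/regulations_sp02.tsv
crossreg run-all -c bundle/pipeline.yaml     # homology + scan + conservation + manifest
crossreg project-regulon -c bundle/pipeline.yaml \
    --query-species sp01 --query-gene SP1_0000 --source sp02 --source sp03
```

`run-all` writes every artifact (TSV/JSON) plus `manifest.json` with SHA-256
checksums; repeated runs with the same seed are byte-identical.

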