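# irkit — comparative intron-retention analysis

Intron retention (IR) is the mode of alternative splicing in which an
intron survives into the mature transcript, typically introducing a
premature termination codon and marking the transcript for
nonsense-mediated decay. In terminally differentiated cells such as
granulocytes, IR acts as a post-transcriptional dial on gene expression,
and its prevalence varies sharply across vertebrates. `irkit` implements
the full comparative analysis around that observation as a tested,
reusable Python library plus a set of narrative analysis drivers:

- **IR quantification** from per-base coverage and splice-junction
  counts. For an intron, `IR ratio = median(intron depth) /
  median(pooled flanking-exon depth)`, clamped to [0, 1]. An intron
  counts as retained when `IR ratio >= 0.1`, supported by >= 4 reads
  exactly crossing the junction, with `splicing depth + trimmed mean
  intron depth >= 10` and no splicing internal to the intron. Per gene,
  the maximum retained-intron ratio is the gene's IR ratio; genes with
  FPKM >= 1 count as expressed.
- **Retained-intron characterization**: length fold difference (FD =
  mean non-retained / mean retained), GC content, intron phase, in-frame
  stop-codon (PTC) density, relative position `index / n_introns`, and
  the binned length-vs-IR-ratio trend.
- **Splice-site strength** as a maximum-entropy model over fixed donor
  (9 nt) and acceptor (23 nt) windows with singleton + adjacent +
  skip-one pairwise marginal constraints, fit by iterative proportional
  fitting with exact sum-product inference on the induced clique chain;
  a site scores `log2 P_model(x) / P_background(x)` bits.
- **3' UTR / miRNA analyses**: spliced 3'-UTR lengths, perfect seed
  matches (reverse complement of miRNA positions 2–8), per-gene site
  counts, and Sylamer-style 6-mer enrichment with upper-tail cumulative
  hypergeometric p-values, Bonferroni-corrected over all 4^6 words.
- **Gene architecture**: head-to-head / tail-to-tail / tandem
  classification of adjacent gene pairs with the corresponding
  TSS–TSS / end–end / end–TSS distances; head-to-head pairs within 1 kb
  are treated as sharing a bidirectional promoter.
- **Cross-species conservation**: ortholog-by-species IR profile matrix,
  quantile normalization, k-means row clustering, 1 − Pearson
  average-linkage species dendrogram, n-way IR-ortholog intersection
  counts, and the Pearson correlation between IR-gene fraction and
  protein-coding gene count.
- **miRNA-sponge kinetics**: a mass-action competing-endogenous-RNA ODE
  system in which an intron-retaining sponge transcript titrates a
  shared miRNA away from a target, with stoichiometric or catalytic
  complex decay.

Real granulocyte RNA-seq is not bundled. Instead, `irkit.simulate`
generates annotation, genome sequence and alignment-level evidence with
planted ground truth for every downstream stage — per-intron retention
fractions, class-dependent intron length/GC/splice-site strength, 3'
positional bias, head-to-head pair placement, class-dependent UTR
lengths, and collision-free planted miRNA seed sites — so every claim
the analysis makes can be checked against a known answer.

## Worked example

```bash
cd analysis
python 01_simulate_cohort.py
python 02_quantify_ir.py
python 06_gene_architecture.py
python 07_conservation.py
```

prints (seed 1, the default in `analysis/_common.py`):

```
simulated 5 species x 200 genes; planted conserved IR core: 86 ortholog groups
study: 20.0% of expressed genes retain >= 1 intron
...
HH pairs <= 1 kb: 23.5% of IR-gene pairs vs 4.0% overall (Fisher p=2.11e-03)
...
IR orthologs shared by all species: 86 (planted core: 86)
published species table: Pearson r(IR fraction, pc genes) = -0.95
```

Reading: the `study` species recovers its planted 20% IR-gene fraction
from coverage evidence alone; the bidirectional-promoter excess planted
among IR genes (23% vs ~5% baseline) is recovered and significant; the
five-way intersection of IR orthologs equals the planted 86-gene
conserved core exactly; and the published five-species table (pc gene
counts 20296, 22547, 19856, 15508, 25642 against IR fractions 17.4%,
13.6%, 18.6%, 40.8%, 7.8%) yields Pearson r = −0.95.

The same stages are available as a CLI (`irkit run-all --seed 1
--out-dir results`, or individual subcommands `simulate`, `quantify`,
`features`, `maxent`, `mirna`, `architecture`, `conserve`, `sponge`) and
as library functions under `irkit.*`.

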