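"""Adjacent gene-pair classification and IR-gene architecture statistics.

Adjacent genes are classified head-to-head (HH, divergent: -/+ with
facing transcription start sites), tail-to-tail (TT, convergent: +/-) or
tandem (TH, same strand). The intergenic distance is TSS-to-TSS for HH
pairs, transcript-end-to-end for TT, and upstream end to downstream TSS
for TH; HH pairs within 1 kb are treated as sharing a bidirectional
promoter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GenePair:
    gene_a: str
    gene_b: str
    orientation: str  # HH | TT | TH
    distance: int  # bp, >= 0


def classify_adjacent_pairs(ann) -> list[GenePair]:
    """Classify every pair of genomically adjacent genes per chromosome.

    Adjacency is nearest-neighbour by TSS order; overlapping genes get
    distance 0.
    """
    by_chrom: dict[str, list] = {}
    for g in ann.genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.tss, g.id))
        for left, right in zip(genes, genes[1:]):
            sa, sb = left.strand, right.strand
            if sa == sb:
                orient = "TH"
                # upstream gene's transcript end to downstream gene's TSS
                if sa == "+":
                    d = right.tss - left.tes
                else:
                    d = right.tes - left.tss
            elif sa == "-" and sb == "+":
                orient = "HH"
                d = right.tss - left.tss
            else:
                orient = "TT"
                d = right.tes - left.tes
            pairs.append(
                GenePair(
                    gene_a=left.id,
                    gene_b=right.id,
                    orientation=orient,
                    distance=max(0, int(d)),
                )
            )
    return pairs


def bidirectional_fraction(pairs, subset=None, cutoff: int = 1000) -> float:
    """Fraction of pairs (optionally restricted to ``subset`` gene ids,
    both members required) that are HH within ``cutoff`` bp."""
    if subset is not None:
        subset = set(subset)
        pairs = [p for p in pairs if p.gene_a in subset and p.gene_b in subset]
    if not pairs:
        return 0.0
    hh = sum(1 for p in pairs if p.orientation == "HH" and p.distance <= cutoff)
    return hh / len(pairs)


def bidirectional_enrichment(pairs, ir_genes, cutoff: int = 1000):
    """Fisher exact test: HH-within-cutoff rate for both-IR pairs vs other."""
    ir = set(ir_genes)
    tab = np.zeros((2, 2), dtype=int)
    for p in pairs:
        is_ir_pair = p.gene_a in ir and p.gene_b in ir
        is_hh = p.orientation == "HH" and p.distance <= cutoff
        tab[0 if is_ir_pair else 1, 0 if is_hh else 1] += 1
    odds, pval = stats.fisher_exact(tab, alternative="greater")
    return {
        "table": tab,
        "odds_ratio": float(odds),
        "p_value": float(pval),
        "fraction_ir": tab[0, 0] / tab[0].sum() if tab[0].sum() else 0.0,
        "fraction_other": tab[1, 0] / tab[1].sum() if tab[1].sum() else 0.0,
    }


def distance_histogram(pairs, bin_kb: float = 1.0, max_kb: float = 20.0):
    """Binned intergenic distances per orientation class."""
    edges = np.arange(0, max_kb + bin_kb, bin_kb)
    out = {}
    for orient in ("HH", "TT", "TH"):
        d = [p.distance / 1000.0 for p in pairs if p.orientation == orient]
        out[orient], _ = np.histogram(d, bins=edges)
    out["edges_kb"] = edges
    return out


def retained_count_histogram(gene_irs) -> dict[int, int]:
    """Counts of IR genes by number of retained introns (k = 1, 2, ...)."""
    hist: dict[int, int] = {}
    for g in gene_irs.values():
        if g.is_ir_gene:
            hist[g.n_retained] = hist.get(g.n_retained, 0) + 1
    return dict(sorted(hist.items()))


def retained_density(n_retained_introns: int, exonic_kbp: float) -> float:
    """Retained introns per kbp of merged exonic sequence."""
    if exonic_kbp <= 0:
        raise ValueError("exonic_kbp must be positive")
    return n_retained_introns / exonic_kbp


def intron_count_vs_ir(ann, gene_irs):
    """Distribution of intron number for IR genes vs other expressed genes."""
    counts_ir, counts_other = [], []
    for gid, g in gene_irs.items():
        gene = ann.genes.get(gid)
        if gene is None or not g.is_expressed:
            continue
        k = len(gene.representative_transcript().exons) - 1
        (counts_ir if g.is_ir_gene else counts_other).append(k)
    res = {
        "counts_ir": np.asarray(counts_ir),
        "counts_other": np.asarray(counts_other),
        "mean_ir": float(np.mean(counts_ir)) if counts_ir else float("nan"),
        "mean_other": float(np.mean(counts_other)) if counts_other else float("nan"),
    }
    if counts_ir and counts_other:
        res["rank_p"] = float(
            stats.mannwhitneyu(counts_ir, counts_other, alternative="two-sided").pvalue
        )
    return res
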