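"""Synthetic annotation, genome, and alignment evidence with planted truth.

Stands in for granulocyte RNA-seq across species: multi-intron gene models
with per-intron retention fractions (rho), class-dependent intron length /
GC / splice-site strength (retained introns shorter, GC-richer, with
weaker sites), a 3' positional bias of retention, head-to-head gene-pair
placement, class-dependent 3' UTR lengths with collision-free planted
miRNA seed sites, and Poisson coverage / junction evidence:

    exonic depth   ~ Poisson(c * e)          per base
    intronic depth ~ Poisson(c * e * rho)    per base
    junction reads ~ Poisson(c_j * e * (1 - rho))

where e is the gene's planted expression (FPKM scale) and c, c_j are
configured coverage factors. Planted categorical fractions (IR-gene
fraction among expressed genes, head-to-head-pair fractions) are planted
as exact rounded counts so that recovery checks measure estimator error,
not planting noise. Fixed seed => byte-identical FASTA/GTF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import GeneModel, GenomeAnnotation, TranscriptModel
from .maxent import revcomp
from .quantify import CoverageStore, JunctionCounts

DNA = np.array(list("ACGT"))


@dataclass
class ClassParams:
    """Per-class (retained vs non-retained) intron properties."""

    length_scale: float  # multiplier on the log-normal intron length scale
    gc_mean: float  # mean intronic GC fraction
    site_strength: float  # 1 = consensus-like splice sites, 0 = uniform


@dataclass
class SimConfig:
    n_genes: int = 200
    mean_introns_per_gene: float = 7.0
    max_introns_per_gene: int = 25
    # intron length: log-normal, class length_scale multiplies the median
    intron_len_median: float = 850.0
    intron_len_sigma_log: float = 0.55
    intron_len_min: int = 70
    exon_len_median: float = 130.0
    exon_len_sigma_log: float = 0.35
    exon_len_min: int = 12
    exon_gc: float = 0.45
    retained: ClassParams = field(
        default_factory=lambda: ClassParams(
            length_scale=0.35, gc_mean=0.55, site_strength=0.35
        )
    )
    non_retained: ClassParams = field(
        default_factory=lambda: ClassParams(
            length_scale=1.0, gc_mean=0.42, site_strength=0.9
        )
    )
    # retention truth
    ir_gene_fraction: float = 0.2  # fraction of *expressed* genes with IR
    retained_intron_frac: float = 0.3  # per-intron retention rate in IR genes
    position_bias: float = 0.6  # 0 = uniform, 1 = fully 3'-weighted retention
    rho_low: float = 0.15
    rho_beta_a: float = 1.5
    rho_beta_b: float = 6.0
    ir_prob_by_introns: bool = False  # IR-gene propensity proportional to intron count
    # phase distributions over {0,1,2} per class
    phase_probs_retained: tuple = (0.42, 0.34, 0.24)
    phase_probs_non_retained: tuple = (0.52, 0.30, 0.18)
    # expression / sequencing
    expressed_fraction: float = 0.85
    expr_mu_log: float = np.log(25.0)
    expr_sigma_log: float = 1.0
    coverage_per_fpkm: float = 2.0  # c: exonic depth per expression unit
    junction_per_fpkm: float = 2.0  # c_j: junction reads per expression unit
    ir_gene_expr_floor: float = 15.0  # planted IR genes sit well above FPKM 1
    expr_floor: float = 2.0  # floor for other expressed genes
    read_length: int = 100
    # gene architecture
    utr5_len: int = 50
    bidir_fraction_ir: float = 0.23  # HH <= 1 kb among IR-gene pairs
    bidir_fraction_other: float = 0.05
    min_intergenic: int = 2000
    # 3' UTR / miRNA
    utr3_median_ir: float = 1200.0
    utr3_median_other: float = 600.0
    utr3_sigma_log: float = 0.45
    utr3_len_min: int = 60
    utr3_intron_prob_ir: float = 0.15
    utr3_intron_prob_other: float = 0.04
    n_mirnas: int = 20
    mirna_length: int = 22
    seed_rate_ir: float = 3.0  # planted UTR seed sites per kb, IR genes
    seed_rate_other: float = 1.5
    intron_seed_rate_retained: float = 0.9  # planted intron sites per kb
    intron_seed_rate_other: float = 0.3
    # sequence emission can be skipped for architecture-only studies
    emit_sequence: bool = True
    chrom: str = "chr1"
    gene_prefix: str = "G"
    ir_class_override: dict | None = None  # gene index -> bool, for panels
    rng_seed: int = 0

    def validate(self) -> list[str]:
        bad = []
        for name in (
            "ir_gene_fraction",
            "retained_intron_frac",
            "position_bias",
            "expressed_fraction",
            "bidir_fraction_ir",
            "bidir_fraction_other",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                bad.append(f"{name}={v} outside [0,1]")
        for name in ("intron_len_median", "exon_len_median", "utr3_median_ir",
                     "utr3_median_other", "coverage_per_fpkm"):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be positive")
        return bad


@dataclass
class SimTruth:
    rho: dict[str, float] = field(default_factory=dict)  # intron id -> rho
    expression: dict[str, float] = field(default_factory=dict)  # gene -> FPKM
    is_ir_gene: dict[str, bool] = field(default_factory=dict)
    is_expressed: dict[str, bool] = field(default_factory=dict)
    utr_seed_sites: dict[str, list] = field(default_factory=dict)  # gene -> [(mirna, pos)]
    intron_seed_sites: dict[str, list] = field(default_factory=dict)
    utr3_intron_ids: set = field(default_factory=set)
    utr3_length: dict[str, int] = field(default_factory=dict)  # spliced UTR length
    planted_hh_pairs: list = field(default_factory=list)  # (gene_a, gene_b, distance)
    mirnas: dict[str, str] = field(default_factory=dict)  # id -> RNA sequence
    intron_phase: dict[str, int] = field(default_factory=dict)


# splice-site positional probability models (columns A,C,G,T); the +1/+2
# GT and -2/-1 AG dinucleotides are fixed.
DONOR_PWM = np.array(
    [
        [0.33, 0.36, 0.18, 0.13],  # exon -3
        [0.60, 0.13, 0.14, 0.13],  # exon -2
        [0.08, 0.04, 0.81, 0.07],  # exon -1
        [0.00, 0.00, 1.00, 0.00],  # intron +1 (G)
        [0.00, 0.00, 0.00, 1.00],  # intron +2 (T)
        [0.59, 0.03, 0.34, 0.04],  # +3
        [0.71, 0.08, 0.12, 0.09],  # +4
        [0.06, 0.05, 0.84, 0.05],  # +5
        [0.17, 0.18, 0.20, 0.45],  # +6
    ]
)

_PPT = [0.10, 0.32, 0.10, 0.48]  # polypyrimidine tract column
ACCEPTOR_PWM = np.array(
    [_PPT] * 14
    + [
        [0.25, 0.30, 0.10, 0.35],  # -6
        [0.06, 0.40, 0.06, 0.48],  # -5
        [0.26, 0.30, 0.20, 0.24],  # -4 (branch-adjacent, mixed)
        [0.05, 0.62, 0.01, 0.32],  # -3 (C/T)
        [1.00, 0.00, 0.00, 0.00],  # -2 (A)
        [0.00, 0.00, 1.00, 0.00],  # -1 (G)
        [0.25, 0.15, 0.48, 0.12],  # exon +1
        [0.25, 0.25, 0.25, 0.25],  # +2
        [0.25, 0.25, 0.25, 0.25],  # +3
    ]
)


def _strength_pwm(pwm: np.ndarray, strength: float) -> np.ndarray:
    """Interpolate consensus PWM toward uniform; fixed columns stay fixed."""
    out = np.empty_like(pwm)
    for i, col in enumerate(pwm):
        if col.max() == 1.0:
            out[i] = col
        else:
            mix = np.power(col.clip(1e-6), strength)
            out[i] = mix / mix.sum()
    return out


def _sample_site(pwm: np.ndarray, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=col) for col in pwm]
    return "".join(DNA[idx])


def _rand_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _exact_subset(items, fraction: float, rng: np.random.Generator):
    """Choose round(fraction * n) items uniformly (exact planted count)."""
    items = list(items)
    k = int(round(fraction * len(items)))
    if k == 0:
        return set()
    picked = rng.choice(len(items), size=k, replace=False)
    return {items[i] for i in picked}


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# generate_annotation_and_genome
# ---------------------------------------------------------------------------


def generate_annotation_and_genome(cfg: SimConfig):
    """Build annotation + genome sequence + truth under the planted model.

    Returns ``(GenomeAnnotation, {chrom: sequence or None}, SimTruth)``.
    Deterministic under cfg.rng_seed.
    """
    bad = cfg.validate()
    if bad:
        raise ConfigError("; ".join(bad))
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_genes
    truth = SimTruth()

    # --- miRNA panel -------------------------------------------------------
    for m in range(cfg.n_mirnas):
        seq = "".join(DNA[rng.integers(0, 4, cfg.mirna_length)])
        truth.mirnas[f"mir-{m + 1}"] = seq.replace("T", "U")
    seed_words = {
        mid: revcomp(seq.replace("U", "T")[1:8]) for mid, seq in truth.mirnas.items()
    }

    # --- per-gene structure draws -----------------------------------------
    p_geo = min(1.0, 1.0 / cfg.mean_introns_per_gene) if cfg.mean_introns_per_gene > 0 else 1.0
    if cfg.mean_introns_per_gene <= 0:
        n_introns = np.zeros(n, dtype=int)
    else:
        n_introns = np.minimum(
            rng.geometric(p_geo, size=n), cfg.max_introns_per_gene
        )

    # --- class assignment (IR gene / expressed), exact planted counts -----
    gene_ids = [f"{cfg.gene_prefix}{i + 1:05d}" for i in range(n)]
    n_blocks = n // 2
    is_ir = np.zeros(n, dtype=bool)
    if cfg.ir_class_override is not None:
        for i in range(n):
            is_ir[i] = bool(cfg.ir_class_override.get(i, False))
        # override-IR genes must have at least one intron to retain
        n_introns[is_ir] = np.maximum(n_introns[is_ir], 1)
    elif cfg.ir_prob_by_introns:
        # retention propensity proportional to intron count
        mean_k = max(n_introns.mean(), 1e-9)
        probs = np.clip(
            cfg.ir_gene_fraction * n_introns / mean_k, 0, 1
        )
        is_ir = (rng.random(n) < probs) & (n_introns > 0)
    else:
        # same-class blocks of two adjacent genes; IR blocks spread out so
        # that cross-block adjacent pairs are never both-IR
        n_expr_planned = int(round(cfg.expressed_fraction * n))
        n_ir = int(round(cfg.ir_gene_fraction * n_expr_planned))
        n_ir_blocks = min(n_blocks, n_ir // 2)
        if n_ir_blocks > 0:
            block_pos = np.unique(
                np.linspace(0, n_blocks - 1, n_ir_blocks).round().astype(int)
            )
            for b in block_pos:
                is_ir[2 * b] = True
                is_ir[2 * b + 1] = True
    is_ir &= n_introns > 0  # single-exon genes cannot retain introns

    # expressed flags: IR genes always expressed; exact count among the rest
    is_expr = np.zeros(n, dtype=bool)
    is_expr[is_ir] = True
    rest = [i for i in range(n) if not is_ir[i]]
    n_expr_target = int(round(cfg.expressed_fraction * n))
    need = min(len(rest), max(0, n_expr_target - int(is_ir.sum())))
    if need and rest:
        for i in rng.choice(len(rest), size=need, replace=False):
            is_expr[rest[i]] = True

    # expression values; planted IR genes sit well above the detection
    # margin so conservation tests measure set arithmetic, not borderline
    # junction depth
    expr = np.where(
        is_expr,
        np.exp(rng.normal(cfg.expr_mu_log, cfg.expr_sigma_log, n)),
        rng.uniform(0.05, 0.6, n),
    )
    expr[is_expr] = np.maximum(expr[is_expr], cfg.expr_floor)
    expr[is_ir] = np.maximum(expr[is_ir], cfg.ir_gene_expr_floor)

    # --- head-to-head pair planting ----------------------------------------
    # blocks (2b, 2b+1) are candidate pairs; plant exact HH<=1kb fractions
    ir_blocks = [b for b in range(n_blocks) if is_ir[2 * b] and is_ir[2 * b + 1]]
    other_blocks = [b for b in range(n_blocks) if b not in set(ir_blocks)]
    hh_ir = _exact_subset(ir_blocks, cfg.bidir_fraction_ir, rng)
    hh_other = _exact_subset(other_blocks, cfg.bidir_fraction_other, rng)
    hh_blocks = hh_ir | hh_other

    # --- per-gene gene-model construction ----------------------------------
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    hh_gap: dict[int, int] = {}
    for b in hh_blocks:
        strands[2 * b] = "-"
        strands[2 * b + 1] = "+"
        hh_gap[b] = int(rng.integers(200, 1000))
    # non-planted pairs keep gaps >= min_intergenic (2 kb), so planted HH
    # blocks are the only pairs within the 1 kb cutoff

    ann = GenomeAnnotation()
    chrom_seq_parts: list[str] = []
    cursor = 0
    phase_probs = {
        True: np.asarray(cfg.phase_probs_retained, float),
        False: np.asarray(cfg.phase_probs_non_retained, float),
    }
    phase_probs = {k: v / v.sum() for k, v in phase_probs.items()}

    for i, gid in enumerate(gene_ids):
        k = int(n_introns[i])
        tx_id = f"{gid}.t1"
        # retention flags with 3' positional bias
        retained_flags = np.zeros(k, dtype=bool)
        rhos = np.zeros(k)
        if is_ir[i] and k > 0:
            relpos = (np.arange(1, k + 1)) / k
            w = (1 - cfg.position_bias) + cfg.position_bias * 2 * relpos
            probs = np.clip(cfg.retained_intron_frac * w, 0, 1)
            retained_flags = rng.random(k) < probs
            if not retained_flags.any():
                retained_flags[int(rng.choice(k, p=w / w.sum()))] = True
            rhos[retained_flags] = cfg.rho_low + (1 - cfg.rho_low) * rng.beta(
                cfg.rho_beta_a, cfg.rho_beta_b, int(retained_flags.sum())
            )
            # anchor intron: one retained intron with moderate rho, so the
            # gene's IR state is detectable with near-certainty
            anchor = int(np.flatnonzero(retained_flags)[0])
            rhos[anchor] = min(rhos[anchor], 0.45)

        # coding exon core lengths, with planted intron phases
        core = np.maximum(
            cfg.exon_len_min,
            np.exp(
                rng.normal(np.log(cfg.exon_len_median), cfg.exon_len_sigma_log, k + 1)
            ).astype(int),
        )
        cum = 0
        phases = np.zeros(k, dtype=int)
        for j in range(k):
            p = int(rng.choice(3, p=phase_probs[bool(retained_flags[j])]))
            core[j] += (p - (cum + core[j])) % 3
            cum += core[j]
            phases[j] = p
        core[k] += (-(cum + core[k])) % 3  # CDS length multiple of 3

        # intron lengths per class
        ilens = np.zeros(k, dtype=int)
        for j in range(k):
            cls = cfg.retained if retained_flags[j] else cfg.non_retained
            ln = np.exp(
                rng.normal(
                    np.log(cfg.intron_len_median * cls.length_scale),
                    cfg.intron_len_sigma_log,
                )
            )
            ilens[j] = max(cfg.intron_len_min, int(ln))

        # 3' UTR, possibly split by a UTR intron
        utr_med = cfg.utr3_median_ir if is_ir[i] else cfg.utr3_median_other
        u3 = max(
            cfg.utr3_len_min,
            int(np.exp(rng.normal(np.log(utr_med), cfg.utr3_sigma_log))),
        )
        utr_ip = cfg.utr3_intron_prob_ir if is_ir[i] else cfg.utr3_intron_prob_other
        has_utr_intron = (
            cfg.mean_introns_per_gene > 0
            and bool(rng.random() < utr_ip)
            and u3 >= 2 * cfg.utr3_len_min
        )
        # local (transcript-oriented, unspliced) exon coordinates
        exon_lens = [int(cfg.utr5_len + core[0])] + [int(c) for c in core[1:]]
        utr_intron_len = 0
        if has_utr_intron:
            u3a = u3 // 2
            u3b = u3 - u3a
            exon_lens[-1] += u3a
            cls = cfg.retained if is_ir[i] else cfg.non_retained
            utr_intron_len = max(
                cfg.intron_len_min,
                int(
                    np.exp(
                        rng.normal(
                            np.log(cfg.intron_len_median * cls.length_scale),
                            cfg.intron_len_sigma_log,
                        )
                    )
                ),
            )
            exon_lens.append(u3b)
            utr_retained = is_ir[i] and rng.random() < 0.5
        else:
            exon_lens[-1] += u3
            utr_retained = False

        all_intron_lens = list(ilens) + ([utr_intron_len] if has_utr_intron else [])
        n_all_introns = len(all_intron_lens)

        # local exon intervals
        local_exons = []
        pos = 0
        for e_idx, elen in enumerate(exon_lens):
            local_exons.append((pos, pos + elen))
            pos += elen
            if e_idx < n_all_introns:
                pos += all_intron_lens[e_idx]
        span = pos

        cds_start_local = cfg.utr5_len  # in exon 1
        cds_len = int(core.sum())
        # map spliced CDS interval to local genomic intervals
        cds_local = _spliced_to_local(local_exons, cds_start_local, cds_len)
        utr3_local = _spliced_to_local(
            local_exons,
            cds_start_local + cds_len,
            sum(exon_lens) - cfg.utr5_len - cds_len,
        )

        # --- sequence -------------------------------------------------------
        local_seq = None
        if cfg.emit_sequence:
            seq = np.empty(span, dtype="<U1")
            # exons
            for s, e in local_exons:
                seq[s:e] = DNA[_rand_seq(e - s, cfg.exon_gc, rng)]
            # introns + splice sites
            intron_meta = []
            for j in range(n_all_introns):
                gs = local_exons[j][1]
                ge = local_exons[j + 1][0]
                if j < k:
                    retained_j = bool(retained_flags[j])
                else:
                    retained_j = utr_retained
                cls = cfg.retained if retained_j else cfg.non_retained
                seq[gs:ge] = DNA[_rand_seq(ge - gs, cls.gc_mean, rng)]
                dwin = _sample_site(_strength_pwm(DONOR_PWM, cls.site_strength), rng)
                awin = _sample_site(_strength_pwm(ACCEPTOR_PWM, cls.site_strength), rng)
                seq[gs - 3 : gs + 6] = list(dwin)
                seq[ge - 20 : ge + 3] = list(awin)
                intron_meta.append((gs, ge, retained_j))
            local_seq = "".join(seq)
            # scrub accidental seed matches outside splice windows, then plant
            forbidden = set()
            for gs, ge, _ in intron_meta:
                forbidden.update(range(gs - 3, gs + 6))
                forbidden.update(range(ge - 20, ge + 3))
            local_seq = _scrub_words(local_seq, set(seed_words.values()), forbidden, rng)

            # plant UTR seed sites (in spliced-UTR exonic sequence)
            utr_rate = cfg.seed_rate_ir if is_ir[i] else cfg.seed_rate_other
            utr_sites, local_seq = _plant_sites_in_intervals(
                local_seq, utr3_local, utr_rate, seed_words, forbidden, rng
            )
            truth.utr_seed_sites[gid] = [
                (mid, _local_to_spliced(local_exons, p) - cds_start_local - cds_len)
                for mid, p in utr_sites
            ]
            # plant intron seed sites
            for j, (gs, ge, retained_j) in enumerate(intron_meta):
                rate = (
                    cfg.intron_seed_rate_retained
                    if retained_j
                    else cfg.intron_seed_rate_other
                )
                body = [(gs + 8, ge - 22)]
                if body[0][1] - body[0][0] > 20:
                    sites, local_seq = _plant_sites_in_intervals(
                        local_seq, body, rate, seed_words, forbidden, rng,
                        norm_length=ge - gs,
                    )
                else:
                    sites = []
                intron_index = j + 1
                truth.intron_seed_sites[f"{tx_id}.i{intron_index}"] = sites

        # --- map to genome ----------------------------------------------------
        strand = strands[i]
        block = i // 2
        if i % 2 == 0:
            gap = cfg.min_intergenic + int(rng.exponential(2000))
        else:
            gap = hh_gap.get(block, cfg.min_intergenic + int(rng.exponential(2000)))
        offset = cursor + gap

        def to_genomic(iv):
            s, e = iv
            if strand == "+":
                return (offset + s, offset + e)
            return (offset + span - e, offset + span - s)

        g_exons = sorted(to_genomic(iv) for iv in local_exons)
        g_cds = sorted(to_genomic(iv) for iv in cds_local)
        g_utr3 = sorted(to_genomic(iv) for iv in utr3_local)
        tx = TranscriptModel(id=tx_id, exons=g_exons, cds=g_cds, utr3=g_utr3)
        gene = GeneModel(id=gid, chrom=cfg.chrom, strand=strand)
        gene.transcripts[tx_id] = tx
        ann.genes[gid] = gene

        if cfg.emit_sequence:
            chrom_seq_parts.append("N" * gap)
            chrom_seq_parts.append(local_seq if strand == "+" else revcomp(local_seq))
        cursor = offset + span

        # --- truth bookkeeping ----------------------------------------------
        truth.expression[gid] = float(expr[i])
        truth.is_ir_gene[gid] = bool(is_ir[i])
        truth.is_expressed[gid] = bool(is_expr[i])
        truth.utr3_length[gid] = u3
        for j in range(n_all_introns):
            # local order is transcript orientation; matches derive_introns
            intron_id = f"{tx_id}.i{j + 1}"
            if j < k:
                truth.rho[intron_id] = float(rhos[j])
                truth.intron_phase[intron_id] = int(phases[j])
            else:
                truth.rho[intron_id] = (
                    float(
                        cfg.rho_low
                        + (1 - cfg.rho_low) * rng.beta(cfg.rho_beta_a, cfg.rho_beta_b)
                    )
                    if utr_retained
                    else 0.0
                )
                truth.utr3_intron_ids.add(intron_id)
        if block in hh_blocks and i % 2 == 1:
            truth.planted_hh_pairs.append((gene_ids[i - 1], gid, hh_gap[block]))

    ann.chrom_lengths[cfg.chrom] = cursor + 100
    genome = {
        cfg.chrom: ("".join(chrom_seq_parts) + "N" * 100) if cfg.emit_sequence else None
    }
    if cfg.emit_sequence and len(genome[cfg.chrom]) != ann.chrom_lengths[cfg.chrom]:
        raise AssertionError("genome length bookkeeping error")
    return ann, genome, truth


def _spliced_to_local(exons, spliced_start, length):
    """Map a spliced-coordinate interval to local (unspliced) intervals."""
    out = []
    seen = 0
    need_start = spliced_start
    need_end = spliced_start + length
    for s, e in exons:
        elen = e - s
        a = max(need_start, seen)
        b = min(need_end, seen + elen)
        if b > a:
            out.append((s + (a - seen), s + (b - seen)))
        seen += elen
    return out


def _local_to_spliced(exons, pos):
    seen = 0
    for s, e in exons:
        if s <= pos < e:
            return seen + (pos - s)
        seen += e - s
    return -1


def _scrub_words(seq: str, words: set, forbidden: set, rng) -> str:
    """Mutate one base inside every accidental occurrence of any word."""
    arr = list(seq)
    wlen = len(next(iter(words))) if words else 0
    changed = True
    guard = 0
    while changed and guard < 10:
        changed = False
        guard += 1
        s = "".join(arr)
        for w in sorted(words):
            start = 0
            while True:
                p = s.find(w, start)
                if p < 0:
                    break
                start = p + 1
                # mutate the first base of the word not inside a splice window
                target = next(
                    (q for q in range(p, p + wlen) if q not in forbidden), None
                )
                if target is None:
                    continue
                old = arr[target]
                choices = [b for b in "ACGT" if b != old]
                arr[target] = choices[int(rng.integers(0, 3))]
                changed = True
    return "".join(arr)


def _plant_sites_in_intervals(
    seq, intervals, rate_per_kb, seed_words, forbidden, rng, norm_length=None
):
    """Plant Poisson(rate * kb) collision-free seed sites inside intervals.

    ``norm_length`` sets the length (bp) the rate refers to when it differs
    from the plantable interval span (e.g. a whole intron including its
    splice windows).
    """
    arr = list(seq)
    total = sum(e - s for s, e in intervals)
    n_sites = rng.poisson(rate_per_kb * (norm_length or total) / 1000.0)
    mirna_ids = sorted(seed_words)
    planted = []
    occupied: set[int] = set(forbidden)
    positions = []
    for s, e in intervals:
        positions.extend(range(s, e - 7))
    if not positions:
        return [], seq
    tries = 0
    while len(planted) < n_sites and tries < n_sites * 20 + 20:
        tries += 1
        p = positions[int(rng.integers(0, len(positions)))]
        if any(q in occupied for q in range(p, p + 7)):
            continue
        mid = mirna_ids[int(rng.integers(0, len(mirna_ids)))]
        word = seed_words[mid]
        arr[p : p + 7] = list(word)
        occupied.update(range(p - 6, p + 13))  # avoid overlapping/adjacent creations
        planted.append((mid, p))
    # planting can create accidental words straddling a site's edges or a
    # spliced junction between intervals: scrub every occurrence in the
    # concatenated (spliced) sequence that is not a planted site, avoiding
    # planted footprints and splice windows
    footprints = set(forbidden)
    planted_at = {(seed_words[mid], p) for mid, p in planted}
    for _, p in planted:
        footprints.update(range(p, p + 7))
    words = sorted(set(seed_words.values()))
    posmap = [q for s_, e_ in intervals for q in range(s_, e_)]
    for _ in range(5):
        dirty = False
        concat = "".join(arr[q] for q in posmap)
        for w in words:
            start = 0
            while True:
                c = concat.find(w, start)
                if c < 0:
                    break
                start = c + 1
                g = posmap[c]
                contiguous = posmap[c + 6] == g + 6
                if contiguous and (w, g) in planted_at:
                    continue
                target = next(
                    (
                        posmap[c + j]
                        for j in range(7)
                        if posmap[c + j] not in footprints
                    ),
                    None,
                )
                if target is None:
                    continue
                old = arr[target]
                arr[target] = [b for b in "ACGT" if b != old][
                    int(rng.integers(0, 3))
                ]
                dirty = True
        if not dirty:
            break
    return planted, "".join(arr)


# ---------------------------------------------------------------------------
# Alignment-level evidence
# ---------------------------------------------------------------------------


def simulate_alignment_evidence(ann, truth: SimTruth, cfg: SimConfig, seed=None):
    """Poisson coverage + junction counts consistent with the planted truth."""
    rng = np.random.default_rng(cfg.rng_seed + 1 if seed is None else seed)
    length = ann.chrom_lengths[cfg.chrom]
    depth = np.zeros(length, dtype=np.int64)
    jx = JunctionCounts()
    for gid, gene in ann.genes.items():
        e = truth.expression[gid]
        c = cfg.coverage_per_fpkm * e
        tx = gene.representative_transcript()
        for s, eo in tx.exons:
            depth[s:eo] += rng.poisson(c, eo - s)
        from .annotation import derive_introns

        for intr in derive_introns(tx, gene.strand, gene.chrom, gid):
            rho = truth.rho.get(intr.id, 0.0)
            if rho > 0:
                depth[intr.start : intr.end] += rng.poisson(
                    c * rho, intr.end - intr.start
                )
            jn = rng.poisson(cfg.junction_per_fpkm * e * (1 - rho))
            if jn > 0:
                jx.add(gene.chrom, intr.start, intr.end, gene.strand, int(jn))
    cov = CoverageStore({cfg.chrom: depth})
    return cov, jx


def emit_sam(ann, truth: SimTruth, cfg: SimConfig, path, seed=None) -> int:
    """Write a SAM file whose reads realize the coverage/junction model.

    Unspliced reads tile exons and retained introns; spliced reads carry an
    N operation exactly matching intron boundaries. Returns read count.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2 if seed is None else seed)
    L = cfg.read_length
    chrom_len = ann.chrom_lengths[cfg.chrom]
    lines = []
    n_reads = 0

    def add_read(pos, cigar, seq_len):
        nonlocal n_reads
        n_reads += 1
        lines.append(
            f"r{n_reads}\t0\t{cfg.chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t"
            f"{'A' * seq_len}\t*"
        )

    from .annotation import derive_introns

    for gid, gene in ann.genes.items():
        e = truth.expression[gid]
        c = cfg.coverage_per_fpkm * e
        tx = gene.representative_transcript()
        regions = [(s, en, c) for s, en in tx.exons]
        introns = derive_introns(tx, gene.strand, gene.chrom, gid)
        for intr in introns:
            rho = truth.rho.get(intr.id, 0.0)
            if rho > 0:
                regions.append((intr.start, intr.end, c * rho))
        for s, en, cc in regions:
            span = en - s
            n = rng.poisson(cc * span / L)
            for _ in range(n):
                p = int(rng.integers(s, max(s + 1, en - L)))
                rl = min(L, chrom_len - p)
                add_read(p, f"{rl}M", rl)
        for intr in introns:
            rho = truth.rho.get(intr.id, 0.0)
            jn = rng.poisson(cfg.junction_per_fpkm * e * (1 - rho))
            ilen = intr.end - intr.start
            for _ in range(jn):
                a = int(rng.integers(10, L - 10))
                b = L - a
                add_read(intr.start - a, f"{a}M{ilen}N{b}M", L)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{chrom_len}\n")
        fh.write("\n".join(lines) + "\n")
    return n_reads


# ---------------------------------------------------------------------------
# Species panel
# ---------------------------------------------------------------------------


@dataclass
class SpeciesSim:
    name: str
    annotation: GenomeAnnotation
    genome: dict
    truth: SimTruth
    coverage: CoverageStore
    junctions: JunctionCounts
    config: SimConfig


def simulate_species_panel(
    cfgs: list[SimConfig],
    ortholog_overlap: float = 1.0,
    n_conserved_core: int = 86,
    species_names=None,
):
    """Generate a multi-species panel with a planted conserved-IR core.

    The first round(overlap * n) gene indices of each species form shared
    ortholog groups; the first ``n_conserved_core`` of those are forced IR
    in every species, and every other shared group is forced non-IR in at
    least one species, so the all-species intersection of IR orthologs
    equals the planted core by construction.

    Returns (list of SpeciesSim, ortholog table rows (group_id, species,
    gene_id), planted core group ids).
    """
    if len(cfgs) < 2:
        raise ConfigError("panel needs >= 2 species configs")
    n_species = len(cfgs)
    if species_names is None:
        species_names = [f"sp{i + 1}" for i in range(n_species)]
    n = min(c.n_genes for c in cfgs)
    n_shared = int(round(ortholog_overlap * n))
    n_core = min(n_conserved_core, n_shared)
    master = np.random.default_rng(cfgs[0].rng_seed + 777)

    # class plan per species: draw, then force core all-IR and break
    # accidental all-IR non-core rows
    plan = np.zeros((n, n_species), dtype=bool)
    for s, cfg in enumerate(cfgs):
        frac = cfg.ir_gene_fraction * cfg.expressed_fraction
        plan[:, s] = master.random(n) < frac
    core_rows = np.arange(n_core)
    plan[core_rows, :] = True
    for g in range(n_core, n_shared):
        if plan[g].all():
            plan[g, int(master.integers(0, n_species))] = False
    # private genes (beyond n_shared) keep their drawn class

    sims = []
    ortho_rows = []
    core_groups = [f"OG{g + 1:05d}" for g in range(n_core)]
    for s, cfg in enumerate(cfgs):
        cfg_s = replace(
            cfg,
            gene_prefix=f"{species_names[s]}_G",
            chrom=f"{species_names[s]}_chr1",
            ir_class_override={g: bool(plan[g, s]) for g in range(n)},
            rng_seed=cfg.rng_seed + 1000 * (s + 1),
        )
        ann, genome, truth = generate_annotation_and_genome(cfg_s)
        cov, jx = simulate_alignment_evidence(ann, truth, cfg_s)
        sims.append(
            SpeciesSim(species_names[s], ann, genome, truth, cov, jx, cfg_s)
        )
        gene_ids = sorted(ann.genes)
        for g in range(n):
            if g < n_shared:
                group = f"OG{g + 1:05d}"
            else:
                group = f"OG_{species_names[s]}_{g + 1:05d}"
            ortho_rows.append((group, species_names[s], gene_ids[g]))
    return sims, ortho_rows, core_groups


# ---------------------------------------------------------------------------
# FASTA / truth output helpers
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            seq = genome[chrom]
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_json(truth: SimTruth, path) -> None:
    import json

    doc = {
        "rho": truth.rho,
        "expression": truth.expression,
        "is_ir_gene": truth.is_ir_gene,
        "is_expressed": truth.is_expressed,
        "utr_seed_sites": truth.utr_seed_sites,
        "intron_seed_sites": truth.intron_seed_sites,
        "utr3_intron_ids": sorted(truth.utr3_intron_ids),
        "utr3_length": truth.utr3_length,
        "planted_hh_pairs": truth.planted_hh_pairs,
        "mirnas": truth.mirnas,
        "intron_phase": truth.intron_phase,
    }
    def conv(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        raise TypeError(f"not JSON serializable: {type(x)}")

    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=conv)


def estimate_fpkm_from_coverage(ann, cov: CoverageStore, coverage_per_fpkm: float):
    """Invert the coverage model: FPKM estimate = mean exonic depth / c."""
    from .annotation import merge_intervals

    out = {}
    for gid, gene in ann.genes.items():
        merged = merge_intervals(
            [iv for t in gene.transcripts.values() for iv in t.exons]
        )
        total = sum(int(cov.get(gene.chrom, s, e).sum()) for s, e in merged)
        nbases = sum(e - s for s, e in merged)
        out[gid] = (total / nbases) / coverage_per_fpkm if nbases else 0.0
    return out
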