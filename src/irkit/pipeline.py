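"""Configuration-driven orchestration of the full analysis over synthetic
or user-supplied inputs.

Stages run in dependency order (simulate -> quantify -> features / maxent
/ mirna / architecture -> conserve -> sponge); every output table carries
the config hash and seed, and a rerun with the same config is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import architecture, conservation, features, maxent, mirna, quantify
from . import simulate as sim
from . import sponge

logger = logging.getLogger("irkit.pipeline")


@dataclass
class PipelineConfig:
    # input paths (None -> synthetic demo)
    gtf: str | None = None
    fasta: str | None = None
    coverage_tsv: str | None = None
    junctions_tsv: str | None = None
    alignments: str | None = None
    orthologs_tsv: str | None = None
    mirnas_fasta: str | None = None
    # thresholds (per the IR-calling definition)
    ir_ratio_min: float = quantify.IR_RATIO_MIN
    splice_depth_min: int = quantify.SPLICE_DEPTH_MIN
    coverage_min: float = quantify.COVERAGE_SUM_MIN
    fpkm_expressed: float = quantify.FPKM_EXPRESSED
    # synthetic demo shape
    n_genes: int = 200
    n_species: int = 5
    n_conserved_core: int = 86
    kmeans_k: int = 8
    seed: int = 0
    out_dir: str = "results"
    run_stages: tuple = (
        "simulate",
        "quantify",
        "features",
        "maxent",
        "mirna",
        "architecture",
        "conserve",
        "sponge",
    )

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(doc.encode()).hexdigest()[:12]


def validate_config(config) -> list[str]:
    """Return a list of violations (empty = ok). Accepts a PipelineConfig
    or a dict (unknown keys are violations)."""
    violations: list[str] = []
    if isinstance(config, dict):
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(config) - known
        violations += [f"unknown key: {k}" for k in sorted(unknown)]
        try:
            config = PipelineConfig(**{k: v for k, v in config.items() if k in known})
        except (TypeError, ValueError) as exc:
            return violations + [str(exc)]
    for name in ("ir_ratio_min", "coverage_min", "fpkm_expressed"):
        if getattr(config, name) <= 0:
            violations.append(f"{name} must be positive")
    if config.splice_depth_min < 1:
        violations.append("splice_depth_min must be >= 1")
    if config.n_genes < 2:
        violations.append("n_genes must be >= 2")
    if config.n_species < 2:
        violations.append("n_species must be >= 2")
    for name in ("gtf", "fasta", "orthologs_tsv", "mirnas_fasta"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            violations.append(f"{name}: no such file: {path}")
    return violations


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the aggregated report dict.

    Outputs land under ``config.out_dir``; the report is also written as
    JSON. A stage failure halts the run, keeping earlier outputs.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s",
    )
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in config.run_stages:
        t0 = time.time()
        logger.info("stage %s: start", stage)
        try:
            _STAGES[stage](config, state, report, out)
        except Exception as exc:  # halt with stage name, keep partials
            _write_report(report, out, config)
            raise StageFailure(stage, exc) from exc
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
    _write_report(report, out, config)
    return report


def _write_report(report, out: Path, config: PipelineConfig) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, frozenset):
        return "+".join(sorted(x))
    return str(x)


def _stamp(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash()
    df["seed"] = config.seed
    return df


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config, state, report, out):
    base = sim.SimConfig(n_genes=config.n_genes, rng_seed=config.seed)
    cfgs = [replace(base, rng_seed=config.seed + s) for s in range(config.n_species)]
    sims, ortho_rows, core = sim.simulate_species_panel(
        cfgs, ortholog_overlap=1.0, n_conserved_core=config.n_conserved_core
    )
    state["sims"] = sims
    state["ortho_rows"] = ortho_rows
    state["core_groups"] = core
    # a dedicated species with the natural planted IR fraction for the
    # per-species feature analyses (the panel's forced conserved core
    # inflates its species' IR fractions)
    study_cfg = replace(
        base, gene_prefix="study_G", chrom="study_chr1",
        rng_seed=config.seed + 991,
    )
    ann_s, genome_s, truth_s = sim.generate_annotation_and_genome(study_cfg)
    cov_s, jx_s = sim.simulate_alignment_evidence(ann_s, truth_s, study_cfg)
    state["sims"] = [
        sim.SpeciesSim("study", ann_s, genome_s, truth_s, cov_s, jx_s,
                       study_cfg)
    ] + sims
    for s in (state["sims"][0], sims[0]):
        ann_mod.write_gtf(s.annotation, out / f"{s.name}.gtf")
        if s.genome[s.config.chrom] is not None:
            sim.write_fasta(s.genome, out / f"{s.name}.fa")
        sim.write_truth_json(s.truth, out / f"{s.name}.truth.json")
    pd.DataFrame(ortho_rows, columns=["group_id", "species", "gene_id"]).to_csv(
        out / "orthologs.tsv", sep="\t", index=False
    )
    report["simulate"] = {
        "n_species": len(sims),
        "n_genes": config.n_genes,
        "planted_core": len(core),
    }


def _stage_quantify(config, state, report, out):
    per_species = {}
    fractions = {}
    for s in state["sims"]:
        fpkm = sim.estimate_fpkm_from_coverage(
            s.annotation, s.coverage, s.config.coverage_per_fpkm
        )
        calls, gene_irs = quantify.quantify_annotation(
            s.annotation, s.coverage, s.junctions, fpkm=fpkm
        )
        per_species[s.name] = {"calls": calls, "gene_irs": gene_irs}
        fractions[s.name] = quantify.ir_gene_fraction(gene_irs)
        introns = s.annotation.all_introns(representative_only=True)
        table = quantify.calls_to_table(calls, introns)
        _stamp(table, config).to_csv(
            out / f"{s.name}.ir_calls.tsv", sep="\t", index=False
        )
    state["quant"] = per_species
    sp0 = state["sims"][0]
    profile = quantify.gene_body_coverage(
        sp0.coverage, sp0.annotation,
        gene_ids={g for g, gi in per_species[sp0.name]["gene_irs"].items()
                  if gi.is_expressed},
    )
    report["quantify"] = {
        "ir_gene_fraction": fractions,
        "gene_body_coverage_range": [float(profile.min()), float(profile.max())],
    }


def _retained_ids(state, species_name) -> set:
    gene_irs = state["quant"][species_name]["gene_irs"]
    return {i for g in gene_irs.values() for i in g.retained_intron_ids}


def _stage_features(config, state, report, out):
    s = state["sims"][0]
    retained = _retained_ids(state, s.name)
    introns = s.annotation.all_introns(representative_only=True)
    chrom_seqs = {c: seq for c, seq in s.genome.items() if seq}
    rows = features.feature_table(introns, chrom_seqs, retained)
    df = pd.DataFrame([r.__dict__ for r in rows])
    _stamp(df, config).to_csv(out / f"{s.name}.intron_features.tsv", sep="\t",
                              index=False)
    ret = df[df.is_retained]
    oth = df[~df.is_retained]
    report["features"] = {
        "length": features.compare_feature(ret.length, oth.length),
        "gc": features.compare_feature(ret.gc, oth.gc),
        "position_shift": features.position_shift_test(
            ret.rel_position, oth.rel_position
        ),
    }
    state["feature_df"] = df


def _stage_maxent(config, state, report, out):
    s = state["sims"][0]
    retained = _retained_ids(state, s.name)
    introns = s.annotation.all_introns(representative_only=True)
    chrom_seqs = {c: seq for c, seq in s.genome.items() if seq}
    seq = chrom_seqs[s.config.chrom]
    donors, acceptors = [], []
    for intr in introns:
        if intr.id in retained:
            continue
        d = maxent.donor_window(seq, intr)
        a = maxent.acceptor_window(seq, intr)
        if len(d) == maxent.DONOR_WIDTH and "N" not in d:
            donors.append(d)
        if len(a) == maxent.ACCEPTOR_WIDTH and "N" not in a:
            acceptors.append(a)
    dm = maxent.train(donors, kind="donor")
    am = maxent.train(acceptors, kind="acceptor")
    dm.to_json(out / "donor_model.json")
    am.to_json(out / "acceptor_model.json")
    ps = maxent.pair_scores(introns, retained, chrom_seqs, dm, am)
    report["maxent"] = {
        "donor_sites_trained": dm.trained_on,
        "acceptor_sites_trained": am.trained_on,
        "donor_mean_shift": ps.get("donor_mean_shift"),
        "acceptor_mean_shift": ps.get("acceptor_mean_shift"),
        "donor_p_lower": ps.get("donor_p_lower"),
        "acceptor_p_lower": ps.get("acceptor_p_lower"),
    }
    state["maxent_models"] = (dm, am)


def _stage_mirna(config, state, report, out):
    s = state["sims"][0]
    gene_irs = state["quant"][s.name]["gene_irs"]
    seq = s.genome[s.config.chrom]
    utr_len = mirna.utr3_length_per_gene(s.annotation)
    counts_ir, counts_other = [], []
    fg, bg = [], []
    for gid, gene in s.annotation.genes.items():
        tx = gene.representative_transcript()
        if not tx.utr3:
            continue
        useq = mirna.spliced_utr3_seq(tx, gene.strand, seq)
        n_sites = len(mirna.scan_seed_sites(useq, s.truth.mirnas, gid))
        bg.append(useq)
        if gene_irs[gid].is_ir_gene:
            counts_ir.append(n_sites)
            fg.append(useq)
        else:
            counts_other.append(n_sites)
    comp = mirna.site_count_comparison(counts_ir, counts_other)
    enr = mirna.word_enrichment(fg, bg)
    pd.DataFrame([e.__dict__ for e in enr[:200]]).to_csv(
        out / f"{s.name}.word_enrichment.tsv", sep="\t", index=False
    )
    lens_ir = [utr_len[g] for g, gi in gene_irs.items()
               if gi.is_ir_gene and utr_len.get(g)]
    lens_other = [utr_len[g] for g, gi in gene_irs.items()
                  if not gi.is_ir_gene and utr_len.get(g)]
    report["mirna"] = {
        "utr_length": features.compare_feature(lens_ir, lens_other,
                                               test="wilcoxon"),
        "site_counts": comp,
        "n_significant_words": len(mirna.significant_words(enr)),
    }


def _stage_architecture(config, state, report, out):
    s = state["sims"][0]
    gene_irs = state["quant"][s.name]["gene_irs"]
    pairs = architecture.classify_adjacent_pairs(s.annotation)
    ir_genes = {g for g, gi in gene_irs.items() if gi.is_ir_gene}
    enrich = architecture.bidirectional_enrichment(pairs, ir_genes)
    hist = architecture.retained_count_histogram(gene_irs)
    n_ret = sum(gi.n_retained for gi in gene_irs.values())
    kbp = ann_mod.merged_exonic_kbp(s.annotation.genes.values())
    pd.DataFrame([p.__dict__ for p in pairs]).to_csv(
        out / f"{s.name}.gene_pairs.tsv", sep="\t", index=False
    )
    report["architecture"] = {
        "bidirectional_fraction_ir": architecture.bidirectional_fraction(
            pairs, subset=ir_genes
        ),
        "bidirectional_fraction_all": architecture.bidirectional_fraction(pairs),
        "fisher_p": enrich["p_value"],
        "retained_count_histogram": {str(k): v for k, v in hist.items()},
        "retained_density_per_kbp": architecture.retained_density(n_ret, kbp),
    }


def _stage_conserve(config, state, report, out):
    panel_species = {sp for _, sp, _ in state["ortho_rows"]}
    gene_irs_by_species = {
        name: d["gene_irs"]
        for name, d in state["quant"].items()
        if name in panel_species
    }
    mat = conservation.build_profile_matrix(
        gene_irs_by_species, state["ortho_rows"]
    )
    norm = conservation.quantile_normalize(mat)
    labels = conservation.kmeans_rows(norm, k=config.kmeans_k, seed=config.seed)
    _, newick, _ = conservation.hcluster_species(norm)
    ir_sets = {
        name: {g for g, gi in d["gene_irs"].items() if gi.is_ir_gene}
        for name, d in state["quant"].items()
        if name in panel_species
    }
    venn = conservation.venn_counts(ir_sets, state["ortho_rows"])
    norm.to_csv(out / "ir_profile_matrix.tsv", sep="\t")
    with open(out / "species_dendrogram.nwk", "w") as fh:
        fh.write(newick + "\n")
    with open(out / "venn_counts.json", "w") as fh:
        json.dump(
            {"+".join(sorted(k)): v for k, v in venn["regions"].items()},
            fh, indent=1,
        )
    r = conservation.correlate_ir_complexity(
        conservation.published_species_summaries()
    )
    report["conserve"] = {
        "n_ortholog_rows": int(mat.shape[0]),
        "all_species_ir_core": venn["all"],
        "planted_core": len(state.get("core_groups", [])),
        "kmeans_clusters": int(labels.nunique()),
        "newick": newick,
        "published_ir_complexity_pearson_r": r,
    }


def _stage_sponge(config, state, report, out):
    params = sponge.SpongeParams()
    grid = np.linspace(0, 50, 11)
    dr = sponge.sponge_dose_response(params, grid)
    pd.DataFrame({"k_S": dr["k_S"], "free_target": dr["free_target"]}).to_csv(
        out / "sponge_dose_response.tsv", sep="\t", index=False
    )
    report["sponge"] = {
        "derepression_ratio": dr["derepression_ratio"],
        "monotone": bool(np.all(np.diff(dr["free_target"]) >= -1e-6)),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "features": _stage_features,
    "maxent": _stage_maxent,
    "mirna": _stage_mirna,
    "architecture": _stage_architecture,
    "conserve": _stage_conserve,
    "sponge": _stage_sponge,
}
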