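"""End-to-end orchestration: configuration, simulation bundles, the
signature pipeline (expression -> trends -> signatures -> network module)
and the regulome pipeline (peaks -> consensus -> targets -> core program).

Every run is deterministic given the config and inputs; the fully resolved
configuration and a per-stage report (counts + timings) are written next to
the outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import expression_qc, io, network_module, regulome, synthdata
from .errors import InputError, TrendsigError
from .genemodel import GeneModel
from .synthdata import SynthExpressionConfig, TruthTable, default_planted
from .trend_signatures import SignatureThresholds, derive_signatures

log = logging.getLogger("trendsig")


@dataclass
class PipelineConfig:
    """Paths plus the printed analysis constants.

    Defaults: significance alpha 0.05, sFC cutoffs 2/4, TSS window
    +/-3000 bp, replicate support >= 2, DEG FDR 0.05.
    """

    expression: str | None = None
    sample_sheet: str | None = None
    probe_map: str | None = None
    edges: str | None = None
    gtf: str | None = None
    peaks: list = field(default_factory=list)
    deg_a: str | None = None
    deg_b: str | None = None
    nanostring_counts: str | None = None
    nanostring_samples: str | None = None
    out_dir: str = "trendsig_out"

    alpha: float = 0.05
    sfc_lo: float = 2.0
    sfc_hi: float = 4.0
    min_score: float = 0.4
    tss_window: int = 3000
    min_support: int = 2
    fdr: float = 0.05
    quantile_normalize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def resolve_out(self) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _require(path, what: str) -> Path:
    if path is None:
        raise InputError(f"config is missing the {what} path")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{what} file not found: {p}")
    return p


class _StageTimer:
    def __init__(self):
        self.timings: dict[str, float] = {}

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            result = fn(*args, **kwargs)
        except TrendsigError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        dt = time.perf_counter() - t0
        self.timings[name] = round(dt, 4)
        log.info("stage %s: done in %.3fs", name, dt)
        return result


# ----------------------------------------------------------------- simulate


def simulate_bundle(out_dir, seed: int = 0,
                    expr_config: SynthExpressionConfig | None = None,
                    n_module_genes: int = 40, n_background_genes: int = 160,
                    p_within: float = 0.8, p_background: float = 0.01,
                    n_model_genes: int = 30, chrom_len: int = 1_000_000,
                    n_chip_targets: int = 12, reproducible_frac: float = 0.75,
                    n_noise_peaks: int = 20, n_core: int = 50,
                    n_line_specific: int = 40, n_null: int = 60,
                    n_pairs: int = 8, effect_log2fc: float = 2.0) -> dict:
    """Generate every pipeline input under ``out_dir`` with planted truth.

    Derived seeds (seed+1, seed+2, ...) keep the generators independent.
    Returns the path map; the combined truth table lands in ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if expr_config is None:
        expr_config = SynthExpressionConfig(
            planted=default_planted(), seed=seed)

    matrix, sheet, probe_map, truth_expr = \
        synthdata.gen_multistudy_expression(expr_config)
    io.write_expression(matrix, out / "expression.tsv")
    io.write_sample_sheet(sheet, out / "samples.tsv")
    io.write_probe_map(probe_map, out / "probe_map.tsv")

    planted_up = [g for g, v in truth_expr.signatures.items()
                  if v["direction"] == "up" and v["archetype"] in ("S2", "S3")]
    module_genes = sorted(planted_up)[:n_module_genes]
    background = [g for g in matrix.index.str.replace(r"_p\d+$", "", regex=True)
                  .unique() if g not in set(module_genes)][:n_background_genes]
    edges = synthdata.gen_interaction_network(
        module_genes, background, p_within, p_background, seed=seed + 1)
    io.write_edge_list(edges, out / "edges.tsv")

    model = synthdata.gen_gene_model(n_model_genes, n_chroms=2,
                                     chrom_len=chrom_len, seed=seed + 2)
    model.to_gtf(out / "genes.gtf")
    targets = model.gene_ids[:n_chip_targets]
    reps, truth_chip = synthdata.gen_chip_replicates(
        model, targets, reproducible_frac=reproducible_frac,
        n_noise_peaks=n_noise_peaks, seed=seed + 3)
    peak_paths = []
    for i, rep in enumerate(reps):
        p = out / f"peaks_rep{i + 1}.narrowPeak"
        io.write_peaks(rep, p)
        peak_paths.append(str(p))

    # DEG core = reproducible ChIP targets plus extra shared DEGs without a
    # peak, so the triple intersection recovers exactly the planted targets
    gene_pool = [f"T{i + 1:04d}" for i in range(n_core + 2 * n_line_specific
                                                + n_null)]
    core = list(truth_chip.peak_targets) + gene_pool[:n_core]
    line_a = gene_pool[n_core:n_core + n_line_specific]
    line_b = gene_pool[n_core + n_line_specific:n_core + 2 * n_line_specific]
    nulls = gene_pool[n_core + 2 * n_line_specific:]
    deg_a, deg_b, truth_deg = synthdata.gen_deg_tables(
        core, line_a, line_b, nulls, seed=seed + 4)
    io.write_deg_table(deg_a, out / "deg_lineA.tsv")
    io.write_deg_table(deg_b, out / "deg_lineB.tsv")

    panel = sorted(planted_up)[:38] or [f"PNL{i}" for i in range(38)]
    mat, classes, meta, truth_ns = synthdata.gen_nanostring_counts(
        panel, n_pairs=n_pairs, effect_log2fc=effect_log2fc, seed=seed + 5)
    io.write_nanostring(mat, classes, meta, out / "nanostring_counts.csv",
                        out / "nanostring_samples.csv")

    truth = TruthTable(
        signatures=truth_expr.signatures, discordant=truth_expr.discordant,
        module_genes=list(module_genes),
        peak_targets=truth_chip.peak_targets,
        nonreproducible_targets=truth_chip.nonreproducible_targets,
        core_genes=truth_deg.core_genes, line_a_genes=truth_deg.line_a_genes,
        line_b_genes=truth_deg.line_b_genes, null_genes=truth_deg.null_genes,
        scale_factors=truth_ns.scale_factors,
        effect_log2fc=truth_ns.effect_log2fc)
    io.write_json(truth.to_dict(), out / "truth.json")

    return {
        "expression": str(out / "expression.tsv"),
        "sample_sheet": str(out / "samples.tsv"),
        "probe_map": str(out / "probe_map.tsv"),
        "edges": str(out / "edges.tsv"),
        "gtf": str(out / "genes.gtf"),
        "peaks": peak_paths,
        "deg_a": str(out / "deg_lineA.tsv"),
        "deg_b": str(out / "deg_lineB.tsv"),
        "nanostring_counts": str(out / "nanostring_counts.csv"),
        "nanostring_samples": str(out / "nanostring_samples.csv"),
        "truth": str(out / "truth.json"),
    }


# --------------------------------------------------------------- pipelines


def run_signature_pipeline(config: PipelineConfig) -> dict:
    """Expression -> QC -> trends -> signatures -> network module.

    Writes trend/signature/module TSVs, a JSON report of per-stage counts
    and the resolved config; returns the report dict.
    """
    out = config.resolve_out()
    timer = _StageTimer()

    m = io.read_expression(_require(config.expression, "expression matrix"))
    sheet = io.read_sample_sheet(_require(config.sample_sheet, "sample sheet"))
    probe_map = io.read_probe_map(_require(config.probe_map, "probe map"))

    if config.quantile_normalize:
        m = timer.run("quantile_normalize", expression_qc.quantile_normalize, m)

    thr = SignatureThresholds(lo=config.sfc_lo, hi=config.sfc_hi)
    res = timer.run("derive_signatures", derive_signatures, m, sheet,
                    probe_map, config.alpha, thr)
    trend = res["trend_table"]
    sig = res["signatures"]

    for name, cmp_res in res["comparisons"].items():
        cmp_res.to_csv(out / f"comparison_{name}.tsv", sep="\t")
    trend.to_csv(out / "trend_table.tsv", sep="\t")
    sig.to_csv(out / "signatures.tsv", sep="\t")

    report = {
        "n_probes": int(m.shape[0]), "n_samples": int(m.shape[1]),
        "n_trend_up": int((trend["label"] == "TrendUp").sum()),
        "n_trend_down": int((trend["label"] == "TrendDown").sum()),
        "n_excluded_discordant":
            int((trend["label"] == "excluded_discordant").sum()),
        "signature_sizes": {
            f"{d}_{s}": int(((sig["direction"] == d)
                             & (sig["signature"] == s)).sum())
            for d in ("up", "down") for s in ("S1", "S2", "S3")},
    }

    if config.edges is not None:
        edges = io.read_edge_list(_require(config.edges, "edge list"))
        focus = sig[(sig["direction"] == "up")
                    & (sig["signature"].isin(["S2", "S3"]))].index
        sub, unmapped = timer.run(
            "map_to_network", network_module.map_to_network,
            list(focus), edges, config.min_score)
        module = timer.run("largest_connected_component",
                           network_module.largest_connected_component, sub)
        pd.DataFrame({"gene_id": list(module.members)}).to_csv(
            out / "module.tsv", sep="\t", index=False)
        mapped = sub.number_of_nodes()
        report.update({
            "n_signature_genes_for_module": int(len(focus)),
            "n_mapped": int(mapped), "n_unmapped": len(unmapped),
            "module_size": module.size,
            "module_fraction_pct":
                network_module.module_fraction(module, mapped) if mapped else None,
        })

    report["timings_s"] = timer.timings
    io.write_json(report, out / "signature_report.json")
    config.to_yaml(out / "resolved_config.yaml")
    return report


def run_core_pipeline(config: PipelineConfig) -> dict:
    """Replicate peaks -> consensus -> TSS targets -> DEG sets -> core program."""
    out = config.resolve_out()
    timer = _StageTimer()

    reps = [io.read_peaks(_require(p, "peak set")) for p in config.peaks]
    model = GeneModel.from_gtf(_require(config.gtf, "gene model GTF"))
    cons = timer.run("consensus_peaks", regulome.consensus_peaks, reps,
                     config.min_support)
    io.write_peaks(cons.rename(columns={"n_replicates": "score"}),
                   out / "consensus.bed")
    annotation, chip_targets = timer.run(
        "assign_peaks_to_genes", regulome.assign_peaks_to_genes,
        cons, model, config.tss_window)
    annotation.to_csv(out / "peak_annotation.tsv", sep="\t", index=False)
    dist = timer.run("genomic_distribution", regulome.genomic_distribution,
                     cons, model, config.tss_window)
    dist.to_csv(out / "genomic_distribution.tsv", sep="\t",
                index_label="category")

    deg_a = regulome.threshold_deg(
        io.read_deg_table(_require(config.deg_a, "DEG table A")), config.fdr)
    deg_b = regulome.threshold_deg(
        io.read_deg_table(_require(config.deg_b, "DEG table B")), config.fdr)
    prog = timer.run("core_program", regulome.core_program,
                     deg_a, deg_b, chip_targets)
    pd.DataFrame({"gene_id": sorted(prog.core)}).to_csv(
        out / "core_program.tsv", sep="\t", index=False)
    io.write_json(prog.venn, out / "venn_counts.json")

    report = {
        "n_consensus_peaks": int(len(cons)),
        "n_chip_targets": len(chip_targets),
        "n_deg_a": len(deg_a), "n_deg_b": len(deg_b),
        "core_size": len(prog.core),
        "venn": prog.venn,
        "genomic_distribution": {k: round(v, 6) for k, v in dist.items()},
        "timings_s": timer.timings,
    }
    io.write_json(report, out / "core_report.json")
    config.to_yaml(out / "resolved_config_core.yaml")
    return report


# -------------------------------------------------------------- evaluation


def evaluate_recovery(trend_table: pd.DataFrame, signatures: pd.DataFrame,
                      truth: TruthTable) -> dict:
    """Score a signature run against the planted truth.

    Reports, over planted genes recovered in the monotone trend lists:
    direction accuracy (trend label vs planted direction) and archetype
    accuracy (assigned signature vs planted archetype), plus overall recall
    and the discordant-exclusion rate.
    """
    planted = truth.signatures
    trend_genes = trend_table[trend_table["label"].isin(
        ["TrendUp", "TrendDown"])]
    recovered = [g for g in trend_genes.index if g in planted]
    # genes that truly carry a monotone trend: both steps shifted, and not
    # given a deliberately discordant probe (the exclusion rule must fire
    # for those instead)
    monotone = [g for g, v in planted.items()
                if v["effect_step1"] != 0 and v["effect_step2"] != 0
                and g not in set(truth.discordant)]
    n_monotone_found = sum(
        1 for g in monotone
        if g in trend_genes.index
        and (trend_genes.at[g, "label"] == "TrendUp")
        == (planted[g]["direction"] == "up"))
    n_dir_ok = sum(
        1 for g in recovered
        if (trend_genes.at[g, "label"] == "TrendUp") ==
           (planted[g]["direction"] == "up"))
    n_arch_ok = sum(
        1 for g in recovered
        if g in signatures.index
        and signatures.at[g, "signature"] == planted[g]["archetype"])
    discordant = set(truth.discordant)
    n_disc_ok = sum(
        1 for g in discordant
        if g in trend_table.index
        and trend_table.at[g, "label"] == "excluded_discordant")
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "n_monotone": len(monotone),
        "n_monotone_found": n_monotone_found,
        "trend_sensitivity":
            n_monotone_found / len(monotone) if monotone else float("nan"),
        "recall": len(recovered) / len(planted) if planted else float("nan"),
        "direction_accuracy":
            n_dir_ok / len(recovered) if recovered else float("nan"),
        "archetype_accuracy":
            n_arch_ok / len(recovered) if recovered else float("nan"),
        "discordant_exclusion_rate":
            n_disc_ok / len(discordant) if discordant else float("nan"),
    }
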