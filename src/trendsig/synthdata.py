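"""Synthetic data generators with planted ground truth.

Every pipeline input — the multi-study expression matrix, the interaction
network, the gene model, replicate ChIP peak sets, knockdown DEG tables and
Nanostring-style count tables — can be generated here with a known truth
table, so each downstream stage is testable end to end without external data.

The expression generator emulates a meta-cohort of microarray profiles from
several studies: log2 intensities with Gaussian within-class noise, an
additive per-study batch offset, multi-probe genes, and planted monotone
effects along the normal -> differentiated (DTC) -> anaplastic (ATC) axis.
Planted genes follow three archetypes: deregulated mainly in the first step
(S1), mainly in the second step (S2), or in both (S3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import make_rng
from .errors import ValidationError
from .genemodel import GeneModel

ARCHETYPES = ("S1", "S2", "S3")
DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    direction: str           # 'up' | 'down'
    archetype: str           # 'S1' | 'S2' | 'S3'
    effect_step1: float      # log2 shift NORM -> DTC
    effect_step2: float      # log2 shift DTC -> ATC


@dataclass
class SynthExpressionConfig:
    """Study conditions for the multi-study expression generator.

    Defaults mirror the meta-cohort the pipeline emulates: 127 normal,
    102 differentiated and 50 anaplastic profiles pooled from 8 studies.
    Effects are in log2 units; S1 archetypes shift only in the first step,
    S2 only in the second, S3 in both.
    """

    n_norm: int = 127
    n_dtc: int = 102
    n_atc: int = 50
    n_studies: int = 8
    n_genes: int = 2000
    planted: list = field(default_factory=list)
    within_sd: float = 0.5
    batch_sd: float = 0.3
    probe_multiplicity: dict = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    discordant_frac: float = 0.1
    baseline_range: tuple = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_norm, self.n_dtc, self.n_atc,
               self.n_studies, self.n_genes) <= 0:
            raise ValidationError("all counts must be positive")
        if self.within_sd < 0 or self.batch_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not 0 <= self.discordant_frac <= 1:
            raise ValidationError("discordant_frac must lie in [0, 1]")
        ids = [p.gene_id for p in self.planted]
        if len(ids) != len(set(ids)):
            raise ValidationError("planted gene ids must be unique")
        if abs(sum(self.probe_multiplicity.values()) - 1) > 1e-9:
            raise ValidationError("probe_multiplicity must sum to 1")


def default_planted(n_per_cell: int = 20,
                    effects: dict | None = None,
                    n_genes: int = 2000) -> list[PlantedGene]:
    """Planted genes for the benchmark conditions: ``n_per_cell`` genes per
    archetype per direction with step effects S1:(2,0), S2:(0,2), S3:(1.5,1.5)
    log2 units, taken from the head of the gene namespace."""
    if effects is None:
        effects = {"S1": (2.0, 0.0), "S2": (0.0, 2.0), "S3": (1.5, 1.5)}
    planted, i = [], 0
    for direction in DIRECTIONS:
        for arch in ARCHETYPES:
            e1, e2 = effects[arch]
            for _ in range(n_per_cell):
                i += 1
                if i > n_genes:
                    raise ValidationError("more planted genes than genes")
                planted.append(PlantedGene(_gene_name(i), direction, arch, e1, e2))
    return planted


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


@dataclass
class TruthTable:
    """Ground truth emitted alongside each generated dataset."""

    signatures: dict = field(default_factory=dict)   # gene -> {direction, archetype, effects}
    discordant: list = field(default_factory=list)   # genes given one flipped probe
    module_genes: list = field(default_factory=list)
    peak_targets: list = field(default_factory=list)  # replicate-reproducible targets
    nonreproducible_targets: list = field(default_factory=list)
    core_genes: list = field(default_factory=list)
    line_a_genes: list = field(default_factory=list)
    line_b_genes: list = field(default_factory=list)
    null_genes: list = field(default_factory=list)
    scale_factors: dict = field(default_factory=dict)  # nanostring sample -> factor
    effect_log2fc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTable":
        return cls(**d)


# ------------------------------------------------------------- expression


def gen_multistudy_expression(config: SynthExpressionConfig):
    """Generate the multi-study log2 expression matrix.

    Returns ``(matrix, sample_sheet, probe_map, truth)``. Probe values are
    class baseline + cumulative planted effect + per-study batch offset +
    Gaussian noise; discordant probes of multi-probe planted genes carry the
    planted effect with flipped sign.
    """
    rng = make_rng(config.seed)
    genes = [_gene_name(i + 1) for i in range(config.n_genes)]
    known = set(genes)
    for p in config.planted:
        if p.gene_id not in known:
            raise ValidationError(f"planted gene {p.gene_id} outside 1..n_genes")
        if p.direction not in DIRECTIONS or p.archetype not in ARCHETYPES:
            raise ValidationError(f"bad planted spec for {p.gene_id}")

    n_samples = config.n_norm + config.n_dtc + config.n_atc
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    tissues = (["NORM"] * config.n_norm + ["DTC"] * config.n_dtc
               + ["ATC"] * config.n_atc)
    studies = rng.integers(0, config.n_studies, size=n_samples)
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "tissue": tissues,
        "study": [f"study{j + 1}" for j in studies],
    })

    # per-study additive batch offsets shared by all probes
    batch = rng.normal(0.0, config.batch_sd, size=config.n_studies)
    sample_batch = batch[studies]

    # cumulative class effect per planted gene (log2), signed by direction
    step = {"NORM": (0.0, 0.0), "DTC": (1.0, 0.0), "ATC": (1.0, 1.0)}
    cum1 = np.array([step[t][0] for t in tissues])
    cum2 = np.array([step[t][1] for t in tissues])
    planted_by_gene = {p.gene_id: p for p in config.planted}

    mult_vals = sorted(config.probe_multiplicity)
    mult_probs = [config.probe_multiplicity[v] for v in mult_vals]
    multiplicity = rng.choice(mult_vals, size=config.n_genes, p=mult_probs)

    # which multi-probe planted genes receive one sign-flipped probe
    discordant: list[str] = []
    flip_draw = rng.random(config.n_genes)
    for gi, g in enumerate(genes):
        if g in planted_by_gene and multiplicity[gi] >= 2 \
                and flip_draw[gi] < config.discordant_frac:
            discordant.append(g)
    discordant_set = set(discordant)

    baselines = rng.uniform(*config.baseline_range, size=config.n_genes)

    probe_rows, probe_ids, probe_genes = [], [], []
    for gi, g in enumerate(genes):
        base = baselines[gi]
        p = planted_by_gene.get(g)
        for k in range(multiplicity[gi]):
            pid = f"{g}_p{k + 1}"
            probe_ids.append(pid)
            probe_genes.append(g)
            mean = np.full(n_samples, base, dtype=float)
            if p is not None:
                sign = 1.0 if p.direction == "up" else -1.0
                # last probe of a discordant gene carries the flipped effect
                if g in discordant_set and k == multiplicity[gi] - 1:
                    sign = -sign
                mean = mean + sign * (cum1 * p.effect_step1 + cum2 * p.effect_step2)
            probe_rows.append(mean)
    means = np.asarray(probe_rows)
    noise = rng.normal(0.0, config.within_sd, size=means.shape) \
        if config.within_sd > 0 else 0.0
    values = means + sample_batch[None, :] + noise

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    probe_map = pd.DataFrame({"probe_id": probe_ids, "gene_id": probe_genes})
    truth = TruthTable(
        signatures={p.gene_id: {"direction": p.direction,
                                "archetype": p.archetype,
                                "effect_step1": p.effect_step1,
                                "effect_step2": p.effect_step2}
                    for p in config.planted},
        discordant=discordant,
    )
    return matrix, sheet, probe_map, truth


# ---------------------------------------------------------------- network


def gen_interaction_network(module_genes, background_genes,
                            p_within: float, p_background: float,
                            seed=0) -> pd.DataFrame:
    """Edge list with a planted densely connected module.

    Pairs inside ``module_genes`` are connected independently at ``p_within``;
    every other pair (background-background and module-background) at
    ``p_background``. Scores are uniform in [0.4, 1).
    """
    if not 0 <= p_within <= 1 or not 0 <= p_background <= 1:
        raise ValidationError("edge probabilities must lie in [0, 1]")
    module_genes = list(module_genes)
    background_genes = list(background_genes)
    if set(module_genes) & set(background_genes):
        raise ValidationError("module and background gene lists must be disjoint")
    rng = make_rng(seed)
    all_genes = module_genes + background_genes
    in_module = set(module_genes)
    edges = []
    for i, a in enumerate(all_genes):
        for b in all_genes[i + 1:]:
            p = p_within if (a in in_module and b in in_module) else p_background
            if rng.random() < p:
                edges.append((a, b, round(float(rng.uniform(0.4, 1.0)), 3)))
    return pd.DataFrame(edges, columns=["gene_a", "gene_b", "score"])


# --------------------------------------------------------------- gene model


def gen_gene_model(n_genes: int, n_chroms: int = 2, chrom_len: int = 1_000_000,
                   seed=0, strand_choice=("+", "-"),
                   tx_len_range=(2000, 6000), min_gap: int = 20_000) -> GeneModel:
    """Random non-overlapping gene model with >= 2 exons and a CDS per gene.

    Genes are distributed round-robin over chromosomes and packed left to
    right with intergenic gaps of at least ``min_gap`` so distal peak
    placement stays feasible.
    """
    rng = make_rng(seed)
    per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0)
                 for c in range(n_chroms)]
    if max(per_chrom) * (tx_len_range[1] + min_gap) + min_gap > chrom_len:
        raise ValidationError(
            f"cannot pack {max(per_chrom)} genes of <= {tx_len_range[1]} bp "
            f"with {min_gap} bp gaps into a {chrom_len} bp chromosome")

    t_rows, e_rows = [], []
    gid = 0
    chrom_sizes = {}
    for c, k in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        chrom_sizes[chrom] = chrom_len
        lengths = rng.integers(tx_len_range[0], tx_len_range[1] + 1, size=k)
        slack = chrom_len - int(lengths.sum()) - (k + 1) * min_gap
        extra = rng.multinomial(slack, np.ones(k + 1) / (k + 1)) if slack > 0 \
            else np.zeros(k + 1, dtype=int)
        pos = min_gap + int(extra[0])
        for j in range(k):
            gid += 1
            g = _gene_name(gid)
            start, end = pos, pos + int(lengths[j])
            strand = str(rng.choice(list(strand_choice)))
            n_exons = int(rng.integers(2, 5))
            # split the transcript into alternating exon/intron blocks
            cuts = np.sort(rng.choice(
                np.arange(start + 100, end - 100, 50),
                size=2 * n_exons - 2, replace=False))
            bounds = [start, *cuts.tolist(), end]
            exon_iv = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
            tid = f"{g}.t1"
            # CDS spans from inside the first exon to inside the last one,
            # leaving UTR stubs on both sides
            cds_start = exon_iv[0][0] + max(1, (exon_iv[0][1] - exon_iv[0][0]) // 3)
            cds_end = exon_iv[-1][1] - max(1, (exon_iv[-1][1] - exon_iv[-1][0]) // 3)
            t_rows.append((g, tid, chrom, start, end, strand, cds_start, cds_end))
            for s, e in exon_iv:
                e_rows.append((tid, chrom, s, e, strand))
            pos = end + min_gap + int(extra[j + 1])

    transcripts = pd.DataFrame(t_rows, columns=[
        "gene_id", "transcript_id", "chrom", "start", "end", "strand",
        "cds_start", "cds_end"])
    exons = pd.DataFrame(e_rows, columns=[
        "transcript_id", "chrom", "start", "end", "strand"])
    return GeneModel(transcripts=transcripts, exons=exons,
                     chrom_sizes=chrom_sizes)


# -------------------------------------------------------------------- ChIP


def gen_chip_replicates(model: GeneModel, target_genes, n_reps: int = 3,
                        reproducible_frac: float = 1.0,
                        n_noise_peaks: int = 0, peak_width: int = 400,
                        tss_window: int = 3000, seed=0):
    """Per-replicate significant peak sets with planted reproducible targets.

    Each target gene receives a peak centred within ``tss_window`` of its TSS
    in >= 2 replicates (reproducible fraction) or in exactly one replicate;
    noise peaks fall at least ``peak_width`` beyond every TSS window and
    appear in exactly one replicate.
    """
    if n_reps < 2:
        raise ValidationError("need at least 2 replicates")
    target_genes = list(target_genes)
    known = set(model.gene_ids)
    missing = [g for g in target_genes if g not in known]
    if missing:
        raise ValidationError(f"target genes not in model: {missing}")
    rng = make_rng(seed)

    tss = model.tss()
    tx = model.transcripts.set_index("transcript_id")
    gene_tss = {}
    for tid, pos in tss.items():
        gene_tss.setdefault(tx.loc[tid, "gene_id"], []).append(
            (tx.loc[tid, "chrom"], int(pos)))

    n_repro = int(round(reproducible_frac * len(target_genes)))
    repro_idx = rng.choice(len(target_genes), size=n_repro, replace=False) \
        if target_genes else np.array([], dtype=int)
    repro = set(np.asarray(target_genes, dtype=object)[repro_idx].tolist())

    reps: list[list[tuple]] = [[] for _ in range(n_reps)]
    half = peak_width // 2
    max_offset = max(tss_window - half - 1, 0)
    for g in target_genes:
        chrom, pos = gene_tss[g][0]
        center = pos + int(rng.integers(-max_offset, max_offset + 1))
        if g in repro:
            support = rng.choice(n_reps, size=int(rng.integers(2, n_reps + 1)),
                                 replace=False)
        else:
            support = [int(rng.integers(0, n_reps))]
        for r in support:
            jitter = int(rng.integers(-50, 51))
            s = max(center + jitter - half, 0)
            reps[r].append((chrom, s, s + peak_width, g))

    # exclusion zones: TSS window padded by one peak width on each side
    pad = tss_window + peak_width
    zones: dict[str, list[tuple]] = {}
    for g, locs in gene_tss.items():
        for chrom, pos in locs:
            zones.setdefault(chrom, []).append((pos - pad, pos + pad))
    chroms = sorted(model.chrom_sizes) or sorted(zones)
    sizes = model.chrom_sizes or {c: 1_000_000 for c in chroms}
    placed = 0
    for _ in range(1000 * max(n_noise_peaks, 1)):
        if placed >= n_noise_peaks:
            break
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, sizes[chrom] - peak_width))
        mid = s + half
        if any(lo <= mid < hi for lo, hi in zones.get(chrom, [])):
            continue
        r = int(rng.integers(0, n_reps))
        reps[r].append((chrom, s, s + peak_width, "noise"))
        placed += 1
    if placed < n_noise_peaks:
        raise ValidationError("no room for distal noise peaks in this model")

    out = []
    for r, rows in enumerate(reps):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        df["name"] = [f"rep{r + 1}_peak{i + 1}" for i in range(len(df))]
        df["score"] = 0
        df["strand"] = "."
        df["signal"] = np.round(rng.uniform(5, 50, size=len(df)), 3)
        df["pvalue"] = np.round(rng.uniform(3, 12, size=len(df)), 3)
        df["qvalue"] = np.round(rng.uniform(2, 10, size=len(df)), 3)
        df["summit"] = (df["end"] - df["start"]) // 2
        out.append(df)

    truth = TruthTable(
        peak_targets=sorted(repro),
        nonreproducible_targets=sorted(set(target_genes) - repro),
    )
    return out, truth


# -------------------------------------------------------------- DEG tables


def gen_deg_tables(core_genes, line_a_only, line_b_only, null_genes,
                   fdr_alt: float = 0.005, fdr_null: float = 0.5,
                   frac_down=(0.52, 0.51), seed=0):
    """Two knockdown DEG tables sharing a planted core gene set.

    Core genes are significant (FDR <= ``fdr_alt``) in both tables,
    line-specific genes in exactly one, null genes in neither; ``frac_down``
    sets the expected fraction of down-regulated genes among the significant
    ones per line.
    """
    groups = [set(core_genes), set(line_a_only), set(line_b_only), set(null_genes)]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if groups[i] & groups[j]:
                raise ValidationError("gene groups must be disjoint")
    if not fdr_alt < fdr_null:
        raise ValidationError("fdr_alt must be < fdr_null")
    rng = make_rng(seed)

    def table(sig_genes, other_genes, frac_dn):
        rows = []
        for g in sorted(sig_genes):
            down = rng.random() < frac_dn
            mag = abs(rng.normal(2.0, 0.6)) + 0.3
            rows.append((g, -mag if down else mag,
                         float(rng.uniform(0, fdr_alt))))
        for g in sorted(other_genes):
            rows.append((g, float(rng.normal(0.0, 0.2)),
                         float(rng.uniform(fdr_null, 1.0))))
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])
        return df.sample(frac=1.0, random_state=int(rng.integers(2**31))) \
                 .reset_index(drop=True)

    sig_a = groups[0] | groups[1]
    sig_b = groups[0] | groups[2]
    deg_a = table(sig_a, groups[2] | groups[3], frac_down[0])
    deg_b = table(sig_b, groups[1] | groups[3], frac_down[1])
    truth = TruthTable(core_genes=sorted(groups[0]),
                       line_a_genes=sorted(sig_a),
                       line_b_genes=sorted(sig_b),
                       null_genes=sorted(groups[3]))
    return deg_a, deg_b, truth


# -------------------------------------------------------------- nanostring


def gen_nanostring_counts(panel_genes, housekeeping: int = 4, n_pos: int = 6,
                          n_neg: int = 6, n_pairs: int = 8,
                          effect_log2fc: float = 2.0, dispersion: float = 0.05,
                          scale_sd: float = 0.3, seed=0):
    """Matched ATC/DTC Nanostring-style raw counts.

    Each sample carries one multiplicative technical scale factor applied to
    every code class; positive controls follow the vendor's geometric ladder,
    negative controls a low background distribution, and panel genes get the
    planted ``effect_log2fc`` in the ATC member of each pair. Endogenous
    counts are Poisson with log-normal extra-dispersion; control counts are
    Poisson around their nominal levels.
    """
    if n_pairs < 2:
        raise ValidationError("need at least 2 matched pairs")
    panel_genes = list(panel_genes)
    rng = make_rng(seed)

    hk_genes = [f"HK{i + 1}" for i in range(housekeeping)]
    pos_genes = [f"POS_{chr(65 + i)}" for i in range(n_pos)]
    neg_genes = [f"NEG_{chr(65 + i)}" for i in range(n_neg)]
    genes = panel_genes + hk_genes + pos_genes + neg_genes
    classes = pd.Series(
        ["Endogenous"] * len(panel_genes) + ["Housekeeping"] * housekeeping
        + ["Positive"] * n_pos + ["Negative"] * n_neg,
        index=pd.Index(genes, name="gene"), name="class")

    sample_ids, tissues, patients = [], [], []
    for p in range(n_pairs):
        for t in ("ATC", "DTC"):
            sample_ids.append(f"P{p + 1:02d}_{t}")
            tissues.append(t)
            patients.append(f"P{p + 1:02d}")
    meta = pd.DataFrame({"sample_id": sample_ids, "tissue": tissues,
                         "patient": patients})

    scale = np.exp(rng.normal(0.0, scale_sd, size=len(sample_ids)))
    base_panel = rng.uniform(200, 4000, size=len(panel_genes))
    base_hk = rng.uniform(40_000, 80_000, size=housekeeping)
    # vendor-style 4-fold positive control ladder
    pos_levels = np.array([2.0e4 / 4 ** i for i in range(n_pos)])
    neg_level = 25.0

    counts = np.zeros((len(genes), len(sample_ids)))
    for j, (sid, tis) in enumerate(zip(sample_ids, tissues)):
        mu_panel = base_panel * (2.0 ** effect_log2fc if tis == "ATC" else 1.0)
        extra = np.exp(rng.normal(0.0, dispersion, size=len(panel_genes))) \
            if dispersion > 0 else 1.0
        mu = np.concatenate([
            mu_panel * extra, base_hk, pos_levels, np.full(n_neg, neg_level),
        ]) * scale[j]
        counts[:, j] = rng.poisson(mu)

    mat = pd.DataFrame(counts, index=classes.index, columns=sample_ids)
    truth = TruthTable(scale_factors=dict(zip(sample_ids, scale.tolist())),
                       effect_log2fc=effect_log2fc)
    return mat, classes, meta, truth
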