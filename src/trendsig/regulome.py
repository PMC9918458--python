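"""ChIP-seq consensus peaks, TSS-window target assignment and the
ChIP/RNA-seq core-program intersection.

Inputs are the outputs of standard upstream processing: per-replicate
significant peak calls (BED/narrowPeak) and per-cell-line knockdown DEG
tables. The stage reproduces the downstream integration: peaks reproducible
in >= 2 of 3 replicates define the binding profile, genes with a consensus
peak within +/-3 kb of a TSS are direct targets, and the core transcriptional
program is the triple intersection of the two DEG sets with the target list.

All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genemodel import GeneModel

CATEGORIES = ("TSS", "five_prime_UTR", "three_prime_UTR", "exon", "intron",
              "downstream", "distal_intergenic")


def consensus_peaks(replicates, min_support: int = 2) -> pd.DataFrame:
    """Merge replicate peak sets and keep spans supported by >= ``min_support``
    distinct replicates.

    Overlapping intervals from all replicates are merged into maximal spans
    (union); a merged span is retained iff it contains peaks from at least
    ``min_support`` different replicates, and the retained interval is the
    full merged span.
    """
    if min_support > len(replicates):
        raise ValidationError(
            f"min_support={min_support} exceeds {len(replicates)} replicates")
    rows = []
    for r, df in enumerate(replicates):
        for t in df.itertuples(index=False):
            if t.start >= t.end:
                raise ValidationError("invalid interval start >= end")
            rows.append((str(t.chrom), int(t.start), int(t.end), r))
    out = []
    all_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rep"])
    for chrom, grp in all_df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        reps: set[int] = set()
        for t in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, reps = t.start, t.end, {t.rep}
            elif t.start < cur_e:  # strict overlap (half-open intervals)
                cur_e = max(cur_e, t.end)
                reps.add(t.rep)
            else:
                out.append((chrom, cur_s, cur_e, len(reps)))
                cur_s, cur_e, reps = t.start, t.end, {t.rep}
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e, len(reps)))
    cons = pd.DataFrame(out, columns=["chrom", "start", "end", "n_replicates"])
    cons = cons[cons["n_replicates"] >= min_support].reset_index(drop=True)
    cons["name"] = [f"consensus_{i + 1}" for i in range(len(cons))]
    return cons[["chrom", "start", "end", "name", "n_replicates"]]


def _anchors(peaks: pd.DataFrame) -> np.ndarray:
    """Peak anchor positions: summit when provided, midpoint otherwise."""
    mid = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    if "summit" in peaks.columns:
        summit = pd.to_numeric(peaks["summit"], errors="coerce")
        use = summit.notna() & (summit >= 0)
        mid = np.where(use, peaks["start"].to_numpy() + summit.fillna(0).astype(int),
                       mid)
    return mid.astype(int)


def _tss_frame(model: GeneModel) -> pd.DataFrame:
    tss = model.tss()
    t = model.transcripts
    return pd.DataFrame({
        "chrom": t["chrom"].to_numpy(),
        "tss": tss.loc[t["transcript_id"]].to_numpy(),
        "strand": t["strand"].to_numpy(),
        "gene_id": t["gene_id"].to_numpy(),
        "transcript_id": t["transcript_id"].to_numpy(),
    })


def assign_peaks_to_genes(peaks: pd.DataFrame, model: GeneModel,
                          tss_window: int = 3000):
    """Annotate peaks with their nearest TSS and derive the target gene set.

    Per peak the nearest TSS is chosen by absolute anchor-TSS distance; the
    reported distance is signed and strand-aware (negative = upstream of the
    TSS). Ties are broken toward the smaller signed distance, then the
    lexicographically smaller gene id. A gene is a *target* iff some peak
    anchor lies within ``+/-tss_window`` of one of its TSSs. Peaks on
    chromosomes absent from the model are annotated "unplaced" and excluded
    from the target set.

    Returns ``(annotation, targets)``.
    """
    tssf = _tss_frame(model)
    by_chrom = {c: g.sort_values("tss").reset_index(drop=True)
                for c, g in tssf.groupby("chrom")}
    anchors = _anchors(peaks)
    rows = []
    targets: set[str] = set()
    for i, (t, anchor) in enumerate(zip(peaks.itertuples(index=False), anchors)):
        chrom = str(t.chrom)
        if chrom not in by_chrom:
            rows.append((chrom, t.start, t.end, anchor, "unplaced", "unplaced",
                         np.nan, False))
            continue
        cand = by_chrom[chrom]
        dist_abs = np.abs(cand["tss"].to_numpy() - anchor)
        signed = np.where(cand["strand"].to_numpy() == "+",
                          anchor - cand["tss"].to_numpy(),
                          cand["tss"].to_numpy() - anchor)
        order = sorted(range(len(cand)),
                       key=lambda j: (dist_abs[j], signed[j],
                                      cand.at[j, "gene_id"]))
        j = order[0]
        is_target = dist_abs[j] <= tss_window
        rows.append((chrom, t.start, t.end, anchor,
                     cand.at[j, "gene_id"], cand.at[j, "transcript_id"],
                     int(signed[j]), bool(is_target)))
        hits = np.nonzero(dist_abs <= tss_window)[0]
        targets.update(cand["gene_id"].iloc[hits])
    annotation = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "anchor", "gene_id", "transcript_id",
        "signed_distance", "within_window"])
    return annotation, targets


def _utr_intervals(model: GeneModel):
    """Per-chromosome 5'/3' UTR, exon and transcript interval tables."""
    ex = model.exons
    tx = model.transcripts.set_index("transcript_id")
    utr5, utr3, cds_exon = [], [], []
    for tid, grp in ex.groupby("transcript_id"):
        t = tx.loc[tid]
        cs, ce = int(t["cds_start"]), int(t["cds_end"])
        for e in grp.itertuples(index=False):
            if cs < 0:  # non-coding: whole exon counts as exon
                cds_exon.append((e.chrom, e.start, e.end))
                continue
            left = (e.start, min(e.end, cs))      # exonic part before CDS
            mid = (max(e.start, cs), min(e.end, ce))
            right = (max(e.start, ce), e.end)     # exonic part after CDS
            if left[0] < left[1]:
                (utr5 if t["strand"] == "+" else utr3).append(
                    (e.chrom, *left))
            if mid[0] < mid[1]:
                cds_exon.append((e.chrom, *mid))
            if right[0] < right[1]:
                (utr3 if t["strand"] == "+" else utr5).append(
                    (e.chrom, *right))
    cols = ["chrom", "start", "end"]
    return (pd.DataFrame(utr5, columns=cols), pd.DataFrame(utr3, columns=cols),
            pd.DataFrame(cds_exon, columns=cols))


def _in_any(chrom: str, pos: int, table: pd.DataFrame) -> bool:
    if table.empty:
        return False
    sel = table[table["chrom"] == chrom]
    return bool(((sel["start"] <= pos) & (pos < sel["end"])).any())


def genomic_distribution(peaks: pd.DataFrame, model: GeneModel,
                         tss_window: int = 3000,
                         downstream_window: int = 3000) -> pd.Series:
    """Fraction of peaks per genomic category.

    Each peak is assigned exactly one category by its anchor with precedence
    TSS > 5'UTR > 3'UTR > exon > intron > downstream > distal_intergenic;
    the returned fractions sum to 1.
    """
    tssf = _tss_frame(model)
    utr5, utr3, cds_exon = _utr_intervals(model)
    tx = model.transcripts
    down = pd.DataFrame({
        "chrom": tx["chrom"].to_numpy(),
        "start": np.where(tx["strand"] == "+", tx["end"].to_numpy(),
                          tx["start"].to_numpy() - downstream_window),
        "end": np.where(tx["strand"] == "+",
                        tx["end"].to_numpy() + downstream_window,
                        tx["start"].to_numpy()),
    })
    body = tx[["chrom", "start", "end"]]

    counts = dict.fromkeys(CATEGORIES, 0)
    anchors = _anchors(peaks)
    for t, anchor in zip(peaks.itertuples(index=False), anchors):
        chrom = str(t.chrom)
        near = tssf[tssf["chrom"] == chrom]
        if len(near) and (np.abs(near["tss"].to_numpy() - anchor)
                          <= tss_window).any():
            cat = "TSS"
        elif _in_any(chrom, anchor, utr5):
            cat = "five_prime_UTR"
        elif _in_any(chrom, anchor, utr3):
            cat = "three_prime_UTR"
        elif _in_any(chrom, anchor, cds_exon):
            cat = "exon"
        elif _in_any(chrom, anchor, body):
            cat = "intron"
        elif _in_any(chrom, anchor, down):
            cat = "downstream"
        else:
            cat = "distal_intergenic"
        counts[cat] += 1
    total = max(sum(counts.values()), 1)
    return pd.Series({c: counts[c] / total for c in CATEGORIES},
                     name="fraction")


def threshold_deg(table: pd.DataFrame, fdr: float = 0.05) -> set:
    """Genes with FDR strictly below the threshold; duplicate gene rows are
    collapsed keeping the smallest FDR."""
    if ((table["fdr"] < 0) | (table["fdr"] > 1)).any():
        raise ValidationError("FDR values outside [0, 1]")
    best = table.groupby("gene_id")["fdr"].min()
    return set(best.index[best < fdr])


@dataclass(frozen=True)
class CoreProgram:
    """Triple intersection of the two knockdown DEG sets with the ChIP target
    list, plus all seven exclusive Venn region counts."""

    deg_a: frozenset
    deg_b: frozenset
    chip_targets: frozenset
    core: frozenset = field(init=False)
    venn: dict = field(init=False)

    def __post_init__(self):
        a, b, c = self.deg_a, self.deg_b, self.chip_targets
        object.__setattr__(self, "core", a & b & c)
        venn = {
            "deg_a_only": len(a - b - c),
            "deg_b_only": len(b - a - c),
            "chip_only": len(c - a - b),
            "deg_a_deg_b": len((a & b) - c),
            "deg_a_chip": len((a & c) - b),
            "deg_b_chip": len((b & c) - a),
            "core": len(a & b & c),
        }
        object.__setattr__(self, "venn", venn)

    @property
    def union_size(self) -> int:
        return len(self.deg_a | self.deg_b | self.chip_targets)


def core_program(deg_a, deg_b, chip_targets) -> CoreProgram:
    """Build the core transcriptional program from three gene sets (exact,
    case-sensitive gene symbols)."""
    return CoreProgram(deg_a=frozenset(deg_a), deg_b=frozenset(deg_b),
                       chip_targets=frozenset(chip_targets))
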