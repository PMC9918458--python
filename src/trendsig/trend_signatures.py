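"""Core signature derivation along the normal -> DTC -> ATC axis.

The model of disease progression is a two-step linear evolution: normal
tissue transforms into differentiated carcinoma (DTC), which may
de-differentiate into anaplastic carcinoma (ATC). Genes are called
deregulated when at least one of their probes is significant (BH-adjusted
p < alpha) in all three pairwise comparisons, and are split into monotone
Trend Up / Trend Down lists. Each trend gene's pair of fold changes —
(DTC vs normal, ATC vs DTC) — is standardized across genes into sFC values,
and explicit sFC cutoffs partition the trend lists into three signatures:
S1 (deregulated mainly in the first step), S2 (mainly in the second step)
and S3 (throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass(frozen=True)
class SignatureThresholds:
    """sFC cutoffs: ``lo`` separates "not deregulated in this step" from
    "deregulated", ``hi`` marks "strongly deregulated". Defaults 2 and 4
    standardized units."""

    lo: float = 2.0
    hi: float = 4.0

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValidationError("thresholds must satisfy 0 < lo < hi")


def differential_probes(m: pd.DataFrame, sheet: pd.DataFrame,
                        class_a: str, class_b: str) -> pd.DataFrame:
    """Per-probe two-sided pooled-variance Student's t of class_a vs class_b.

    Returns a frame indexed by probe with columns log2fc (mean(a) - mean(b)),
    t_stat, p, q (Benjamini-Hochberg across all probes of this comparison)
    and a ``degenerate`` flag for probes where both groups are constant and
    equal (p set to 1 by convention).
    """
    ids_a = sheet.loc[sheet["tissue"] == class_a, "sample_id"]
    ids_b = sheet.loc[sheet["tissue"] == class_b, "sample_id"]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(
            f"need >= 2 samples per class, got {class_a}:{len(ids_a)} "
            f"{class_b}:{len(ids_b)}")
    a = m[list(ids_a)].to_numpy(dtype=float)
    b = m[list(ids_b)].to_numpy(dtype=float)
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # constant probes trip scipy's precision warning; they are flagged
        # and handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t_stat)
    # zero pooled variance with equal means: no evidence either way
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "log2fc": log2fc, "t_stat": t_stat, "p": p, "q": q,
        "degenerate": degenerate,
    }, index=m.index.rename("probe_id"))


def classify_trends(res_dtc_vs_norm: pd.DataFrame,
                    res_atc_vs_dtc: pd.DataFrame,
                    res_atc_vs_norm: pd.DataFrame,
                    probe_map: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Collapse probe-level comparisons into a per-gene trend table.

    A probe *qualifies* when its BH q is below ``alpha`` in all three
    comparisons. A gene is deregulated iff it has >= 1 qualifying probe; its
    trend is Up when the qualifying probes rise in both steps (both fold
    changes > 0), Down when both fall, and the gene is excluded as
    discordant when qualifying probes disagree. The representative probe is
    the qualifying probe with the smallest ATC-vs-DTC q (ties -> smaller
    probe id); for non-deregulated genes it is the probe with the smallest
    ATC-vs-DTC q, so every gene still contributes one fold-change pair to
    the standardization population.
    """
    tables = (res_dtc_vs_norm, res_atc_vs_dtc, res_atc_vs_norm)
    probes = tables[0].index
    for t in tables[1:]:
        if not probes.equals(t.index):
            raise ValidationError("comparison tables cover different probes")
    unmapped = set(probes) - set(probe_map["probe_id"])
    if unmapped:
        raise ValidationError(f"probes missing from probe map: "
                              f"{sorted(unmapped)[:5]}")

    df = pd.DataFrame({
        "gene_id": probe_map.set_index("probe_id").loc[probes, "gene_id"],
        "fc_step1": res_dtc_vs_norm["log2fc"],
        "fc_step2": res_atc_vs_dtc["log2fc"],
        "q1": res_dtc_vs_norm["q"],
        "q2": res_atc_vs_dtc["q"],
        "q3": res_atc_vs_norm["q"],
    }, index=probes)
    df["qualifies"] = (df["q1"] < alpha) & (df["q2"] < alpha) & (df["q3"] < alpha)
    df["trend"] = np.select(
        [(df["fc_step1"] > 0) & (df["fc_step2"] > 0),
         (df["fc_step1"] < 0) & (df["fc_step2"] < 0)],
        ["up", "down"], default="none")

    rows = []
    for gene, grp in df.groupby("gene_id", sort=True):
        qual = grp[grp["qualifies"]]
        pool = qual if len(qual) else grp
        rep = min(pool.index, key=lambda pid: (pool.at[pid, "q2"], pid))
        if len(qual) == 0:
            label = "not_deg"
        else:
            trends = set(qual["trend"]) - {"none"}
            if trends == {"up"}:
                label = "TrendUp"
            elif trends == {"down"}:
                label = "TrendDown"
            elif len(trends) == 2:
                label = "excluded_discordant"
            else:  # significant in all comparisons but never monotone
                label = "not_deg"
        rows.append((gene, label, rep,
                     df.at[rep, "fc_step1"], df.at[rep, "fc_step2"]))
    return pd.DataFrame(rows, columns=[
        "gene_id", "label", "representative_probe", "fc_step1", "fc_step2",
    ]).set_index("gene_id")


def standardize_fc(fc_values: pd.Series) -> pd.Series:
    """Standardized fold change: (FC - mean FC) / sd FC over the input
    population (sample sd, ddof=1)."""
    if len(fc_values) < 2:
        raise ValidationError("need >= 2 fold changes to standardize")
    sd = fc_values.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero fold-change standard deviation")
    return (fc_values - fc_values.mean()) / sd


def assign_signatures(trend_table: pd.DataFrame,
                      sfc_step1: pd.Series, sfc_step2: pd.Series,
                      thr: SignatureThresholds = SignatureThresholds()
                      ) -> pd.DataFrame:
    """Partition trend genes into S1/S2/S3 by their sFC pair.

    Up genes: S1 iff s1 > hi and s2 < lo; S2 iff s1 < lo and s2 > hi;
    S3 iff s1 > lo and s2 > lo and the gene is not already S1/S2 (the S3
    region overlaps the corners of S1/S2; precedence S1 > S2 > S3 keeps the
    signatures disjoint). Down genes use the mirrored rules with negated
    thresholds. All inequalities are strict; values at a cutoff stay
    unassigned.
    """
    trend_genes = trend_table[trend_table["label"].isin(["TrendUp", "TrendDown"])]
    missing = set(trend_genes.index) - (set(sfc_step1.index) & set(sfc_step2.index))
    if missing:
        raise ValidationError(f"trend genes missing sFC: {sorted(missing)[:5]}")

    lo, hi = thr.lo, thr.hi
    rows = []
    for gene, row in trend_genes.iterrows():
        s1 = float(sfc_step1[gene])
        s2 = float(sfc_step2[gene])
        direction = "up" if row["label"] == "TrendUp" else "down"
        if direction == "up":
            if s1 > hi and s2 < lo:
                sig = "S1"
            elif s1 < lo and s2 > hi:
                sig = "S2"
            elif s1 > lo and s2 > lo:
                sig = "S3"
            else:
                sig = "unassigned"
        else:
            if s1 < -hi and s2 > -lo:
                sig = "S1"
            elif s1 > -lo and s2 < -hi:
                sig = "S2"
            elif s1 < -lo and s2 < -lo:
                sig = "S3"
            else:
                sig = "unassigned"
        rows.append((gene, direction, s1, s2, sig))
    out = pd.DataFrame(rows, columns=[
        "gene_id", "direction", "sfc_step1", "sfc_step2", "signature",
    ]).set_index("gene_id")
    return out.sort_index()


def derive_signatures(m: pd.DataFrame, sheet: pd.DataFrame,
                      probe_map: pd.DataFrame, alpha: float = 0.05,
                      thresholds: SignatureThresholds = SignatureThresholds()
                      ) -> dict:
    """Run the full signature derivation on a normalized matrix.

    Computes the three pairwise comparisons, the per-gene trend table, the
    per-comparison sFC values (standardized over all genes, using each
    gene's representative-probe fold change) and the S1/S2/S3 assignment.
    Returns a dict with keys ``comparisons``, ``trend_table``, ``sfc_step1``,
    ``sfc_step2`` and ``signatures``.
    """
    comparisons = {
        "dtc_vs_norm": differential_probes(m, sheet, "DTC", "NORM"),
        "atc_vs_dtc": differential_probes(m, sheet, "ATC", "DTC"),
        "atc_vs_norm": differential_probes(m, sheet, "ATC", "NORM"),
    }
    trend_table = classify_trends(comparisons["dtc_vs_norm"],
                                  comparisons["atc_vs_dtc"],
                                  comparisons["atc_vs_norm"],
                                  probe_map, alpha=alpha)
    sfc1 = standardize_fc(trend_table["fc_step1"])
    sfc2 = standardize_fc(trend_table["fc_step2"])
    signatures = assign_signatures(trend_table, sfc1, sfc2, thresholds)
    return {
        "comparisons": comparisons,
        "trend_table": trend_table,
        "sfc_step1": sfc1,
        "sfc_step2": sfc2,
        "signatures": signatures,
    }


def enrichment_test(gene_set, annotation: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``gene_set`` in each
    named annotation set, BH-corrected across sets."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    gene_set = set(gene_set) & universe
    rows = []
    for name in sorted(annotation):
        ann = set(annotation[name]) & universe
        k = len(gene_set & ann)
        M, n, N = len(universe), len(ann), len(gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((name, k, N * n / M, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "expected", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df
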