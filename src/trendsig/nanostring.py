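"""Nanostring-style count normalization and validation statistics.

Raw counts carry four code classes: Endogenous (the panel), Positive and
Negative spike-in controls, and Housekeeping genes. Normalization follows
the vendor's standard scheme: subtract a background estimated from negative
controls, rescale by a positive-control factor (lane technical yield), then
by a housekeeping factor (RNA content), and log2-transform. The module also
computes per-gene differential statistics between ATC and DTC samples,
matched-pair comparisons, percent-expressing summaries, and the qPCR
delta-delta-Ct relative quantification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import round_half_up
from .errors import ValidationError


def _geomean(x: np.ndarray, axis=0) -> np.ndarray:
    return np.exp(np.log(x).mean(axis=axis))


def normalize_nanostring(mat: pd.DataFrame, classes: pd.Series):
    """Normalize raw counts to a log2 matrix of Endogenous genes.

    Per sample: (1) background = mean + 2*sd of negative controls, subtracted
    and clipped at zero; (2) positive-control factor = grand geometric mean of
    the per-sample positive-control geomeans divided by this sample's geomean,
    multiplied in; (3) housekeeping factor computed the same way from the
    housekeeping genes after steps 1-2, multiplied in; (4) values floored at
    1 count and log2-transformed (so "not above background" maps to 0).

    Returns ``(norm, factors)``: the panel's log2 matrix and a per-sample
    frame with background, pos_factor, hk_factor and their product.
    """
    classes = classes.loc[mat.index]
    neg = mat[classes == "Negative"]
    pos = mat[classes == "Positive"]
    hk = mat[classes == "Housekeeping"]
    endo = mat[classes == "Endogenous"]
    if neg.empty or pos.empty:
        raise ValidationError("need >= 1 positive and >= 1 negative control")
    if hk.empty:
        raise ValidationError("need >= 1 housekeeping gene")

    dead = [s for s in mat.columns
            if (pos[s] <= 0).all() or (hk[s] <= 0).all()]
    if dead:
        raise ValidationError(f"all-zero controls in samples: {dead}")

    background = neg.mean(axis=0) + 2 * neg.std(axis=0, ddof=1)
    sub = (mat.loc[classes != "Negative"] - background).clip(lower=0.0)

    pos_gm = pd.Series(_geomean(pos.to_numpy(), axis=0), index=mat.columns)
    pos_factor = _geomean(pos_gm.to_numpy()) / pos_gm
    scaled = sub.mul(pos_factor, axis=1)

    hk_scaled = scaled.loc[hk.index].clip(lower=1.0)
    hk_gm = pd.Series(_geomean(hk_scaled.to_numpy(), axis=0), index=mat.columns)
    hk_factor = _geomean(hk_gm.to_numpy()) / hk_gm
    final = scaled.mul(hk_factor, axis=1)

    norm = np.log2(final.loc[endo.index].clip(lower=1.0))
    factors = pd.DataFrame({
        "background": background,
        "pos_factor": pos_factor,
        "hk_factor": hk_factor,
        "total_factor": pos_factor * hk_factor,
    })
    return norm, factors


def differential_panel(norm: pd.DataFrame, tissues: pd.Series,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene ATC vs DTC two-sided Student's t on log2 values, with BH
    correction across the panel and a ``validated`` flag (q < alpha and
    log2FC > 0)."""
    tissues = tissues.loc[norm.columns]
    atc = norm.loc[:, tissues == "ATC"].to_numpy()
    dtc = norm.loc[:, tissues == "DTC"].to_numpy()
    if atc.shape[1] < 2 or dtc.shape[1] < 2:
        raise ValidationError("need >= 2 samples per tissue class")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(atc, dtc, axis=1, equal_var=True)
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    log2fc = atc.mean(axis=1) - dtc.mean(axis=1)
    return pd.DataFrame({
        "log2fc": log2fc, "p": p, "q": q,
        "validated": (q < alpha) & (log2fc > 0),
    }, index=norm.index)


def paired_component_compare(norm: pd.DataFrame,
                             meta: pd.DataFrame) -> pd.DataFrame:
    """Matched ATC/DTC comparison within patients.

    ``meta`` needs sample_id, tissue and patient columns; every patient must
    contribute exactly one ATC and one DTC sample. Returns per gene the mean
    paired log2 difference, the paired t p-value and the fraction of pairs
    with a positive difference.
    """
    meta = meta.set_index("sample_id").loc[norm.columns]
    deltas = {}
    for patient, grp in meta.groupby("patient"):
        atc = grp.index[grp["tissue"] == "ATC"]
        dtc = grp.index[grp["tissue"] == "DTC"]
        if len(atc) != 1 or len(dtc) != 1:
            raise ValidationError(f"patient {patient} lacks a complete "
                                  f"ATC/DTC pair")
        deltas[patient] = norm[atc[0]] - norm[dtc[0]]
    d = pd.DataFrame(deltas)  # genes x patients
    t_stat, p = stats.ttest_1samp(d.to_numpy(), 0.0, axis=1)
    return pd.DataFrame({
        "mean_delta": d.mean(axis=1),
        "p": np.where(np.isfinite(p), p, 1.0),
        "frac_positive": (d > 0).mean(axis=1),
    }, index=norm.index)


def percent_expressing(norm: pd.DataFrame, tissues: pd.Series) -> pd.DataFrame:
    """Percentage of samples per tissue with the gene above background
    (normalized log2 value > 0), one decimal."""
    tissues = tissues.loc[norm.columns]
    out = {}
    for tis in sorted(tissues.unique()):
        cols = norm.loc[:, tissues == tis]
        pct = (cols > 0).mean(axis=1) * 100.0
        out[tis] = pct.map(lambda v: round_half_up(v, 1))
    return pd.DataFrame(out, index=norm.index)


def ddct(ct: pd.DataFrame, reference_gene: str,
         control_condition: str) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``ct`` has columns (condition, gene, ct). For each gene and condition,
    dCt = Ct(gene) - Ct(reference); ddCt = dCt(condition) - dCt(control);
    relative expression = 2**(-ddCt), hence 1.0 in the control condition.
    """
    pivot = ct.pivot_table(index="gene", columns="condition", values="ct")
    if reference_gene not in pivot.index:
        raise ValidationError(f"reference gene {reference_gene!r} missing")
    ref = pivot.loc[reference_gene]
    if ref.isna().any():
        missing = list(ref.index[ref.isna()])
        raise ValidationError(f"reference Ct missing in conditions: {missing}")
    if control_condition not in pivot.columns:
        raise ValidationError(f"control condition {control_condition!r} missing")
    dct = pivot.sub(ref, axis=1)
    ddct_tab = dct.sub(dct[control_condition], axis=0)
    rel = 2.0 ** (-ddct_tab)
    rel = rel.drop(index=reference_gene)
    return rel.reset_index().melt(id_vars="gene", value_name="rel_expression")
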