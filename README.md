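# trendsig

Tools for deriving **three-state disease-progression gene signatures** and
the regulatory program behind them, built around the evolution of
differentiated thyroid carcinoma (DTC) into anaplastic thyroid carcinoma
(ATC). The package is aimed at computational biologists who assemble
multi-study expression cohorts of normal / DTC / ATC profiles and want a
tested, reproducible implementation of the whole downstream chain:
signature derivation, interaction-network module extraction,
Nanostring-style validation statistics, and ChIP-seq/RNA-seq integration.

## The model

Disease progression is modelled as a two-step linear evolution
normal → DTC → ATC. On a probe-level log2 expression matrix with tissue
labels, the pipeline computes three pairwise comparisons (pooled-variance
Student's *t*, Benjamini–Hochberg FDR). A gene is *deregulated* when at
least one of its probes is significant (q < 0.05) in **all three**
comparisons, and it enters the **Trend Up** (resp. **Trend Down**) list when
its qualifying probes rise (fall) monotonically in both steps; genes whose
qualifying probes disagree are excluded as discordant.

Each gene contributes one fold-change pair
(FC₁ = DTC − normal, FC₂ = ATC − DTC, log2 units) from its representative
probe. Per comparison the fold changes are standardized across genes into
the *standardized fold change*

    sFC = (FC − mean FC) / sd FC

and explicit cutoffs (lo = 2, hi = 4 standardized units) partition the
trend lists into three signatures:

| signature | meaning | Up rule |
|---|---|---|
| S1 | deregulated mainly in the normal→DTC step | sFC₁ > 4 and sFC₂ < 2 |
| S2 | deregulated mainly in the DTC→ATC step | sFC₁ < 2 and sFC₂ > 4 |
| S3 | deregulated throughout | sFC₁ > 2 and sFC₂ > 2 |

Down rules are mirrored with negated thresholds; precedence S1 > S2 > S3
keeps the signatures disjoint. Signature genes are then mapped into a
protein–protein interaction edge list (STRING-export-like) and the disease
*gene module* is the largest connected component of the induced subgraph.

The regulome stage consumes per-replicate ChIP-seq peak calls and two
knockdown DEG tables: peaks reproducible in ≥ 2 of 3 replicates define the
binding profile, genes with a consensus peak within ±3 kb of a TSS are
direct targets, and the *core program* is the triple intersection
DEG(line A) ∩ DEG(line B) ∩ targets. A Nanostring module implements the
vendor-style normalization (negative-control background, positive-control
and housekeeping geometric-mean factors) plus per-gene validation
statistics and qPCR ΔΔCt.

Every input can be generated synthetically with planted truth
(`trendsig.synthdata`), so the full pipeline is verifiable at desk scale.

## Worked example

```python
from trendsig import SynthExpressionConfig, derive_signatures, synthdata
from trendsig.expression_qc import quantile_normalize
from trendsig.pipeline import evaluate_recovery

cfg = SynthExpressionConfig(
    n_norm=30, n_dtc=30, n_atc=20, n_genes=2000,
    planted=synthdata.default_planted(), within_sd=0.5, seed=1)
matrix, sheet, probe_map, truth = synthdata.gen_multistudy_expression(cfg)
res = derive_signatures(quantile_normalize(matrix), sheet, probe_map)

trend = res["trend_table"]
print(trend["label"].value_counts().to_dict())
sig = res["signatures"]
print(sig.groupby(["direction", "signature"]).size().to_dict())
print({k: round(v, 3) for k, v in
       evaluate_recovery(trend, sig, truth).items()})
```

prints

```
{'not_deg': 1962, 'TrendUp': 18, 'TrendDown': 18, 'excluded_discordant': 2}
{('down', 'S3'): 15, ('down', 'unassigned'): 3, ('up', 'S1'): 1, ('up', 'S3'): 16, ('up', 'unassigned'): 1}
{'n_planted': 120, 'n_recovered': 36, 'n_monotone': 38, 'n_monotone_found': 36, 'trend_sensitivity': 0.947, 'recall': 0.3, 'direction_accuracy': 1.0, 'archetype_accuracy': 0.861, 'discordant_exclusion_rate': 0.4}
```

The 120 planted genes comprise 20 per archetype (S1/S2/S3) per direction.
Only genes that shift in *both* steps (the S3 archetypes) can satisfy the
all-three-comparisons monotone rule, so 36 of the 38 eligible genes are
recovered (`trend_sensitivity` 0.947), all with the correct direction, and
86% land in their planted signature; two genes carrying a deliberately
discordant probe are correctly excluded.

The same stages are available from the shell:

```bash
trendsig simulate --out-dir demo --seed 1
trendsig signatures --expression demo/expression.tsv \
    --sample-sheet demo/samples.tsv --probe-map demo/probe_map.tsv \
    --edges demo/edges.tsv --out-dir demo/out
trendsig chip-consensus --peaks demo/peaks_rep1.narrowPeak \
    --peaks demo/peaks_rep2.narrowPeak --peaks demo/peaks_rep3.narrowPeak \
    --out-dir demo/out
trendsig annotate-peaks --peaks demo/out/consensus.bed --gtf demo/genes.gtf \
    --out-dir demo/out
```

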