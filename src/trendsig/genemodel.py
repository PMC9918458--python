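"""Transcript/gene model container with GTF round-trip.

Coordinates are 0-based half-open in memory. On disk the model is a standard
GTF (1-based, closed intervals); conversion happens only at I/O time so that
interval arithmetic inside the package never mixes conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pyranges as pr

from .errors import InputError, ValidationError

TRANSCRIPT_COLS = [
    "gene_id", "transcript_id", "chrom", "start", "end", "strand",
    "cds_start", "cds_end",
]
EXON_COLS = ["transcript_id", "chrom", "start", "end", "strand"]


@dataclass
class GeneModel:
    """A set of transcripts with exon blocks and an optional CDS per transcript.

    ``transcripts`` columns: gene_id, transcript_id, chrom, start, end, strand,
    cds_start, cds_end (cds bounds may be -1 for non-coding transcripts).
    ``exons`` columns: transcript_id, chrom, start, end, strand.
    """

    transcripts: pd.DataFrame
    exons: pd.DataFrame
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        t, e = self.transcripts, self.exons
        if not set(TRANSCRIPT_COLS) <= set(t.columns):
            raise ValidationError(f"transcripts need columns {TRANSCRIPT_COLS}")
        if not set(EXON_COLS) <= set(e.columns):
            raise ValidationError(f"exons need columns {EXON_COLS}")
        if (t["start"] >= t["end"]).any() or (e["start"] >= e["end"]).any():
            raise ValidationError("intervals must satisfy start < end")
        bad = set(t["strand"]) - {"+", "-"}
        if bad:
            raise ValidationError(f"invalid strand values: {bad}")
        # exons must stay inside their transcript
        merged = e.merge(t[["transcript_id", "start", "end"]],
                         on="transcript_id", suffixes=("", "_tx"))
        if ((merged["start"] < merged["start_tx"]) |
                (merged["end"] > merged["end_tx"])).any():
            raise ValidationError("exon outside its transcript bounds")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.transcripts["gene_id"].unique())

    def tss(self) -> pd.Series:
        """Per-transcript TSS: start on '+', end-1 on '-' (0-based position)."""
        t = self.transcripts
        return pd.Series(
            t["start"].where(t["strand"] == "+", t["end"] - 1).to_numpy(),
            index=t["transcript_id"], name="tss",
        )

    def tes(self) -> pd.Series:
        """Per-transcript transcription end site (0-based position)."""
        t = self.transcripts
        return pd.Series(
            (t["end"] - 1).where(t["strand"] == "+", t["start"]).to_numpy(),
            index=t["transcript_id"], name="tes",
        )

    def to_gtf(self, path) -> None:
        """Serialize as GTF (1-based closed intervals, transcript + exon rows)."""
        rows = []
        ex_by_tx = {k: v for k, v in self.exons.groupby("transcript_id")}
        for t in self.transcripts.itertuples(index=False):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            rows.append((t.chrom, "trendsig", "transcript",
                         t.start + 1, t.end, ".", t.strand, ".", attrs))
            for e in ex_by_tx.get(t.transcript_id, pd.DataFrame(columns=EXON_COLS)).itertuples(index=False):
                rows.append((e.chrom, "trendsig", "exon",
                             e.start + 1, e.end, ".", e.strand, ".", attrs))
            if t.cds_start >= 0:
                rows.append((t.chrom, "trendsig", "CDS",
                             t.cds_start + 1, t.cds_end, ".", t.strand, ".", attrs))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False,
                                  quoting=3)

    @classmethod
    def from_gtf(cls, path) -> "GeneModel":
        try:
            df = pr.read_gtf(str(path)).df
        except Exception as exc:  # pragma: no cover - passthrough context
            raise InputError(f"failed to parse GTF {path}: {exc}") from exc
        if df.empty:
            raise InputError(f"GTF {path} contains no features")
        df = df.rename(columns={"Chromosome": "chrom", "Start": "start",
                                "End": "end", "Strand": "strand"})
        tx = df[df["Feature"] == "transcript"]
        cds = df[df["Feature"] == "CDS"].set_index("transcript_id")
        transcripts = pd.DataFrame({
            "gene_id": tx["gene_id"].to_numpy(),
            "transcript_id": tx["transcript_id"].to_numpy(),
            "chrom": tx["chrom"].astype(str).to_numpy(),
            "start": tx["start"].astype(int).to_numpy(),
            "end": tx["end"].astype(int).to_numpy(),
            "strand": tx["strand"].astype(str).to_numpy(),
        })
        transcripts["cds_start"] = [
            int(cds.loc[t, "start"]) if t in cds.index else -1
            for t in transcripts["transcript_id"]]
        transcripts["cds_end"] = [
            int(cds.loc[t, "end"]) if t in cds.index else -1
            for t in transcripts["transcript_id"]]
        ex = df[df["Feature"] == "exon"]
        exons = pd.DataFrame({
            "transcript_id": ex["transcript_id"].to_numpy(),
            "chrom": ex["chrom"].astype(str).to_numpy(),
            "start": ex["start"].astype(int).to_numpy(),
            "end": ex["end"].astype(int).to_numpy(),
            "strand": ex["strand"].astype(str).to_numpy(),
        })
        order = transcripts.sort_values(["chrom", "start", "transcript_id"]).index
        transcripts = transcripts.loc[order].reset_index(drop=True)
        exons = exons.sort_values(["chrom", "start"]).reset_index(drop=True)
        return cls(transcripts=transcripts, exons=exons)

    def equals(self, other: "GeneModel") -> bool:
        a = self.transcripts.sort_values("transcript_id").reset_index(drop=True)
        b = other.transcripts.sort_values("transcript_id").reset_index(drop=True)
        ea = self.exons.sort_values(["transcript_id", "start"]).reset_index(drop=True)
        eb = other.exons.sort_values(["transcript_id", "start"]).reset_index(drop=True)
        return a[TRANSCRIPT_COLS].equals(b[TRANSCRIPT_COLS]) and \
            ea[EXON_COLS].equals(eb[EXON_COLS])
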