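"""Gene/transcript/exon annotation container with GTF round-trip.

Coordinates are stored 0-based half-open internally; GTF files are written
and read with the usual 1-based closed convention.  The hierarchy mirrors the
Ensembl gene -> transcript -> exon nesting used throughout the analysis: every
transcript interval is contained in its gene, every exon in its transcript,
and introns are the gaps between consecutive exons of a transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import pandas as pd

GENE_COLS = ["gene_id", "chrom", "start", "end"]
TX_COLS = ["transcript_id", "gene_id", "chrom", "start", "end"]
EXON_COLS = ["exon_id", "transcript_id", "gene_id", "chrom", "start", "end"]


@dataclass
class FeatureAnnotation:
    """Three interval tables sharing the 0-based half-open convention.

    ``exons`` may contain one row per (exon_id, transcript_id) membership, so
    an exon shared by several transcripts appears on several rows.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes[GENE_COLS].reset_index(drop=True)
        self.transcripts = self.transcripts[TX_COLS].reset_index(drop=True)
        self.exons = self.exons[EXON_COLS].reset_index(drop=True)

    def validate(self) -> None:
        """Raise if any feature escapes its parent interval."""
        tx = self.transcripts.merge(
            self.genes, on="gene_id", suffixes=("", "_gene"), validate="many_to_one"
        )
        bad = tx[(tx.start < tx.start_gene) | (tx.end > tx.end_gene) | (tx.chrom != tx.chrom_gene)]
        if len(bad):
            raise ValueError(f"transcripts escape gene span: {sorted(bad.transcript_id)[:5]}")
        ex = self.exons.merge(
            self.transcripts,
            on="transcript_id",
            suffixes=("", "_tx"),
            validate="many_to_one",
        )
        bad = ex[(ex.start < ex.start_tx) | (ex.end > ex.end_tx) | (ex.chrom != ex.chrom_tx)]
        if len(bad):
            raise ValueError(f"exons escape transcript span: {sorted(bad.exon_id)[:5]}")
        if (self.genes.start >= self.genes.end).any():
            raise ValueError("degenerate gene interval")

    def feature_table(self, level: str) -> pd.DataFrame:
        """Unique feature intervals for one level, with an id column ``feature_id``."""
        if level == "gene":
            df = self.genes.rename(columns={"gene_id": "feature_id"}).copy()
            df["gene_id"] = df.feature_id
            return df
        if level == "transcript":
            df = self.transcripts.rename(columns={"transcript_id": "feature_id"})
            return df[["feature_id", "gene_id", "chrom", "start", "end"]].copy()
        if level == "exon":
            df = self.exons.rename(columns={"exon_id": "feature_id"})
            return (
                df[["feature_id", "gene_id", "chrom", "start", "end"]]
                .drop_duplicates("feature_id")
                .reset_index(drop=True)
            )
        raise ValueError(f"unknown level: {level!r}")

    def gene_of_feature(self) -> dict[str, str]:
        """Map any feature id (gene, transcript or exon) to its gene id."""
        out = {g: g for g in self.genes.gene_id}
        out.update(dict(zip(self.transcripts.transcript_id, self.transcripts.gene_id)))
        out.update(dict(zip(self.exons.exon_id, self.exons.gene_id)))
        return out

    # ---------------------------------------------------------------- GTF IO

    def to_gtf(self, path) -> None:
        """Conventional interleaved layout: each gene followed by its
        transcripts and their exons."""
        tx_by_gene = dict(iter(self.transcripts.groupby("gene_id")))
        ex_by_tx = dict(iter(self.exons.groupby("transcript_id")))
        with open(path, "w") as fh:
            for _, g in self.genes.sort_values(["chrom", "start"]).iterrows():
                fh.write(_gtf_line(g.chrom, "gene", g.start, g.end, f'gene_id "{g.gene_id}";'))
                txs = tx_by_gene.get(g.gene_id)
                if txs is None:
                    continue
                for _, t in txs.sort_values(["start", "transcript_id"]).iterrows():
                    fh.write(
                        _gtf_line(
                            t.chrom,
                            "transcript",
                            t.start,
                            t.end,
                            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";',
                        )
                    )
                    exs = ex_by_tx.get(t.transcript_id)
                    if exs is None:
                        continue
                    for _, e in exs.sort_values(["start", "exon_id"]).iterrows():
                        fh.write(
                            _gtf_line(
                                e.chrom,
                                "exon",
                                e.start,
                                e.end,
                                f'gene_id "{e.gene_id}"; transcript_id "{e.transcript_id}"; '
                                f'exon_id "{e.exon_id}";',
                            )
                        )

    @classmethod
    def from_gtf(cls, path) -> "FeatureAnnotation":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes, txs, exons = [], [], []
        for f in db.features_of_type("gene"):
            genes.append((f.attributes["gene_id"][0], f.seqid, f.start - 1, f.end))
        for f in db.features_of_type("transcript"):
            txs.append(
                (f.attributes["transcript_id"][0], f.attributes["gene_id"][0], f.seqid, f.start - 1, f.end)
            )
        for f in db.features_of_type("exon"):
            exons.append(
                (
                    f.attributes["exon_id"][0],
                    f.attributes["transcript_id"][0],
                    f.attributes["gene_id"][0],
                    f.seqid,
                    f.start - 1,
                    f.end,
                )
            )
        return cls(
            genes=pd.DataFrame(genes, columns=GENE_COLS),
            transcripts=pd.DataFrame(txs, columns=TX_COLS),
            exons=pd.DataFrame(exons, columns=EXON_COLS),
        )


def _gtf_line(chrom, feature, start0, end, attrs) -> str:
    return f"{chrom}\tstemqtl\t{feature}\t{start0 + 1}\t{end}\t.\t+\t.\t{attrs}\n"
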