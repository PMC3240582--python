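"""Readers and writers for the standard text formats the pipeline exchanges.

FASTA/FASTQ go through Bio.SeqIO; GFF3 reading goes through gffutils.
WIG (fixedStep), BED and the tag-table TSVs are simple line formats written
directly.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Transcript, TransposonCopy

# ---------------------------------------------------------------- FASTA/FASTQ


def write_fasta(chromosomes: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Sequence[Tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs with constant 'I' quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------- GFF3


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """GFF3 export (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tflychip\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tflychip\tmRNA\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t"
                    f"ID={t.tx_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\tflychip\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={t.tx_id}.exon{i};Parent={t.tx_id}\n"
                    )
                if t.cds is not None:
                    fh.write(
                        f"{g.chrom}\tflychip\tCDS\t{t.cds[0] + 1}\t{t.cds[1]}\t.\t{g.strand}\t0\t"
                        f"ID={t.tx_id}.cds;Parent={t.tx_id}\n"
                    )


def read_gff3(path) -> List[GeneModel]:
    """Rebuild gene models from a GFF3 file via gffutils (in-memory DB)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA"):
            exons = tuple(sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon")))
            cds_feats = list(db.children(t, featuretype="CDS"))
            cds = None
            if cds_feats:
                cds = (min(c.start - 1 for c in cds_feats), max(c.end for c in cds_feats))
            transcripts.append(Transcript(t.id, t.start - 1, t.end, exons, cds))
        genes.append(GeneModel(g.id, g.seqid, g.strand, tuple(transcripts)))
    return genes


# ----------------------------------------------------------------------- BED


def write_bed6(copies: Iterable[TransposonCopy], path) -> None:
    with open(path, "w") as fh:
        for c in copies:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.family}\t0\t{c.strand}\n")


def read_bed6(path) -> List[TransposonCopy]:
    copies = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            copies.append(TransposonCopy(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return copies


def write_bed_regions(regions: pd.DataFrame, path, name_prefix: str = "region") -> None:
    """Write a chrom/start/end DataFrame as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, row in enumerate(regions.itertuples(index=False), 1):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name_prefix}{i}\n")


# ----------------------------------------------------------------------- WIG


def write_wig(scores: Dict[str, np.ndarray], path, bin_size: int = 50,
              track_name: str = "flychip") -> None:
    """fixedStep WIG output, one block per chromosome (1-based starts)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for chrom, arr in scores.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step={bin_size} span={bin_size}\n")
            fh.write("\n".join(f"{v:g}" for v in arr))
            fh.write("\n")


def read_wig(path) -> Tuple[Dict[str, np.ndarray], int]:
    """Read fixedStep WIG written by :func:`write_wig`; returns (scores, bin_size)."""
    scores: Dict[str, List[float]] = {}
    bin_size = 50
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                bin_size = int(fields.get("step", 50))
                current = scores.setdefault(fields["chrom"], [])
            else:
                current.append(float(line))
    return {c: np.asarray(v, dtype=float) for c, v in scores.items()}, bin_size


# ----------------------------------------------------------------- tag table


def write_tag_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tag_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
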