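"""File I/O: FASTA, GFF3, FASTQ, TSV and run manifests.

Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive, per the format.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import os
from typing import TYPE_CHECKING, Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import FeatureRecord


def _open_text(path, mode: str = "rt"):
    """Open a file, transparently decompressing ``.gz``."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


# ---------------------------------------------------------------- FASTQ


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write ``(read_id, sequence)`` pairs as Phred+33 FASTQ with constant quality."""
    buf = io.StringIO()
    for read_id, seq in reads:
        buf.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
    with _open_text(path, "wt") as handle:
        handle.write(buf.getvalue())


def read_fastq_sequences(path) -> Iterator[str]:
    """Yield read sequences (uppercased) from a FASTQ file, gzip-transparent."""
    with _open_text(path) as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq.upper()


# ---------------------------------------------------------------- GFF3

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(features: Iterable["FeatureRecord"], path) -> None:
    """Serialize features to GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for f in features:
        attrs = f"ID={f.feature_id}"
        if f.anticodon is not None:
            attrs += f";anticodon={f.anticodon}"
        lines.append(
            "\t".join(
                [
                    f.chrom,
                    "srnascape",
                    f.category,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    with _open_text(path, "wt") as handle:
        handle.write("\n".join(lines) + "\n")


def read_gff3(path) -> list["FeatureRecord"]:
    from .annotate import FeatureRecord

    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS, dtype={"seqid": str}
    )
    features = []
    for row in df.itertuples(index=False):
        attrs = dict(
            item.split("=", 1) for item in str(row.attributes).split(";") if "=" in item
        )
        features.append(
            FeatureRecord(
                feature_id=attrs["ID"],
                category=row.type,
                chrom=row.seqid,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
                anticodon=attrs.get("anticodon"),
            )
        )
    return features


# ---------------------------------------------------------------- TSV


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------- manifest


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(outdir, paths: Iterable[str]) -> dict[str, str]:
    """Map each relative output path to its content checksum."""
    return {p: sha256_file(os.path.join(outdir, p)) for p in sorted(paths)}
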