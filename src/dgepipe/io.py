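"""Readers and writers for the pipeline's text formats.

FASTA/FASTQ go through Biopython; tabular outputs are tab-separated with a
'#'-prefixed provenance header (tool version, config hash, seed) so that a
rerun with the same configuration is byte-identical and self-describing.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """Write (id, sequence, quality-string) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq), qual))
    return out


def provenance_header(seed: int, config_hash: str) -> str:
    return (
        f"# dgepipe {__version__}\n"
        f"# config_hash: {config_hash}\n"
        f"# seed: {seed}\n"
    )


def config_hash(config_dict: Mapping) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, seed: int, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, chash))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(df: pd.DataFrame, path, name_col: str = "feature_id") -> None:
    """BED6 (chrom, start, end, name, score, strand), 0-based half-open."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = getattr(row, name_col)
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[1]),
                    "end": int(f[2]),
                    "feature_id": f[3] if len(f) > 3 else ".",
                    "strand": f[5] if len(f) > 5 else "+",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_id", "strand"])


def write_tag_counts(counts: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for tag in sorted(counts):
            fh.write(f"{tag}\t{counts[tag]}\n")


def read_tag_counts(path) -> Counter:
    out: Counter = Counter()
    with open(path) as fh:
        next(fh)
        for line in fh:
            tag, count = line.rstrip("\n").split("\t")
            out[tag] = int(count)
    return out
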