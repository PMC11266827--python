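"""Format I/O and pre-processing shims.

FASTA/FASTQ through Biopython; interleaved-pair FASTA with /1 and /2 mate
suffixes (the input convention of comparative read clustering); hitsort and
cluster-membership TSVs (1-based read coordinates in reports).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from .graph import HitTable, RepeatCluster
from .synth import ReadSet


def _records(reads: ReadSet):
    for i in range(reads.n_reads):
        yield reads.read_id(i), _seq.decode(reads.seqs[i])


def write_fasta(reads: ReadSet, path) -> None:
    recs = (SeqRecord(Seq(s), id=rid, description="") for rid, s in _records(reads))
    SeqIO.write(recs, str(path), "fasta-2line")


def write_fastq(reads: ReadSet, path) -> None:
    """FASTQ with constant Sanger quality 'I' for every base."""
    with open(path, "w") as fh:
        for rid, s in _records(reads):
            fh.write(f"@{rid}\n{s}\n+\n{'I' * len(s)}\n")


def write_interleaved_fasta(reads: ReadSet, path) -> None:
    # reads are already mate-interleaved in a ReadSet
    write_fasta(reads, path)


def read_fasta_sequence(path) -> np.ndarray:
    """Concatenated sequence of all records in a FASTA file (reference use)."""
    parts = [_seq.encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not parts:
        raise ValueError(f"no sequences in {path}")
    return np.concatenate(parts)


def interleave_pairs(mates1: list[tuple[str, str]], mates2: list[tuple[str, str]],
                     sample_code: str = "") -> list[tuple[str, str]]:
    """Merge two mate lists [(id, seq), ...] into interleaved /1,/2 records.

    Ids must match between files after stripping any existing mate suffix.
    """
    if len(mates1) != len(mates2):
        raise ValueError("mate files differ in record count")
    out = []
    for (id1, s1), (id2, s2) in zip(mates1, mates2):
        base1 = id1.rsplit("/", 1)[0]
        base2 = id2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"orphan mates: {id1!r} vs {id2!r}")
        out.append((f"{sample_code}{base1}/1", s1))
        out.append((f"{sample_code}{base2}/2", s2))
    return out


def load_mates(path) -> list[tuple[str, str]]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def length_filter(reads: ReadSet, length: int = 101) -> ReadSet:
    """Keep pairs whose mates both reach ``length``; truncate longer reads.

    ReadSet matrices are fixed-width, so only truncation/pass-through can
    occur here; the record-level variant is ``length_filter_records``.
    """
    if reads.read_length < length:
        return reads.subset(np.empty(0, dtype=int))
    if reads.read_length == length:
        return reads
    out = reads.subset(np.arange(reads.n_reads))
    out.seqs = out.seqs[:, :length].copy()
    return out


def length_filter_records(records: list[tuple[str, str]],
                          length: int = 101) -> list[tuple[str, str]]:
    """Pair-aware MINLEN filter on interleaved (id, seq) records."""
    out = []
    for i in range(0, len(records) - 1, 2):
        (id1, s1), (id2, s2) = records[i], records[i + 1]
        if len(s1) >= length and len(s2) >= length:
            out.append((id1, s1[:length]))
            out.append((id2, s2[:length]))
    return out


def write_hitsort(hits: HitTable, reads: ReadSet, path) -> None:
    df = hits.to_dataframe(ids=reads.ids)
    df.to_csv(path, sep="\t", index=False)


def write_clusters(clusters: list[RepeatCluster], reads: ReadSet, path) -> None:
    rows = [(reads.read_id(int(m)), c.cluster_id)
            for c in clusters for m in c.members]
    pd.DataFrame(rows, columns=["read_id", "cluster_id"]).to_csv(
        path, sep="\t", index=False)


def write_truth(truth, path) -> None:
    rows = [{"family": f, "lineage": truth.lineages[f],
             "planted_bases": truth.planted_bases[f],
             "proportion": truth.planted_bases[f] / truth.holoploid_length}
            for f in truth.family_names]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
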