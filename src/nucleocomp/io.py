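"""Readers and writers for the standard text formats the pipeline touches.

FASTA and MAF go through Biopython; bedGraph, BED and TSV are plain tables
(pandas). GFF-style 1-based inclusive gene coordinates are converted to the
internal 0-based half-open convention at the boundary. All formats are
uncompressed text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .substitution import NT, AlignmentBlock, Tree

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NT):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def codes_to_str(codes: np.ndarray) -> str:
    chars = np.array(list(NT + "N"))
    idx = np.where(codes >= 0, codes, 4)
    return "".join(chars[idx])


def str_to_codes(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def write_fasta(path, sequences: dict[str, np.ndarray | str],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            s = seq if isinstance(seq, str) else codes_to_str(np.asarray(seq))
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    from Bio import SeqIO
    return {rec.id: str_to_codes(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def write_maf(path, block: AlignmentBlock, chrom: str = "chr1") -> None:
    L = block.length
    with open(path, "w") as fh:
        fh.write("##maf version=1\n\na score=0.0\n")
        for name, row in zip(block.leaf_names, block.seqs):
            fh.write(f"s {name}.{chrom} 0 {L} + {L} {codes_to_str(row)}\n")
        fh.write("\n")


def read_maf(path) -> AlignmentBlock:
    from Bio import AlignIO
    blocks = list(AlignIO.parse(str(path), "maf"))
    if not blocks:
        raise ValueError(f"no alignment blocks in {path}")
    names, chunks = None, []
    for aln in blocks:
        d = {rec.id.split(".")[0]: str(rec.seq) for rec in aln}
        if names is None:
            names = list(d)
        chunks.append(d)
    seqs = {n: "".join(c[n] for c in chunks) for n in names}
    return AlignmentBlock.from_strings(seqs)


def write_bedgraph(path, values: np.ndarray, chrom: str = "chr1") -> None:
    """Per-position track compressed into maximal constant runs."""
    v = np.asarray(values, dtype=float)
    breaks = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [v.size]))
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}"\n')
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")


def read_bedgraph(path, length: int | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="t", header=None,
                     names=["chrom", "start", "end", "value"])
    n = length or int(df["end"].max())
    out = np.full(n, np.nan)
    for _, row in df.iterrows():
        out[int(row.start):int(row.end)] = row.value
    return out


def write_bed(path, intervals, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            s, e = iv[0], iv[1]
            name = iv[2] if len(iv) > 2 else "."
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_bed(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[1, 2],
                     names=["start", "end"])
    return list(zip(df["start"].astype(int), df["end"].astype(int)))


def gff_to_intervals(path) -> list[tuple[int, int]]:
    """Exon intervals from a GFF file (1-based inclusive -> 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attr"])
    ex = df[df["type"].str.lower() == "exon"]
    return [(int(s) - 1, int(e)) for s, e in zip(ex["start"], ex["end"])]


def write_newick(path, tree: Tree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path) -> Tree:
    return Tree.from_newick(Path(path).read_text())


def save_world(outdir, truth, occupancy: np.ndarray | None = None,
               snps: pd.DataFrame | None = None,
               planted: pd.DataFrame | None = None) -> None:
    """Write a simulated world as FASTA/MAF/bedGraph/BED/TSV/Newick files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = truth.spec
    write_fasta(out / "nodes.fa", truth.node_seqs)
    write_maf(out / "leaves.maf", truth.block)
    write_newick(out / "tree.nwk", spec.tree)
    pd.DataFrame({"tss": spec.tss_positions}).to_csv(
        out / "tss.tsv", sep="\t", index=False)
    write_bed(out / "exons.bed", spec.exon_intervals)
    truth.events.to_csv(out / "events.tsv", sep="\t", index=False)
    if occupancy is not None:
        write_bedgraph(out / "occupancy.bedgraph", occupancy)
    if snps is not None:
        snps.to_csv(out / "snps.tsv", sep="\t", index=False)
    if planted is not None:
        planted.to_csv(out / "planted_pairs.tsv", sep="\t", index=False)
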