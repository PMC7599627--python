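"""Readers and writers for the pipeline's plain-text formats.

Coordinate conventions: depth TSVs are 1-based (samtools-depth dialect);
PAF, LASTZ-general, BED and all internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sexlink import DepthTrack, ScaffoldCall, WindowStat
from .strata import AlignmentBlock, SimilarityWindow, StratumAnnotation


class InputError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_depth_tsv(path) -> dict[str, DepthTrack]:
    """samtools-depth TSV (scaffold, 1-based position, depth) -> tracks."""
    scaffolds: dict[str, tuple[list[int], list[int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}:{ln}: expected 3 tab-separated columns")
            sid, pos_s, depth_s = parts
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError:
                raise InputError(f"{path}:{ln}: non-integer position or depth") from None
            if depth < 0:
                raise InputError(f"{path}:{ln}: negative depth")
            positions, depths = scaffolds.setdefault(sid, ([], []))
            if positions and pos <= positions[-1]:
                raise InputError(f"{path}:{ln}: positions not strictly increasing")
            positions.append(pos)
            depths.append(depth)
    return {
        sid: DepthTrack(sid, np.array(p, dtype=np.int64), np.array(d, dtype=np.int64))
        for sid, (p, d) in scaffolds.items()
    }


def write_depth_tsv(path, tracks: dict[str, DepthTrack]) -> None:
    with open(path, "w") as fh:
        for sid in tracks:
            t = tracks[sid]
            for pos, depth in zip(t.positions, t.depth):
                fh.write(f"{sid}\t{pos}\t{depth}\n")


def read_alignments(path, dialect: str = "paf") -> list[AlignmentBlock]:
    """PAF or LASTZ-general alignment table -> blocks in Z coordinates.

    PAF: query = W sequence, target = Z (columns 1-12); identity =
    matches / alignment block length (cols 10/11), aligned fraction =
    query span / query length. LASTZ general dialect: name1 start1 end1
    name2 start2 end2 identity_frac length — name1 is the Z.
    """
    blocks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if dialect == "paf":
                    if len(f) < 12:
                        raise InputError(f"{path}:{ln}: PAF needs >= 12 columns")
                    qlen, qs, qe = int(f[1]), int(f[2]), int(f[3])
                    ts, te = int(f[7]), int(f[8])
                    matches, blocklen = int(f[9]), int(f[10])
                    if ts >= te or qs >= qe or ts < 0 or qs < 0:
                        raise InputError(f"{path}:{ln}: inverted or negative coordinates")
                    blocks.append(
                        AlignmentBlock(
                            z_scaffold=f[5], z_start=ts, z_end=te,
                            w_scaffold=f[0], aligned_length=blocklen,
                            matches=matches, aligned_fraction=(qe - qs) / qlen,
                        )
                    )
                elif dialect == "lastz_general":
                    if len(f) < 8:
                        raise InputError(f"{path}:{ln}: LASTZ general needs 8 columns")
                    name1, s1, e1, name2, s2, e2, ident_s, length_s = f[:8]
                    s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
                    if s1 >= e1 or s1 < 0:
                        raise InputError(f"{path}:{ln}: inverted or negative coordinates")
                    ident = float(ident_s.rstrip("%")) / 100 if ident_s.endswith("%") else float(ident_s)
                    length = int(length_s)
                    blocks.append(
                        AlignmentBlock(
                            z_scaffold=name1, z_start=s1, z_end=e1,
                            w_scaffold=name2, aligned_length=length,
                            matches=int(round(ident * length)),
                            aligned_fraction=min(1.0, length / max(1, e2 - s2)),
                        )
                    )
                else:
                    raise InputError(f"unknown alignment dialect: {dialect}")
            except InputError:
                raise
            except ValueError:
                raise InputError(f"{path}:{ln}: malformed numeric field") from None
    return blocks


def write_scaffold_calls(path, calls: Sequence[ScaffoldCall]) -> None:
    df = pd.DataFrame(
        [
            {
                "scaffold_id": c.scaffold_id,
                "relative_depth": c.relative_depth,
                "z_aligned_fraction": c.z_aligned_fraction,
                "label": c.label,
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bed(path, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    """BED (0-based half-open): (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise InputError(f"{path}:{ln}: BED needs >= 3 columns")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


def write_similarity_windows(path, windows: Sequence[SimilarityWindow], z_scaffold="Z") -> None:
    df = pd.DataFrame(
        [
            {
                "z_scaffold": z_scaffold,
                "z_start": w.z_start,
                "z_end": w.z_end,
                "mean_identity": w.mean_identity,
                "aligned_bp": w.aligned_bp,
            }
            for w in windows
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_strata_bed(path, strata: Sequence[StratumAnnotation], z_scaffold="Z") -> None:
    write_bed(path, [(z_scaffold, s.z_start, s.z_end, s.label) for s in strata])


def read_expression_tsv(path) -> pd.DataFrame:
    """TPM matrix: gene_id index, tissue_sex(_replicate) columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise InputError(f"{path}: negative TPM value")
    return df


def write_expression_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[str]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
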