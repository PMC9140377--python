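"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython (tolerant of wrapping and mixed case), Newick via the
tree layer, TSV tables via pandas, plus the flat key=value config format
used by the command-line tools. All errors name the offending record or
line.
"""

from __future__ import annotations

import io as _io
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .alignment import CodingAlignment
from .phylo import Phylogeny


def read_fasta(path, coding_map=()) -> CodingAlignment:
    """Read an aligned multi-FASTA into a CodingAlignment."""
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    length = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != length:
            raise ValueError(
                f"record {rid!r} has length {len(s)}, expected {length} "
                f"(alignment must be flush)"
            )
    return CodingAlignment(tuple(ids), tuple(seqs), tuple(coding_map))


def fasta_string(aln: CodingAlignment, width: int = 70) -> str:
    buf = _io.StringIO()
    for rid, seq in zip(aln.ids, aln.seqs):
        buf.write(f">{rid}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()


def write_fasta(aln: CodingAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(fasta_string(aln, width))


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def write_newick(t: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(t.to_newick() + "\n")


def read_tsv_points(path) -> pd.DataFrame:
    """Read a tab-separated table with a mandatory header row."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty table: {path}")
    return df


def read_config(path) -> dict[str, str]:
    """Flat key=value config; '#' starts a comment; blank lines ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(
                    f"{path}:{ln}: expected key=value, got {raw.strip()!r}"
                )
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        for key in cfg:
            fh.write(f"{key}={cfg[key]}\n")
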