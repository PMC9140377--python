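"""Coding-aware alignment container and genetic-code machinery.

Coordinates are 0-based, half-open. A coding interval is a tuple
``(start, end, frame, code_id)`` where ``frame`` is the offset of codon
position 1 within the interval (sites before the first complete codon, and
any trailing partial codon, are treated as non-coding) and ``code_id`` is an
NCBI translation-table id (2 = vertebrate mitochondrial, the default
throughout this package). Only the forward strand is modelled: the simulator
defines the reference orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
GAP = "-"

#: byte -> base index (A=0, C=1, G=2, T=3); anything else (gaps, ambiguity
#: codes) maps to -1 and is treated as missing.
ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    ENCODE[ord(_b)] = _i
    ENCODE[ord(_b.lower())] = _i

DEFAULT_CODE_ID = 2  # vertebrate mitochondrial


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 indices (-1 for gap/ambiguous)."""
    return ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(arr: np.ndarray) -> str:
    out = np.full(arr.shape, ord(GAP), dtype=np.uint8)
    valid = arr >= 0
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    out[valid] = lut[arr[valid]]
    return out.tobytes().decode("ascii")


def is_transition(a: str, b: str) -> bool:
    """A<->G and C<->T exchanges are transitions."""
    if a == b:
        raise ValueError("identical bases are not a substitution")
    return {a, b} in ({"A", "G"}, {"C", "T"})


@lru_cache(maxsize=None)
def genetic_code(code_id: int) -> dict[str, str]:
    """Codon -> amino acid (one letter, '*' for stop) for an NCBI table id."""
    try:
        table = CodonTable.unambiguous_dna_by_id[code_id]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id: {code_id}") from exc
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = "*"
    return code


@lru_cache(maxsize=None)
def aa_table(code_id: int) -> np.ndarray:
    """(4,4,4) array of amino-acid bytes indexed by codon base indices."""
    code = genetic_code(code_id)
    out = np.zeros((4, 4, 4), dtype=np.uint8)
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            for k, c in enumerate(BASES):
                out[i, j, k] = ord(code[a + b + c])
    return out


def normalize_coding_map(
    coding_map: Iterable[Sequence[int]] | None, length: int
) -> tuple[tuple[int, int, int, int], ...]:
    """Validate and normalize a coding map to 4-tuples.

    Entries may be (start, end), (start, end, frame) or
    (start, end, frame, code_id); missing fields default to frame 0 and the
    vertebrate mitochondrial code.
    """
    if not coding_map:
        return ()
    norm: list[tuple[int, int, int, int]] = []
    for entry in coding_map:
        entry = tuple(int(x) for x in entry)
        if len(entry) == 2:
            entry = entry + (0, DEFAULT_CODE_ID)
        elif len(entry) == 3:
            entry = entry + (DEFAULT_CODE_ID,)
        elif len(entry) != 4:
            raise ValueError(f"coding interval must have 2-4 fields: {entry!r}")
        start, end, frame, code_id = entry
        if not (0 <= start < end <= length):
            raise ValueError(
                f"coding interval ({start}, {end}) outside [0, {length})"
            )
        if frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
        genetic_code(code_id)  # raises on unknown id
        norm.append((start, end, frame, code_id))
    norm.sort()
    for (s1, e1, *_), (s2, _e2, *_) in zip(norm, norm[1:]):
        if s2 < e1:
            raise ValueError(
                f"coding intervals overlap: [{s1}, {e1}) and [{s2}, ...)"
            )
    return tuple(norm)


@dataclass(frozen=True)
class SiteTables:
    """Per-column lookup tables derived from a coding map.

    ``codon_col0[i]`` is the alignment column of codon position 1 of the
    codon containing column i (-1 for non-coding columns), ``codon_pos[i]``
    its 0-based position within the codon, and ``code_id[i]`` the genetic
    code in force there.
    """

    length: int
    codon_col0: np.ndarray
    codon_pos: np.ndarray
    code_id: np.ndarray

    @property
    def coding_mask(self) -> np.ndarray:
        return self.codon_col0 >= 0

    def codon_columns(self, column: int) -> tuple[int, int, int]:
        c0 = int(self.codon_col0[column])
        if c0 < 0:
            raise ValueError(f"column {column} is not in a complete codon")
        return (c0, c0 + 1, c0 + 2)


def build_site_tables(
    length: int, coding_map: Iterable[Sequence[int]] | None
) -> SiteTables:
    cmap = normalize_coding_map(coding_map, length)
    codon_col0 = np.full(length, -1, dtype=np.int64)
    codon_pos = np.full(length, -1, dtype=np.int8)
    code_arr = np.zeros(length, dtype=np.int64)
    for start, end, frame, code_id in cmap:
        first = start + frame
        n_codons = (end - first) // 3
        for c in range(n_codons):
            c0 = first + 3 * c
            codon_col0[c0 : c0 + 3] = c0
            codon_pos[c0 : c0 + 3] = (0, 1, 2)
            code_arr[c0 : c0 + 3] = code_id
    return SiteTables(length, codon_col0, codon_pos, code_arr)


@dataclass(frozen=True)
class CodingAlignment:
    """An aligned set of nucleotide sequences with coding annotation.

    Invariants: ids are unique, all sequences have equal length, the coding
    map is valid for that length.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    coding_map: tuple[tuple[int, int, int, int], ...] = ()
    _tables: SiteTables | None = field(
        default=None, repr=False, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in number")
        if not self.ids:
            raise ValueError("alignment is empty")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        length = len(self.seqs[0])
        for rid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise ValueError(
                    f"record {rid!r} has length {len(seq)}, expected {length}"
                )
        object.__setattr__(
            self, "coding_map", normalize_coding_map(self.coding_map, length)
        )
        object.__setattr__(
            self, "seqs", tuple(s.upper() for s in self.seqs)
        )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, rid: str) -> str:
        try:
            return self.seqs[self.ids.index(rid)]
        except ValueError as exc:
            raise KeyError(f"no record {rid!r} in alignment") from exc

    def matrix(self) -> np.ndarray:
        """(n, length) int8 matrix; -1 marks gaps/ambiguity."""
        return np.stack([encode_sequence(s) for s in self.seqs])

    def tables(self) -> SiteTables:
        tab = self._tables
        if tab is None:
            tab = build_site_tables(self.length, self.coding_map)
            object.__setattr__(self, "_tables", tab)
        return tab

    def subset(self, ids: Sequence[str]) -> "CodingAlignment":
        seqs = tuple(self.get(r) for r in ids)
        return CodingAlignment(tuple(ids), seqs, self.coding_map)

    @staticmethod
    def concat(*alignments: "CodingAlignment") -> "CodingAlignment":
        """Join alignments over the same columns (e.g. mtDNA + NUMT sets)."""
        first = alignments[0]
        ids: list[str] = []
        seqs: list[str] = []
        for aln in alignments:
            if aln.length != first.length:
                raise ValueError("alignments have different column counts")
            ids.extend(aln.ids)
            seqs.extend(aln.seqs)
        return CodingAlignment(tuple(ids), tuple(seqs), first.coding_map)
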