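"""Ancestral reconstruction and branch-wise mutation classification.

Maps substitutions onto the branches of a joint NUMT/mtDNA tree by Fitch
parsimony, classifies each as synonymous / non-synonymous / non-coding under
the alignment's genetic code (vertebrate mitochondrial by default), and
tests the diagnostic contrast: stem mutations of a true NUMT are
mitochondrial-like (synonymous-rich) while post-insertion branch mutations
are not.

Fitch tie-breaking is deterministic: on the final pass a node takes its
parent's state when that state is in its candidate set, otherwise the
alphabetically first candidate; the gap character is carried as a fifth
state but never overrides a nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import fisher_exact, hypergeom

from .alignment import BASES, CodingAlignment, genetic_code
from .phylo import Node, Phylogeny

#: state bits: A=1, C=2, G=4, T=8, gap=16; other ambiguity = missing (any base)
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 16}
_NUC_MASK = 15
_BIT_TO_CHAR = {1: "A", 2: "C", 4: "G", 8: "T", 16: "-"}


def _seq_bits(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        out[i] = _BIT.get(ch, _NUC_MASK)  # ambiguity codes = missing
    return out


def _bits_to_seq(bits: np.ndarray) -> str:
    return "".join(_BIT_TO_CHAR[int(b)] for b in bits)


def fitch_sets(t: Phylogeny, aln: CodingAlignment) -> dict[Node, np.ndarray]:
    """Fitch up-pass: candidate state sets (bitmasks) for every node."""
    sets: dict[Node, np.ndarray] = {}
    for node in t.postorder():
        if node.is_leaf:
            try:
                sets[node] = _seq_bits(aln.get(node.name))
            except KeyError as exc:
                raise ValueError(
                    f"leaf {node.name!r} has no sequence in the alignment"
                ) from exc
        else:
            acc = sets[node.children[0]].copy()
            union = acc.copy()
            for child in node.children[1:]:
                acc &= sets[child]
                union |= sets[child]
            sets[node] = np.where(acc != 0, acc, union)
    return sets


def fitch_score(t: Phylogeny, aln: CodingAlignment) -> int:
    """Minimum number of state changes over the tree (sum over columns)."""
    score = 0
    sets: dict[Node, np.ndarray] = {}
    for node in t.postorder():
        if node.is_leaf:
            sets[node] = _seq_bits(aln.get(node.name))
        else:
            acc = sets[node.children[0]].copy()
            for child in node.children[1:]:
                inter = acc & sets[child]
                empty = inter == 0
                score += int(np.count_nonzero(empty))
                acc = np.where(empty, acc | sets[child], inter)
            sets[node] = acc
    return score


def _choose_state(candidates: np.ndarray,
                  parent_state: np.ndarray | None) -> np.ndarray:
    """Resolve candidate sets to single states (vectorized over columns)."""
    nuc = candidates & _NUC_MASK
    cand = np.where(nuc != 0, nuc, candidates)  # gap never overrides a base
    if parent_state is not None:
        keep = (cand & parent_state) != 0
    else:
        keep = np.zeros(cand.shape, dtype=bool)
    lowest = (cand & (-cand.astype(np.int16))).astype(np.uint8)
    return np.where(keep, parent_state, lowest)


def reconstruct_ancestors(t: Phylogeny, aln: CodingAlignment) -> Phylogeny:
    """Fitch parsimony ancestral sequences on a copy of the tree.

    Leaves keep their aligned sequences; every internal node receives a
    reconstructed sequence. Internal nodes without names get stable
    auto-assigned ones so branches can be keyed by child-node name.
    """
    t = t.copy()
    t.assign_internal_names()
    sets = fitch_sets(t, aln)
    for node in t.preorder():
        if node.is_leaf:
            node.sequence = aln.get(node.name)
            continue
        parent_bits = (
            None
            if node.parent is None
            else _seq_bits(node.parent.sequence)
        )
        node.sequence = _bits_to_seq(_choose_state(sets[node], parent_bits))
    return t


# ---------------------------------------------------------------------------
# mutation records


@dataclass(frozen=True)
class Mutation:
    branch: str
    column: int
    from_base: str
    to_base: str
    klass: str  # synonymous | non_synonymous | non_coding


@dataclass
class BranchMutationSet:
    """Per-branch inferred substitutions, keyed by child-node name."""

    by_branch: dict[str, list[Mutation]] = field(default_factory=dict)

    def branches(self) -> list[str]:
        return list(self.by_branch)

    def __getitem__(self, branch: str) -> list[Mutation]:
        return self.by_branch[branch]

    def slice(self, branches: Iterable[str]) -> "BranchMutationSet":
        return BranchMutationSet(
            {b: self.by_branch[b] for b in branches if b in self.by_branch}
        )

    def all_mutations(self) -> list[Mutation]:
        return [m for muts in self.by_branch.values() for m in muts]

    def counts(self) -> dict[str, int]:
        out = {"synonymous": 0, "non_synonymous": 0, "non_coding": 0}
        for m in self.all_mutations():
            out[m.klass] += 1
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("branch_id\tcolumn\tfrom\tto\tclass\n")
            for branch in self.by_branch:
                for m in self.by_branch[branch]:
                    fh.write(
                        f"{m.branch}\t{m.column}\t{m.from_base}\t"
                        f"{m.to_base}\t{m.klass}\n"
                    )


def classify_mutation(
    column: int,
    from_base: str,
    to_base: str,
    codon_context: tuple[str, int] | None,
    code_id: int = 2,
) -> str:
    """Classify one substitution against its parent codon background.

    ``codon_context`` is ``(codon, position)`` with the parent's full codon
    and the 0-based codon position of ``column``; ``None`` marks a
    non-coding column. Synonymous means the encoded amino acid (stop
    included) is unchanged under ``code_id``.
    """
    if codon_context is None:
        return "non_coding"
    codon, pos = codon_context
    codon = codon.upper()
    if len(codon) != 3 or pos not in (0, 1, 2):
        raise ValueError(f"invalid codon context ({codon!r}, {pos})")
    if any(b not in BASES for b in codon) or to_base not in BASES:
        raise ValueError(
            f"column {column}: codon {codon!r} is not resolvable to bases"
        )
    if codon[pos] != from_base:
        raise ValueError(
            f"column {column}: codon position {pos} holds {codon[pos]!r}, "
            f"not the ancestral base {from_base!r}"
        )
    code = genetic_code(code_id)
    new = codon[:pos] + to_base + codon[pos + 1 :]
    return "synonymous" if code[codon] == code[new] else "non_synonymous"


def assign_branch_mutations(
    t: Phylogeny, aln: CodingAlignment
) -> BranchMutationSet:
    """One mutation record per branch and column where parent != child.

    Requires ancestral sequences (see :func:`reconstruct_ancestors`).
    Mutations are classified against the parent's codon progressively
    updated by earlier mutations on the same branch (document order), so
    multi-hit codons are handled deterministically. Columns where either
    endpoint is a gap or ambiguous are skipped; codons that cannot be
    translated (gap inside) yield non-coding records.
    """
    tab = aln.tables()
    out = BranchMutationSet()
    for node in t.preorder():
        if node.parent is None:
            continue
        if node.parent.sequence is None or node.sequence is None:
            raise ValueError(
                "tree lacks ancestral sequences; run reconstruct_ancestors"
            )
        ps, cs = node.parent.sequence, node.sequence
        muts: list[Mutation] = []
        applied: dict[int, str] = {}
        for col in range(aln.length):
            a, b = ps[col], cs[col]
            if a == b or a not in BASES or b not in BASES:
                continue
            c0 = int(tab.codon_col0[col])
            if c0 < 0:
                klass = "non_coding"
            else:
                codon = "".join(
                    applied.get(c, ps[c]) for c in (c0, c0 + 1, c0 + 2)
                )
                if any(x not in BASES for x in codon):
                    klass = "non_coding"
                else:
                    klass = classify_mutation(
                        col, codon[col - c0], b,
                        (codon, col - c0), int(tab.code_id[col]),
                    )
            muts.append(Mutation(str(node.name), col, a, b, klass))
            applied[col] = b
        out.by_branch[str(node.name)] = muts
    return out


# ---------------------------------------------------------------------------
# stem-vs-branches contrast


@dataclass(frozen=True)
class ContrastResult:
    syn_fraction_stem: float
    syn_fraction_others: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def _coding_counts(muts: Iterable[Mutation]) -> tuple[int, int]:
    syn = nonsyn = 0
    for m in muts:
        if m.klass == "synonymous":
            syn += 1
        elif m.klass == "non_synonymous":
            nonsyn += 1
    return syn, nonsyn


def stem_contrast_test(
    stem: BranchMutationSet | Iterable[Mutation],
    others: BranchMutationSet | Iterable[Mutation],
) -> ContrastResult:
    """One-sided Fisher exact test: is the stem more synonymous?

    Builds the 2x2 table (synonymous vs non-synonymous) x (stem vs other
    branches), excluding non-coding records, and tests the alternative that
    the stem's synonymous fraction is higher — the signature of stem
    evolution inside a functional mitochondrial genome. A table with an
    empty margin (e.g. no non-synonymous changes anywhere) is flagged
    degenerate with p = 1.
    """
    if isinstance(stem, BranchMutationSet):
        stem = stem.all_mutations()
    if isinstance(others, BranchMutationSet):
        others = others.all_mutations()
    s_syn, s_non = _coding_counts(stem)
    o_syn, o_non = _coding_counts(others)
    if s_syn + s_non == 0 or o_syn + o_non == 0:
        raise ValueError(
            "stem contrast needs at least one coding-region mutation in "
            "each slice; fully non-coding (e.g. rRNA-homologous) NUMTs are "
            "not apt for this test"
        )
    table = ((s_syn, s_non), (o_syn, o_non))
    f_stem = s_syn / (s_syn + s_non)
    f_oth = o_syn / (o_syn + o_non)
    if s_syn + o_syn == 0 or s_non + o_non == 0:
        return ContrastResult(f_stem, f_oth, 1.0, table, degenerate=True)
    _, p = fisher_exact(np.array(table), alternative="greater")
    return ContrastResult(f_stem, f_oth, float(p), table)


def hypergeom_tail_p(table) -> float:
    """Direct hypergeometric tail sum for the one-sided Fisher test.

    Independent closed-form route used to validate the Fisher p-value:
    P(X >= stem_syn) with X ~ Hypergeom(N = all coding mutations,
    K = all synonymous, n = stem size).
    """
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + c, a + b
    return float(hypergeom.sf(a - 1, N, K, n))
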