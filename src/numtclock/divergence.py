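"""Delete-d jackknife divergence estimation on a fixed topology.

The stem of a NUMT clade is a single branch of the joint NUMT/mtDNA tree;
its length is the divergence the NUMT precursor accumulated before
insertion. To put an uncertainty on that length, each jackknife replicate
drops a fixed fraction of alignment columns at random (without replacement,
a true delete-d jackknife), recomputes all pairwise model-corrected
distances, re-fits branch lengths on the fixed topology by non-negative
least squares, and records the statistic of interest. The spread of the
replicate estimates is the reported uncertainty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .alignment import CodingAlignment
from .phylo import (
    Node,
    Phylogeny,
    SaturationError,
    UnrootedEdges,
    _distance_from_counts,
    fit_branch_lengths,
)

#: a statistic maps the (re-fitted) working tree and its unrooted edge set
#: to a scalar in substitutions/site
Statistic = Callable[[Phylogeny, UnrootedEdges], float]


@dataclass
class JackknifeDistribution:
    """Replicate estimates of one divergence statistic.

    Estimates are in substitutions/site; ``mean_percent``/``sd_percent``
    give the "% divergence" scale. ``correction_factor`` records a
    mitochondrial-fraction correction if one was applied.
    """

    replicate_estimates: np.ndarray
    delete_fraction: float
    model: str
    statistic: str = ""
    correction_factor: float | None = None
    n_excluded: int = 0

    def __post_init__(self):
        self.replicate_estimates = np.asarray(
            self.replicate_estimates, dtype=float
        )
        if not (0.0 <= self.delete_fraction < 1.0):
            raise ValueError("delete_fraction must lie in [0, 1)")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_estimates)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_estimates))

    @property
    def sd(self) -> float:
        if self.n_replicates < 2:
            return 0.0
        return float(np.std(self.replicate_estimates, ddof=1))

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean

    @property
    def sd_percent(self) -> float:
        return 100.0 * self.sd

    def scaled(self, factor: float, note: float | None = None
               ) -> "JackknifeDistribution":
        return JackknifeDistribution(
            self.replicate_estimates * factor,
            self.delete_fraction,
            self.model,
            statistic=self.statistic,
            correction_factor=note if note is not None else factor,
            n_excluded=self.n_excluded,
        )

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "mean": self.mean,
            "sd": self.sd,
            "mean_percent": self.mean_percent,
            "sd_percent": self.sd_percent,
            "n_replicates": self.n_replicates,
            "n_excluded": self.n_excluded,
            "delete_fraction": self.delete_fraction,
            "model": self.model,
            "correction_factor": self.correction_factor,
        }

    def to_json(self, indent: int = 2) -> str:
        d = self.summary()
        d["replicate_estimates"] = [
            float(x) for x in self.replicate_estimates
        ]
        return json.dumps(d, indent=indent, sort_keys=True)


# ---------------------------------------------------------------------------
# statistic factories


def branch_length_stat(side: frozenset[str] | set[str]) -> Statistic:
    """Length of the unrooted edge with the given leaf-set bipartition."""
    side = frozenset(side)

    def stat(tree: Phylogeny, edges: UnrootedEdges) -> float:
        k = edges.index_of(side)
        return float(edges.lengths()[k])

    return stat


def taxon_divergence_stat(leaf: str, sisters: Sequence[str]) -> Statistic:
    """Divergence of ``leaf`` from its common ancestor with ``sisters``.

    This is the Fig-2-style per-taxon reference statistic: e.g. Homo from
    its common ancestor with Pan, or one Pan species from the ancestor it
    shares with its congener.
    """
    group = set(sisters) | {leaf}

    def stat(tree: Phylogeny, edges: UnrootedEdges) -> float:
        return float(tree.path_length(leaf, tree.mrca(sorted(group))))

    return stat


# ---------------------------------------------------------------------------
# the resampler


def jackknife_statistics(
    aln: CodingAlignment,
    topology: Phylogeny,
    stats: Mapping[str, Statistic],
    n_replicates: int = 1000,
    delete_fraction: float = 0.5,
    model: str = "k80",
    seed: int = 0,
    max_excluded: float = 0.2,
) -> dict[str, JackknifeDistribution]:
    """Jointly jackknife any number of statistics of the fitted tree.

    The topology is held fixed; only branch lengths are re-fitted per
    replicate. Replicates where any pairwise distance saturates are
    excluded and counted; more than ``max_excluded`` of them is an error.
    Identical seeds give identical distributions.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    work = topology.copy()
    leaf_order = work.leaf_names()
    missing = [l for l in leaf_order if l not in aln.ids]
    if missing:
        raise ValueError(f"alignment lacks sequences for leaves: {missing}")
    M = aln.subset(leaf_order).matrix()
    n = len(leaf_order)
    L = aln.length
    keep = L if delete_fraction == 0.0 else int(
        round((1.0 - delete_fraction) * L)
    )
    if keep < 1:
        raise ValueError("delete_fraction leaves no columns")

    edges = UnrootedEdges(work)
    A = edges.design_matrix(leaf_order)
    rng = np.random.default_rng(seed)
    results: dict[str, list[float]] = {name: [] for name in stats}
    n_excluded = 0

    for _ in range(n_replicates):
        if delete_fraction == 0.0:
            sub = M
        else:
            cols = rng.choice(L, size=keep, replace=False)
            sub = M[:, cols]
        D = np.zeros((n, n))
        try:
            valid = sub >= 0
            for i in range(n):
                for j in range(i + 1, n):
                    both = valid[i] & valid[j]
                    a, b = sub[i][both], sub[j][both]
                    diff = a != b
                    ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
                    tv = int(np.count_nonzero(diff)) - ts
                    ncomp = int(both.sum())
                    if ncomp == 0:
                        raise SaturationError("no comparable columns")
                    D[i, j] = D[j, i] = _distance_from_counts(
                        ncomp, ts, tv, model
                    )
        except SaturationError:
            n_excluded += 1
            continue
        fit_branch_lengths(edges, D, leaf_order, A)
        for name, stat in stats.items():
            results[name].append(stat(work, edges))

    if n_excluded > max_excluded * n_replicates:
        raise RuntimeError(
            f"{n_excluded}/{n_replicates} jackknife replicates saturated "
            f"(> {max_excluded:.0%}); the alignment is too diverged for "
            f"model {model!r}"
        )
    return {
        name: JackknifeDistribution(
            np.array(vals),
            delete_fraction,
            model,
            statistic=name,
            n_excluded=n_excluded,
        )
        for name, vals in results.items()
    }


def _resolve_bipartition(topology: Phylogeny, target_branch) -> frozenset:
    if isinstance(target_branch, Node):
        return topology.leafset(target_branch)
    if isinstance(target_branch, str):
        return topology.leafset(topology.find(target_branch))
    return frozenset(target_branch)


def jackknife_divergence(
    aln: CodingAlignment,
    topology: Phylogeny,
    target_branch,
    n_replicates: int = 1000,
    delete_fraction: float = 0.5,
    model: str = "k80",
    seed: int = 0,
) -> JackknifeDistribution:
    """Jackknife distribution of one branch length of the fixed topology.

    ``target_branch`` may be a node, a node name, or a leaf-label set
    giving the branch's bipartition (e.g. the NUMT clade for the stem).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    side = _resolve_bipartition(topology, target_branch)
    out = jackknife_statistics(
        aln,
        topology,
        {"branch_length": branch_length_stat(side)},
        n_replicates=n_replicates,
        delete_fraction=delete_fraction,
        model=model,
        seed=seed,
    )
    dist = out["branch_length"]
    dist.statistic = f"branch[{'|'.join(sorted(side))}]"
    return dist


def full_data_estimate(
    aln: CodingAlignment,
    topology: Phylogeny,
    target_branch,
    model: str = "k80",
) -> float:
    """The keep-all-columns estimate of a branch length (no resampling)."""
    side = _resolve_bipartition(topology, target_branch)
    out = jackknife_statistics(
        aln,
        topology,
        {"x": branch_length_stat(side)},
        n_replicates=1,
        delete_fraction=0.0,
        model=model,
    )
    return out["x"].mean


# ---------------------------------------------------------------------------
# correction and taxonomic placement


def correct_stem_divergence(raw, mito_fraction: float):
    """Scale a raw stem divergence by its mitochondrial-phase fraction.

    Part of an observed NUMT stem accrues after insertion (at the nuclear
    rate) and before the first split of the orthologs; only the
    mitochondrial fraction dates the precursor's divergence. The classic
    reference setting for the ps5 locus is 0.75. Accepts a scalar or a
    :class:`JackknifeDistribution` (scaled elementwise).
    """
    if not (0.0 <= mito_fraction <= 1.0):
        raise ValueError(f"mito_fraction must lie in [0, 1]: {mito_fraction}")
    if isinstance(raw, JackknifeDistribution):
        return raw.scaled(mito_fraction)
    return raw * mito_fraction


def classify_divergence(
    stem: JackknifeDistribution,
    congeneric_refs: Sequence[JackknifeDistribution],
    intergeneric_refs: Sequence[JackknifeDistribution],
) -> tuple[str, dict]:
    """Place a stem divergence against reference taxon divergences.

    Compares the stem mean with the congeneric (within-genus) and
    intergeneric reference divergences: ``intermediate`` means strictly
    between the largest congeneric and smallest intergeneric mean — the
    hallmark of a precursor from a distinct, now-extinct species. Overlap
    fractions (share of stem replicates inside each reference's range) are
    reported alongside.
    """
    if not congeneric_refs or not intergeneric_refs:
        raise ValueError("need at least one reference of each class")
    s = stem.mean
    con = [r.mean for r in congeneric_refs]
    inter = [r.mean for r in intergeneric_refs]

    if s <= min(con):
        category = "within_reference"
    elif s <= max(con):
        category = "congeneric_level"
    elif s < min(inter):
        category = "intermediate"
    elif s <= max(inter):
        category = "intergeneric_level"
    else:
        category = "beyond"

    def overlap(ref: JackknifeDistribution) -> float:
        lo = float(np.min(ref.replicate_estimates))
        hi = float(np.max(ref.replicate_estimates))
        x = stem.replicate_estimates
        return float(np.mean((x >= lo) & (x <= hi)))

    details = {
        "stem_mean": s,
        "congeneric_means": con,
        "intergeneric_means": inter,
        "overlap_congeneric": [overlap(r) for r in congeneric_refs],
        "overlap_intergeneric": [overlap(r) for r in intergeneric_refs],
    }
    return category, details


# ---------------------------------------------------------------------------
# plotting


def plot_jackknife_densities(
    dists: Mapping[str, JackknifeDistribution],
    path,
    percent: bool = True,
    title: str = "Jackknife divergence distributions",
) -> None:
    """Density curves of jackknife estimates, one per taxon/stem."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, dist in dists.items():
        x = dist.replicate_estimates * (100.0 if percent else 1.0)
        if np.ptp(x) < 1e-12:
            ax.axvline(float(np.mean(x)), label=name)
            continue
        kde = gaussian_kde(x)
        grid = np.linspace(x.min() - 3 * x.std(), x.max() + 3 * x.std(), 200)
        ax.plot(grid, kde(grid), label=name)
    ax.set_xlabel("% divergence" if percent else "divergence (subst/site)")
    ax.set_ylabel("density")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
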