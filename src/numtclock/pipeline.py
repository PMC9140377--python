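"""End-to-end NUMT analysis: from alignments (simulated or supplied) to a
dated, classified, scenario-called report.

Stages: build the joint NUMT/mtDNA tree, map mutations and test the
stem-vs-branches synonymous contrast, jackknife the stem and the reference
taxon divergences, correct the stem by its mitochondrial fraction, convert
to time via the linear calibration, run the ancestral-Ne counterargument,
and call the scenario (NUMT transfer vs mtDNA introgression) from the
shared-stem statistic.

The shared-stem statistic operationalizes the qualitative signature that
separates the two hybridization scenarios: under mtDNA introgression the
NUMT subtree shares ancestry — a common stem — with the non-introgressed
mtDNA branch (the gorilla branch in the hominine case), whereas a plain
NUMT transfer attaches the NUMT clade independently at the ingroup root.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time as _time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .alignment import CodingAlignment
from .calibrate import divergence_to_time, fit_calibration, ne_extrapolation
from .divergence import (
    JackknifeDistribution,
    branch_length_stat,
    classify_divergence,
    correct_stem_divergence,
    jackknife_statistics,
    plot_jackknife_densities,
    taxon_divergence_stat,
)
from .io import fasta_string, read_fasta, read_tsv_points, write_fasta
from .mutmap import (
    assign_branch_mutations,
    reconstruct_ancestors,
    stem_contrast_test,
)
from .phylo import Phylogeny, build_nj_tree, distance_matrix, root_with_outgroup
from .seqsim import (
    MT_SUFFIX,
    NUMT_SUFFIX,
    ScenarioSpec,
    simulate_scenario,
    synthetic_ne_points,
)

log = logging.getLogger("numtclock.pipeline")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and cause."""


# ---------------------------------------------------------------------------
# shared-stem statistic


def detect_shared_stem(
    t: Phylogeny,
    numt_clade: Iterable[str],
    candidate_branch_leaves: Iterable[str],
    reference: Iterable[str] | None = None,
) -> float:
    """Length of the stem shared by the NUMT clade and a candidate branch.

    Measures the overlap of the root-to-MRCA paths of the NUMT clade and
    the candidate leaf set: the distance from the reference point (the
    tree root, or the MRCA of ``reference`` when given — typically the
    ingroup ancestor, so the outgroup's pendant branch cannot leak into
    the statistic) down to the common ancestor of the two MRCAs. Zero when
    the two attach independently at the reference point.
    """
    numt = sorted(set(numt_clade))
    cand = sorted(set(candidate_branch_leaves))
    if not cand:
        raise ValueError("candidate leaf set is empty")
    if set(numt) & set(cand):
        raise ValueError("candidate leaves overlap the NUMT clade")
    if not t.is_monophyletic(numt):
        raise ValueError(
            f"NUMT clade {numt} is not monophyletic in the tree"
        )
    ref_node = t.root if reference is None else t.mrca(sorted(set(reference)))
    join = t.mrca([t.mrca(numt), t.mrca(cand)])
    # walk from the join point up to the reference point
    total = 0.0
    node = join
    while node is not None and node is not ref_node:
        total += node.length or 0.0
        node = node.parent
    if node is None:  # join above the reference point: no shared stem
        return 0.0
    return total


def scenario_call(shared: JackknifeDistribution) -> str:
    """Call the generating scenario from the shared-stem distribution.

    ``introgression_consistent`` requires a shared stem exceeding 3x its
    jackknife sd, ``numt_transfer_consistent`` one below 1 sd; anything
    between is ``ambiguous``.
    """
    mean, sd = shared.mean, shared.sd
    if mean <= sd:
        return "numt_transfer_consistent"
    if mean > 3.0 * sd:
        return "introgression_consistent"
    return "ambiguous"


# ---------------------------------------------------------------------------
# configuration

_DEFAULTS = {
    "model": "k80",
    "n_replicates": "1000",
    "delete_fraction": "0.5",
    "outgroup": "Orangutan" + MT_SUFFIX,
    "candidate_mt": "Gorilla" + MT_SUFFIX,
    "congeneric_taxa": "Chimp,Bonobo",
    "intergeneric_taxa": "Human,Gorilla",
    "mito_fraction": "auto",
    "ancestral_ne": "50000",
    "seed": "0",
}

_SCENARIO_KEYS = {f.name for f in dataclasses.fields(ScenarioSpec)}


@dataclass
class AnalysisReport:
    """Everything the analysis concluded, plus provenance for replay."""

    stem_raw_percent: float
    stem_raw_sd_percent: float
    mito_fraction: float
    stem_corrected_percent: float
    stem_corrected_sd_percent: float
    calibration_slope: float
    time_myr: float
    time_sd_myr: float
    contrast: dict | None
    divergence_category: str
    classification: dict
    ne_test: dict | None
    shared_stem: dict
    scenario: str
    tree_newick: str
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            dataclasses.asdict(self), indent=indent, sort_keys=True
        )


def _reference_sets(
    species_tree: str, mt_leaves: Sequence[str]
) -> dict[str, tuple[list[str], float]]:
    """Per-taxon (sister mt leaves, split time Myr) from a dated tree.

    The split time of a taxon is its time to the common ancestor with its
    sister group — exactly the node its divergence statistic runs to.
    """
    sp = Phylogeny.from_newick(species_tree)
    out: dict[str, tuple[list[str], float]] = {}
    for leaf in sp.leaves():
        if leaf.parent is None:
            continue
        sisters = [
            name
            for sib in leaf.parent.children
            if sib is not leaf
            for name in sp.leafset(sib)
        ]
        sisters_mt = [s + MT_SUFFIX for s in sisters
                      if s + MT_SUFFIX in mt_leaves]
        if leaf.name + MT_SUFFIX in mt_leaves and sisters_mt:
            out[leaf.name] = (sisters_mt, float(leaf.length or 0.0))
    return out


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: dict, out_dir=None) -> AnalysisReport:
    """Run every stage on a simulated scenario or user-supplied files.

    ``config`` is a flat mapping. Scenario fields (``mode``,
    ``sequence_length`` ...) select the simulation route; alternatively
    ``mt_fasta``/``numt_fasta`` plus ``ref_<Taxon>=<sister,..>@<Myr>``
    entries select the file route. On any stage failure the partial
    outputs written to ``out_dir`` are removed and a PipelineError names
    the stage.
    """
    cfg = dict(_DEFAULTS)
    cfg.update({str(k): str(v) for k, v in config.items()})
    written: list[str] = []
    stage = "configure"
    t_start = _time.time()

    def emit(path: str, text: str) -> None:
        if out_dir is None:
            return
        os.makedirs(out_dir, exist_ok=True)
        full = os.path.join(out_dir, path)
        with open(full, "w") as fh:
            fh.write(text)
        written.append(full)

    try:
        seed = int(cfg["seed"])
        model = cfg["model"]
        n_reps = int(cfg["n_replicates"])
        delete_fraction = float(cfg["delete_fraction"])

        # -- stage: inputs -------------------------------------------------
        stage = "inputs"
        truth = None
        if "mt_fasta" in cfg:
            coding_map = ()
            if "coding_map" in cfg:
                coding_map = ScenarioSpec.from_dict(
                    {"coding_map": cfg["coding_map"]}
                ).coding_map
            mt_aln = read_fasta(cfg["mt_fasta"], coding_map)
            numt_aln = read_fasta(cfg["numt_fasta"], coding_map)
            refsets = {}
            for key, val in cfg.items():
                if key.startswith("ref_"):
                    sisters, t_split = val.split("@")
                    refsets[key[4:]] = (
                        [s.strip() for s in sisters.split(",")],
                        float(t_split),
                    )
            species_tree = None
        else:
            scen = {k: v for k, v in cfg.items() if k in _SCENARIO_KEYS}
            scen["seed"] = str(seed)
            spec = ScenarioSpec.from_dict(scen)
            mt_aln, numt_aln, truth = simulate_scenario(spec)
            species_tree = spec.species_tree
            refsets = None
        joint = CodingAlignment.concat(mt_aln, numt_aln)
        numt_ids = list(numt_aln.ids)
        input_hash = hashlib.sha256(
            fasta_string(joint).encode()
        ).hexdigest()
        log.info("stage=inputs n_seqs=%d length=%d hash=%s",
                 joint.n, joint.length, input_hash[:12])

        # -- stage: tree ---------------------------------------------------
        stage = "tree"
        outgroup = cfg["outgroup"]
        D, labels = distance_matrix(joint, model)
        nj = build_nj_tree(D, labels)
        tree = root_with_outgroup(nj, outgroup)
        tree.assign_internal_names()
        if not tree.is_monophyletic(numt_ids):
            raise ValueError(
                f"NUMT sequences {numt_ids} are not monophyletic in the "
                f"joint tree; cannot define a stem"
            )
        ingroup = [l for l in tree.leaf_names() if l != outgroup]
        log.info("stage=tree model=%s leaves=%d", model, len(labels))

        # -- stage: mutmap -------------------------------------------------
        stage = "mutmap"
        anc = reconstruct_ancestors(tree, joint)
        mutset = assign_branch_mutations(anc, joint)
        numt_mrca = anc.mrca(numt_ids)
        stem_branch = str(numt_mrca.name)
        numt_internal = [
            str(n.name)
            for n in anc.preorder()
            if n is not numt_mrca
            and anc.mrca([n, numt_mrca]) is numt_mrca
        ]
        mt_branches = [
            b
            for b in mutset.branches()
            if b not in numt_internal
            and b != stem_branch
            and b != outgroup
            and b != str(anc.root.name)
        ]
        contrast = None
        contrast_note = None
        try:
            res = stem_contrast_test(
                mutset.slice([stem_branch]), mutset.slice(numt_internal)
            )
            contrast = {
                "syn_fraction_stem": res.syn_fraction_stem,
                "syn_fraction_others": res.syn_fraction_others,
                "p_value": res.p_value,
                "table": [list(r) for r in res.table],
                "degenerate": res.degenerate,
            }
        except ValueError as exc:
            contrast_note = str(exc)
            log.info("stage=mutmap contrast skipped: %s", exc)

        # -- stage: jackknife ----------------------------------------------
        stage = "jackknife"
        if refsets is None:
            refsets = _reference_sets(species_tree, list(mt_aln.ids))
        # the outgroup's own divergence is not identifiable in the joint
        # tree (its pendant branch merges with the ingroup stalk), so it
        # never serves as a calibration reference
        refsets = {
            t: v for t, v in refsets.items() if t + MT_SUFFIX != outgroup
        }
        candidates = [c.strip() for c in cfg["candidate_mt"].split(",")]
        stats = {"stem": branch_length_stat(frozenset(numt_ids))}
        for taxon, (sisters, _t) in refsets.items():
            stats[f"ref:{taxon}"] = taxon_divergence_stat(
                taxon + MT_SUFFIX if taxon + MT_SUFFIX in mt_aln.ids
                else taxon,
                sisters,
            )
        for cand in candidates:
            stats[f"shared:{cand}"] = (
                lambda tr, _e, c=cand: detect_shared_stem(
                    tr, numt_ids, [c], reference=ingroup
                )
            )
        dists = jackknife_statistics(
            joint,
            tree,
            stats,
            n_replicates=n_reps,
            delete_fraction=delete_fraction,
            model=model,
            seed=seed + 1,
        )
        stem_dist = dists["stem"]
        log.info(
            "stage=jackknife reps=%d stem=%.3f%%+-%.3f%%",
            n_reps, stem_dist.mean_percent, stem_dist.sd_percent,
        )

        # -- stage: correction ----------------------------------------------
        stage = "correction"
        mito_cfg = cfg["mito_fraction"]
        if mito_cfg == "auto":
            mito_fraction = _estimate_mito_fraction(
                mutset, stem_branch, numt_internal, mt_branches
            )
        else:
            mito_fraction = float(mito_cfg)
        corrected = correct_stem_divergence(stem_dist, mito_fraction)

        # -- stage: calibration ----------------------------------------------
        stage = "calibration"
        points = [
            (refsets[taxon][1], dists[f"ref:{taxon}"].mean_percent)
            for taxon in refsets
        ]
        cal = fit_calibration(points)
        time_myr, time_sd = divergence_to_time(
            corrected.mean_percent, cal, corrected.sd_percent
        )

        # -- stage: classification -------------------------------------------
        stage = "classification"
        congeneric = [t.strip() for t in cfg["congeneric_taxa"].split(",")]
        intergeneric = [
            t.strip() for t in cfg["intergeneric_taxa"].split(",")
        ]
        category, details = classify_divergence(
            corrected,
            [dists[f"ref:{t}"] for t in congeneric if f"ref:{t}" in dists],
            [dists[f"ref:{t}"] for t in intergeneric if f"ref:{t}" in dists],
        )

        # -- stage: ne -------------------------------------------------------
        stage = "ne"
        if "ne_table" in cfg:
            ne_points = read_tsv_points(cfg["ne_table"])
        else:
            ne_points = synthetic_ne_points(seed + 2)
        ne = ne_extrapolation(
            ne_points, float(cfg["ancestral_ne"]), corrected.mean_percent
        )

        # -- stage: scenario -------------------------------------------------
        stage = "scenario"
        shared_report = {}
        for cand in candidates:
            d = dists[f"shared:{cand}"]
            shared_report[cand] = {
                "mean": d.mean,
                "sd": d.sd,
                "mean_percent": d.mean_percent,
            }
        call = scenario_call(dists[f"shared:{candidates[0]}"])

        # -- stage: report ---------------------------------------------------
        stage = "report"
        report = AnalysisReport(
            stem_raw_percent=stem_dist.mean_percent,
            stem_raw_sd_percent=stem_dist.sd_percent,
            mito_fraction=mito_fraction,
            stem_corrected_percent=corrected.mean_percent,
            stem_corrected_sd_percent=corrected.sd_percent,
            calibration_slope=cal.slope,
            time_myr=time_myr,
            time_sd_myr=time_sd,
            contrast=contrast,
            divergence_category=category,
            classification=details,
            ne_test=ne.summary(),
            shared_stem=shared_report,
            scenario=call,
            tree_newick=tree.to_newick(),
            provenance={
                "package_version": __version__,
                "seed": seed,
                "jackknife_seed": seed + 1,
                "input_sha256": input_hash,
                "config": cfg,
                "contrast_note": contrast_note,
                "calibration_points": points,
                "simulated": truth is not None,
                **(
                    {
                        "true_stem_divergence": truth.true_stem_divergence,
                        "scenario_mode": cfg.get("mode", "numt_transfer"),
                    }
                    if truth is not None
                    else {}
                ),
            },
        )
        emit("report.json", report.to_json())
        if out_dir is not None:
            named = {"stem (corrected)": corrected}
            named.update(
                {k: v for k, v in dists.items() if k.startswith("ref:")}
            )
            fig_path = os.path.join(out_dir, "divergence_densities.png")
            plot_jackknife_densities(named, fig_path)
            written.append(fig_path)
            write_fasta(joint, os.path.join(out_dir, "joint.fasta"))
            written.append(os.path.join(out_dir, "joint.fasta"))
            if truth is not None:
                emit("truth.json", truth.to_json())
        log.info(
            "pipeline done in %.1fs: stem %.2f%%, time %.2f Myr, %s",
            _time.time() - t_start, stem_dist.mean_percent, time_myr, call,
        )
        return report
    except Exception as exc:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _estimate_mito_fraction(
    mutset, stem_branch: str, numt_internal, mt_branches
) -> float:
    """Mixture estimate of the stem's mitochondrial fraction.

    The observed stem synonymous fraction is modelled as a mixture of the
    mitochondrial-phase fraction (estimated from the mtDNA branches) and
    the neutral nuclear fraction (estimated from the post-insertion NUMT
    branches); clipped to [0, 1], defaulting to 1 when the contrast is
    undefined.
    """

    def syn_frac(branches) -> float | None:
        c = mutset.slice(branches).counts()
        tot = c["synonymous"] + c["non_synonymous"]
        return c["synonymous"] / tot if tot else None

    s_stem = syn_frac([stem_branch])
    s_mito = syn_frac(mt_branches)
    s_neutral = syn_frac(numt_internal)
    if s_stem is None or s_mito is None or s_neutral is None:
        return 1.0
    denom = s_mito - s_neutral
    if denom <= 0:
        return 1.0
    return float(np.clip((s_stem - s_neutral) / denom, 0.0, 1.0))
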