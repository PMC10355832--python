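"""End-to-end workflows tying the stages together on synthetic libraries.

These drivers are what the acceptance analyses and the command line run:
simulate libraries, classify them hierarchically, screen for host genes,
recover planted triggers, measure phasing, and compare mutant conditions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic_data as syn
from .classify_map import (
    ClassifyPolicy,
    LibraryProfile,
    ReadAssignment,
    _Annot,
    classify_hierarchical,
    quantify,
    quantify_transcript_reads,
    size_select,
)
from .core_io import GenomeAssets, Read, child_rng
from .differential import FoldChangeRecord, class_fold_change
from .host_screen import ScreenCriteria, run_screen
from .overlap_pairs import ReadGroup, find_overlap_pairs, group_reads
from .phasing import PhasingResult, phase_reads, phasing_distances, phasing_zscore, shuffle_5prime

__all__ = [
    "classify_library",
    "ScreenExperiment",
    "run_screen_experiment",
    "screen_performance",
    "trigger_recovery",
    "transcript_intervals",
    "phasing_by_gene",
    "shuffled_z1",
    "run_depletion_experiment",
]


def _lib_key(label: str) -> int:
    return zlib.crc32(("classify:" + label).encode()) & 0x7FFFFFFF


def classify_library(
    reads: Sequence[Read],
    assets: GenomeAssets,
    seed: int,
    library: str,
    min_len: int = 18,
    max_len: int = 29,
    policy: ClassifyPolicy | None = None,
    annot: "_Annot | None" = None,
) -> tuple[list[ReadAssignment], int]:
    """Size-select and hierarchically classify one library.

    Returns (assignments, number of reads removed by size selection).  The
    within-tier random placement stream is keyed by seed and library label.
    """
    policy = policy or ClassifyPolicy()
    kept, n_removed = size_select(reads, min_len, max_len)
    rng = child_rng(seed, _lib_key(library))
    assignments = classify_hierarchical(kept, assets, policy, rng=rng,
                                        annot=annot)
    return assignments, n_removed


@dataclass
class ScreenExperiment:
    """Everything the default screen run produces."""

    spec: syn.SimulationSpec
    assets: GenomeAssets
    reads: dict[str, list[Read]]
    truth: pd.DataFrame
    assignments: dict[str, list[ReadAssignment]]
    profiles: dict[str, LibraryProfile]
    mrna_tpm: pd.Series
    screen: pd.DataFrame
    host_ids: list[str] = field(default_factory=list)


TOTAL_LIBS = ("total_rep1", "total_rep2")
AUB_LIBS = ("aub_ip_rep1", "aub_ip_rep2")


def run_screen_experiment(
    spec: syn.SimulationSpec | None = None,
    criteria: ScreenCriteria | None = None,
    with_junctions: bool = False,
) -> ScreenExperiment:
    """Simulate the standard conditions (two total + two Aub-IP libraries
    plus mRNA-seq), classify, and run the host screen."""
    spec = spec or syn.SimulationSpec.default()
    assets = syn.build_toy_assets(spec)
    annot = _Annot(assets, ClassifyPolicy())

    reads: dict[str, list[Read]] = {}
    truths = []
    assignments: dict[str, list[ReadAssignment]] = {}
    profiles: dict[str, LibraryProfile] = {}
    for lib in TOTAL_LIBS + AUB_LIBS:
        ip = "Aub" if lib.startswith("aub") else None
        r, t = syn.simulate_srna_library(assets, spec, lib, ip=ip)
        reads[lib] = r
        truths.append(t)
        asg, _ = classify_library(r, assets, spec.seed, lib, annot=annot)
        assignments[lib] = asg
        profiles[lib] = quantify(
            [a for a in asg if 23 <= a.length <= 29], assets, lib,
            total_raw=len(r))

    mrna_reads, deg_reads, deg_truth = syn.simulate_mrna_and_degradome(assets, spec)
    reads["mrna"] = mrna_reads
    reads["degradome"] = deg_reads
    truths.append(deg_truth)
    mrna_df = quantify_transcript_reads(mrna_reads, assets, "mrna")
    mrna_tpm = mrna_df["tpm"]

    unassigned = []
    if with_junctions:
        id_to_read = {lib: {r.read_id: r for r in reads[lib]} for lib in TOTAL_LIBS}
        for lib in TOTAL_LIBS:
            unassigned.append([
                id_to_read[lib][a.read_id]
                for a in assignments[lib] if a.cls == "unassigned"
            ])

    screen = run_screen(
        assets,
        [assignments[l] for l in TOTAL_LIBS],
        [assignments[l] for l in AUB_LIBS],
        mrna_tpm,
        unassigned_reads=unassigned,
        criteria=criteria,
    )
    return ScreenExperiment(
        spec=spec, assets=assets, reads=reads,
        truth=pd.concat(truths, ignore_index=True),
        assignments=assignments, profiles=profiles, mrna_tpm=mrna_tpm,
        screen=screen, host_ids=syn.host_gene_ids(spec),
    )


def screen_performance(exp: ScreenExperiment) -> tuple[float, float]:
    """(sensitivity, precision) of the composite host call against the
    planted truth."""
    hosts = set(exp.host_ids)
    called = set(exp.screen.index[exp.screen["call"]])
    tp = len(called & hosts)
    sensitivity = tp / len(hosts) if hosts else float("nan")
    precision = tp / len(called) if called else float("nan")
    return sensitivity, precision


def trigger_recovery(
    exp: ScreenExperiment,
    library: str = "aub_ip_rep1",
    min_responder_reads: int = 10,
) -> tuple[set[str], set[str], dict[str, int]]:
    """Run the 10-nt overlap search of the planted triggers against genic
    piRNAs of one library.

    Returns (recovered trigger names, all trigger names, planted responder
    read count per trigger in that library's truth).
    """
    genic = [Read(a.read_id, a.sequence)
             for a in exp.assignments[library]
             if a.cls == "genic" and 23 <= a.length <= 29]
    responders = group_reads(genic, label=library)
    triggers = [ReadGroup(t.seq, 1, t.name) for t in exp.assets.triggers]
    pairs = find_overlap_pairs(triggers, responders,
                               min_responder_reads=min_responder_reads)
    recovered = {p.trigger.label for p in pairs}
    truth_lib = exp.truth[(exp.truth["library"] == library)
                          & (exp.truth["responder_of"] != "")]
    planted = truth_lib.groupby("responder_of").size().to_dict()
    return recovered, {t.name for t in exp.assets.triggers}, planted


def transcript_intervals(
    assignments: Sequence[ReadAssignment], assets: GenomeAssets, gene_id: str
) -> list[tuple[int, int]]:
    """Sense-strand genic reads of one gene as transcript-space intervals."""
    gene = assets.gene(gene_id)
    out = []
    for a in assignments:
        if a.cls != "genic" or a.locus != gene_id or a.strand != gene.strand:
            continue
        five_g = a.pos if gene.strand == "+" else a.pos + a.length - 1
        t5 = gene.genomic_to_transcript(five_g)
        if t5 is not None:
            out.append((t5, t5 + a.length))
    return out


def phasing_by_gene(
    exp: ScreenExperiment, library: str = "aub_ip_rep1"
) -> dict[str, PhasingResult]:
    """Phasing signature per planted phased gene in one library."""
    out = {}
    for gid in syn.phased_gene_ids(exp.spec):
        ivs = transcript_intervals(exp.assignments[library], exp.assets, gid)
        out[gid] = phase_reads(ivs)
    return out


def shuffled_z1(
    exp: ScreenExperiment,
    gene_id: str,
    library: str = "aub_ip_rep1",
    n_shuffles: int = 20,
    seed: int | None = None,
) -> float:
    """Mean z1 over independent 5'-end shuffles of one gene's reads
    (permutation control for the phased signal)."""
    # the distance histogram is computed over distinct read species, so the
    # permutation control shuffles distinct intervals, not read copies
    ivs = sorted(set(
        transcript_intervals(exp.assignments[library], exp.assets, gene_id)))
    span = len(exp.assets.transcripts[gene_id].seq)
    rng = child_rng(exp.spec.seed if seed is None else seed,
                    _lib_key("shuffle:" + gene_id))
    zs = []
    for _ in range(n_shuffles):
        res = phase_reads(shuffle_5prime(ivs, span, rng))
        if np.isfinite(res.z1):
            zs.append(res.z1)
    return float(np.mean(zs)) if zs else float("nan")


def run_depletion_experiment(
    seed: int,
    depletion_factor: float = 0.6,
    n_pairs: int = 2,
    tier_rpm: float = 1000.0,
) -> dict[str, FoldChangeRecord]:
    """Simulate paired mutant/control Aub-IP-like libraries with the
    exon-mapper (host piRNA) class depleted, classify, and measure class
    fold changes with the genic class restricted to the control RPM tier.

    The default tier cut (control RPM > 1000) selects the piRNA host tier
    at toy library depth, where decay-only genes already sit near ~200 RPM
    because few genes share the denominator; it plays the role a deep
    library's RPM > 10 tier plays at genome scale."""
    spec = syn.SimulationSpec.mutant_default()
    spec.seed = seed
    assets = syn.build_toy_assets(spec)
    annot = _Annot(assets, ClassifyPolicy())
    case_profiles, control_profiles = [], []
    for i in range(1, n_pairs + 1):
        for cond, profs, dep in (
            ("mut", case_profiles, {"host_pirna": depletion_factor}),
            ("het", control_profiles, {}),
        ):
            lib = f"aub_{cond}_rep{i}"
            r, _t = syn.simulate_srna_library(assets, spec, lib, depletion=dep)
            asg, _ = classify_library(r, assets, spec.seed, lib, annot=annot)
            profs.append(quantify(
                [a for a in asg if 23 <= a.length <= 29], assets, lib,
                total_raw=len(r)))
    mean_ctrl_rpm = pd.concat(
        [p.genes["rpm"] for p in control_profiles], axis=1).mean(axis=1)
    tier_genes = list(mean_ctrl_rpm.index[mean_ctrl_rpm > tier_rpm])
    return class_fold_change(case_profiles, control_profiles,
                             classes=("cluster", "TE", "genic"),
                             gene_set=tier_genes)
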