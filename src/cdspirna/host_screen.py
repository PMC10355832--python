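"""The CDS-piRNA host-gene screen.

Per-gene metrics over one or more small-RNA libraries — enrichment of
23–29-nt RNAs relative to mRNA (TPM/TPM), 18–29-nt size profile with a
24–26-nt peak test, positional nucleotide probabilities and 5'U fraction,
PIWI-protein IP enrichment, Aub-RPM tiers, 5'UTR/CDS/3'UTR read densities,
sense-strand fraction and exon-junction read counts — and the composite
host call combining them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify_map import (
    LibraryProfile,
    ReadAssignment,
    ReferenceIndex,
    quantify,
)
from .core_io import GeneModel, GenomeAssets, Read, Transcript

__all__ = [
    "ScreenCriteria",
    "enrichment_ratio",
    "size_profile",
    "nt_probability",
    "ip_enrichment",
    "tier_hosts",
    "region_density",
    "region_density_test",
    "sense_fraction",
    "junction_reads",
    "call_hosts",
    "run_screen",
]

SIZE_WINDOW = range(18, 30)
PIRNA_MIN, PIRNA_MAX = 23, 29


@dataclass
class ScreenCriteria:
    """Thresholds of the composite host call (all configurable)."""

    ratio_threshold: float = 10.0
    u1_min: float = 0.5
    aub_enrichment_min: float = 2.0
    pseudo: float = 0.5
    tier_thresholds: tuple[float, float] = (100.0, 10.0)
    junction_anchor: int = 4


def _pseudo_ratio(num: float, den: float, pseudo: float) -> float:
    num = num if num > 0 else pseudo
    den = den if den > 0 else pseudo
    if den == 0:
        return float("nan")
    return num / den


def enrichment_ratio(
    srna_tpm: float, mrna_tpm: float, pseudo: float = 0.0,
    threshold: float = 10.0,
) -> tuple[float, bool]:
    """Small-RNA over mRNA abundance ratio (the screen's y axis).

    Zero terms fall back to the pseudocount; genes with ratio at or below
    the threshold are excluded from further analysis.
    """
    if srna_tpm < 0 or mrna_tpm < 0:
        raise ValueError("TPM values must be >= 0")
    ratio = _pseudo_ratio(srna_tpm, mrna_tpm, pseudo)
    return ratio, bool(ratio > threshold)


def size_profile(
    lengths_by_library: Sequence[Sequence[int]],
) -> tuple[pd.Series, bool]:
    """Length → proportion over 18–29 nt, averaged across libraries.

    The peak test is true iff the modal length lies in 24–26 nt.  Libraries
    without reads in the window are skipped; no reads anywhere raises.
    """
    per_lib = []
    for lengths in lengths_by_library:
        counts = pd.Series(0.0, index=list(SIZE_WINDOW))
        for L in lengths:
            if 18 <= L <= 29:
                counts[L] += 1
        if counts.sum() > 0:
            per_lib.append(counts / counts.sum())
    if not per_lib:
        raise ValueError("no reads in the 18-29-nt window")
    prop = sum(per_lib) / len(per_lib)
    peak = int(prop.idxmax()) in (24, 25, 26)
    return prop, peak


def nt_probability(
    seqs: Sequence[str], positions: int = 23
) -> tuple[pd.DataFrame, float]:
    """Per-position base probabilities over the first ``positions`` bases.

    Reads shorter than ``positions`` are ignored for the matrix; returns
    (positions × ACGT probability matrix, 5'U fraction).  U is T in the DNA
    alphabet.
    """
    mat = pd.DataFrame(0.0, index=range(1, positions + 1),
                       columns=list("ACGT"))
    n = 0
    for s in seqs:
        if len(s) < positions:
            continue
        n += 1
        for i in range(positions):
            if s[i] in mat.columns:
                mat.loc[i + 1, s[i]] += 1
    if n == 0:
        raise ValueError("no reads of sufficient length")
    mat = mat / n
    return mat, float(mat.loc[1, "T"])


def ip_enrichment(
    total_tpm: float, ip_tpms: Sequence[float], pseudo: float = 0.5
) -> float:
    """Bound/total abundance ratio: mean of the IP libraries over the total
    library, zero terms replaced by the pseudocount."""
    mean_ip = float(np.mean(list(ip_tpms)))
    return _pseudo_ratio(mean_ip, total_tpm, pseudo)


def tier_hosts(
    aub_rpm: pd.Series, thresholds: tuple[float, float] = (100.0, 10.0)
) -> pd.Series:
    """Strict-inequality abundance tiers on mean Aub-IP RPM."""
    hi, lo = thresholds
    def tier(v: float) -> str:
        if v > hi:
            return "rpm_gt_100"
        if v > lo:
            return "rpm_gt_10"
        return "below"
    return aub_rpm.map(tier)


def region_density(
    gene: GeneModel, region_counts: dict[str, float]
) -> tuple[dict[str, float], dict[str, float], bool]:
    """Per-nt densities over 5'UTR/CDS/3'UTR and their relative values.

    Returns (density, relative density summing to 1, all-regions-present
    flag); zero-length regions are flagged and excluded from cohort tests.
    """
    lengths = gene.region_lengths()
    density = {}
    complete = True
    for region in ("utr5", "cds", "utr3"):
        n = float(region_counts.get(region, 0.0))
        if lengths[region] == 0:
            complete = False
            density[region] = float("nan")
        else:
            density[region] = n / lengths[region]
    total = np.nansum(list(density.values()))
    if total > 0:
        relative = {k: (0.0 if np.isnan(v) else v / total)
                    for k, v in density.items()}
    else:
        relative = {k: float("nan") for k in density}
    return density, relative, complete


def region_density_test(
    densities: pd.DataFrame, region_a: str = "cds", region_b: str = "utr3"
) -> float:
    """Two-tailed paired t-test of per-gene densities between two regions."""
    sub = densities[[region_a, region_b]].dropna()
    if len(sub) < 3:
        return float("nan")
    return float(stats.ttest_rel(sub[region_a], sub[region_b]).pvalue)


def sense_fraction(n_sense: int, n_antisense: int) -> float:
    """Proportion of reads on the gene's strand; NaN when no reads."""
    total = n_sense + n_antisense
    if total == 0:
        return float("nan")
    return n_sense / total


def junction_reads(
    reads: Sequence[Read],
    transcript: Transcript,
    genome_index: ReferenceIndex,
    anchor: int = 4,
) -> int:
    """Count reads that demand the spliced transcript.

    A read counts iff it matches the transcript exactly, crosses an
    exon-exon junction with at least ``anchor`` nt on each side, and has no
    contiguous genomic placement of equal quality (exact genome hit).
    """
    n = 0
    genome_cache: dict[str, bool] = {}
    for r in reads:
        seq, L = r.seq, len(r.seq)
        placements = []
        j = transcript.seq.find(seq)
        while j >= 0:
            placements.append(j)
            j = transcript.seq.find(seq, j + 1)
        crosses = any(
            s + anchor <= junc <= s + L - anchor
            for s in placements
            for junc in transcript.junctions
        )
        if not crosses:
            continue
        if seq not in genome_cache:
            genome_cache[seq] = bool(genome_index.exact(seq, "both"))
        if not genome_cache[seq]:
            n += 1
    return n


def call_hosts(
    records: pd.DataFrame, criteria: ScreenCriteria | None = None
) -> pd.Series:
    """Composite host call: enrichment ratio above threshold AND 24–26-nt
    peak AND 5'U fraction AND Aub IP enrichment."""
    c = criteria or ScreenCriteria()
    return (
        (records["enrichment_ratio"] > c.ratio_threshold)
        & records["peak_24_26"].astype(bool)
        & (records["u1_fraction"] >= c.u1_min)
        & (records["aub_ip_enrichment"] >= c.aub_enrichment_min)
    )


# ---------------------------------------------------------------------------
# Screen driver
# ---------------------------------------------------------------------------


def _pirna_subset(assignments: Sequence[ReadAssignment]) -> list[ReadAssignment]:
    return [a for a in assignments if PIRNA_MIN <= a.length <= PIRNA_MAX]


def run_screen(
    assets: GenomeAssets,
    total_assignments: Sequence[Sequence[ReadAssignment]],
    aub_assignments: Sequence[Sequence[ReadAssignment]],
    mrna_tpm: pd.Series,
    piwi_assignments: Sequence[Sequence[ReadAssignment]] = (),
    unassigned_reads: Sequence[Sequence[Read]] = (),
    criteria: ScreenCriteria | None = None,
) -> pd.DataFrame:
    """Compute one screen record per gene and the composite host call.

    ``total_assignments``/``aub_assignments`` hold per-library hierarchical
    assignments classified over the 18–29-nt window; TPM/RPM metrics use the
    23–29-nt subset, the size profile the full window, as in the screen's
    two size modes.  ``mrna_tpm`` is the mean per-gene mRNA abundance.
    ``unassigned_reads`` (optional, per total library) feed the
    junction-read count.
    """
    c = criteria or ScreenCriteria()
    total_profiles = [
        quantify(_pirna_subset(a), assets, f"total{i}")
        for i, a in enumerate(total_assignments)
    ]
    aub_profiles = [
        quantify(_pirna_subset(a), assets, f"aub{i}")
        for i, a in enumerate(aub_assignments)
    ]
    piwi_profiles = [
        quantify(_pirna_subset(a), assets, f"piwi{i}")
        for i, a in enumerate(piwi_assignments)
    ]

    gene_ids = sorted(g.gene_id for g in assets.genes)
    srna_tpm = pd.concat([p.genes["tpm"] for p in total_profiles], axis=1).mean(axis=1)
    aub_tpm = (pd.concat([p.genes["tpm"] for p in aub_profiles], axis=1).mean(axis=1)
               if aub_profiles else pd.Series(0.0, index=gene_ids))
    piwi_tpm = (pd.concat([p.genes["tpm"] for p in piwi_profiles], axis=1).mean(axis=1)
                if piwi_profiles else None)
    aub_rpm = (pd.concat([p.genes["rpm"] for p in aub_profiles], axis=1).mean(axis=1)
               if aub_profiles else pd.Series(0.0, index=gene_ids))

    # per-gene read lengths (18-29 window) and sequences (>=23 nt), per library
    lengths_by_gene: dict[str, list[list[int]]] = {g: [] for g in gene_ids}
    for a_list in total_assignments:
        per_gene: dict[str, list[int]] = {}
        for a in a_list:
            if a.cls == "genic":
                per_gene.setdefault(a.locus, []).append(a.length)
        for g, lens in per_gene.items():
            lengths_by_gene[g].append(lens)
    seqs_by_gene: dict[str, list[str]] = {g: [] for g in gene_ids}
    for a_list in total_assignments:
        for a in a_list:
            if a.cls == "genic" and a.length >= PIRNA_MIN:
                seqs_by_gene[a.locus].append(a.sequence)

    # region counts and strand from the Aub-bound libraries (fall back to
    # totals when no IP data given)
    density_profiles = aub_profiles or total_profiles
    region_counts = sum(p.genes[["utr5", "cds", "utr3"]] for p in density_profiles)
    strand_counts = sum(p.genes[["sense", "antisense"]] for p in total_profiles)

    genome_index = ReferenceIndex(assets.sequences)
    rows = []
    for gid in gene_ids:
        gene = assets.gene(gid)
        ratio, retained = enrichment_ratio(
            float(srna_tpm.get(gid, 0.0)), float(mrna_tpm.get(gid, 0.0)),
            pseudo=c.pseudo, threshold=c.ratio_threshold)
        lens_libs = lengths_by_gene[gid]
        if any(lens_libs):
            prop, peak = size_profile([l for l in lens_libs if l])
            peak_mass = float(prop.loc[24:26].sum())
        else:
            prop, peak, peak_mass = None, False, float("nan")
        seqs = seqs_by_gene[gid]
        if seqs:
            _mat, u1 = nt_probability(seqs)
        else:
            u1 = float("nan")
        aub_enr = ip_enrichment(float(srna_tpm.get(gid, 0.0)),
                                [float(aub_tpm.get(gid, 0.0))], c.pseudo)
        piwi_enr = (ip_enrichment(float(srna_tpm.get(gid, 0.0)),
                                  [float(piwi_tpm.get(gid, 0.0))], c.pseudo)
                    if piwi_tpm is not None else float("nan"))
        density, relative, complete = region_density(
            gene, region_counts.loc[gid].to_dict())
        sf = sense_fraction(int(strand_counts.loc[gid, "sense"]),
                            int(strand_counts.loc[gid, "antisense"]))
        n_junc = 0
        if unassigned_reads:
            tx = assets.transcripts[gid]
            for lib_reads in unassigned_reads:
                n_junc += junction_reads(lib_reads, tx, genome_index,
                                         c.junction_anchor)
        rows.append({
            "gene_id": gid,
            "srna_tpm": float(srna_tpm.get(gid, 0.0)),
            "mrna_tpm": float(mrna_tpm.get(gid, 0.0)),
            "enrichment_ratio": ratio,
            "retained": retained,
            "peak_24_26": peak,
            "peak_mass_24_26": peak_mass,
            "u1_fraction": u1,
            "aub_ip_enrichment": aub_enr,
            "piwi_ip_enrichment": piwi_enr,
            "aub_rpm": float(aub_rpm.get(gid, 0.0)),
            "density_utr5": density["utr5"],
            "density_cds": density["cds"],
            "density_utr3": density["utr3"],
            "rel_density_cds": relative["cds"],
            "regions_complete": complete,
            "sense_fraction": sf,
            "junction_count": n_junc,
        })
    df = pd.DataFrame(rows).set_index("gene_id")
    df["tier"] = tier_hosts(df["aub_rpm"], c.tier_thresholds)
    df["call"] = call_hosts(df, c)
    return df
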