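"""Read processing: adapter trimming, size selection, matching, hierarchical
classification and normalization.

The classification follows the sequential policy used for testis small-RNA
libraries: reads mapping to annotated rRNA/tRNA/miRNA/sn/snoRNA loci are
excluded as non-piRNAs; remaining reads are claimed in order by piRNA
clusters, then transposon consensus sequences, then the genome, where a read
whose best hits touch more than one gene is discarded while multimappers
within a single gene are kept at a seeded random position ("mapped
randomly").  An independent (non-sequential) cluster/TE mode is available
for between-library abundance comparisons.

The internal matcher reports all end-to-end placements of a read (no
clipping, substitutions only) at identity ≥ a similarity threshold; it is a
k-mer-seeded scanner adequate for toy references, not a general aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_io import CoverageTrack, GeneModel, GenomeAssets, Read, revcomp

__all__ = [
    "trim_adapter",
    "size_select",
    "match_reads",
    "ReferenceIndex",
    "Hit",
    "ReadAssignment",
    "ClassifyPolicy",
    "classify_hierarchical",
    "LibraryProfile",
    "quantify",
    "quantify_transcript_reads",
    "coverage_from_assignments",
    "assignments_frame",
]

ADAPTER_ILLUMINA = "AGATCGGAAGAGCACACGTCT"


# ---------------------------------------------------------------------------
# Trimming and size selection
# ---------------------------------------------------------------------------


@dataclass
class TrimResult:
    reads: list[Read]
    n_no_adapter: int = 0
    n_empty_dropped: int = 0
    no_adapter_ids: list[str] = field(default_factory=list)


def trim_adapter(reads: Iterable[Read], adapter: str) -> TrimResult:
    """Keep the longest prefix before the leftmost adapter occurrence.

    Reads without the adapter are kept whole and flagged; reads that begin
    with the adapter (empty insert) are dropped.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    out: list[Read] = []
    res = TrimResult(out)
    for r in reads:
        i = r.seq.find(adapter)
        if i < 0:
            res.n_no_adapter += 1
            res.no_adapter_ids.append(r.read_id)
            out.append(r)
        elif i == 0:
            res.n_empty_dropped += 1
        else:
            out.append(Read(r.read_id, r.seq[:i]))
    return res


def size_select(
    reads: Sequence[Read], min_len: int, max_len: int
) -> tuple[list[Read], int]:
    """Retain reads with min_len ≤ length ≤ max_len; return (kept, n_removed)."""
    if not 0 < min_len <= max_len:
        raise ValueError("need 0 < min_len <= max_len")
    kept = [r for r in reads if min_len <= len(r.seq) <= max_len]
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hit:
    ref: str
    pos: int
    strand: str  # strand of the reference the read agrees with
    identity: float
    mismatches: int


class ReferenceIndex:
    """Exact-seed index over a set of reference sequences.

    Supports exact end-to-end lookup in O(1) per read via a k-mer table and
    a numpy substitution scan for mismatch-tolerant search.
    """

    def __init__(self, sequences: dict[str, str], k: int = 16):
        self.k = k
        self.sequences = dict(sequences)
        self._table: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(sequences):
            seq = sequences[name]
            for i in range(len(seq) - k + 1):
                self._table.setdefault(seq[i:i + k], []).append((name, i))
        self._arrays = {
            name: np.frombuffer(sequences[name].encode(), dtype=np.uint8)
            for name in sorted(sequences)
        }

    def _exact_one_strand(self, seq: str) -> list[tuple[str, int]]:
        if len(seq) < self.k:
            # rare short query: fall back to scanning
            out = []
            for name in sorted(self.sequences):
                ref = self.sequences[name]
                j = ref.find(seq)
                while j >= 0:
                    out.append((name, j))
                    j = ref.find(seq, j + 1)
            return out
        out = []
        for name, i in self._table.get(seq[: self.k], ()):
            if self.sequences[name][i:i + len(seq)] == seq:
                out.append((name, i))
        return out

    def exact(self, seq: str, strand_mode: str = "both") -> list[Hit]:
        hits = []
        if strand_mode in ("both", "forward"):
            hits += [Hit(n, p, "+", 1.0, 0) for n, p in self._exact_one_strand(seq)]
        if strand_mode in ("both", "reverse"):
            hits += [
                Hit(n, p, "-", 1.0, 0)
                for n, p in self._exact_one_strand(revcomp(seq))
            ]
        hits.sort(key=lambda h: (h.ref, h.pos, h.strand))
        return hits

    def scan(self, seq: str, min_similarity: float,
             strand_mode: str = "both") -> list[Hit]:
        """All end-to-end placements with identity ≥ min_similarity
        (substitutions only, full read length required)."""
        L = len(seq)
        max_mm = int(np.floor(L * (1.0 - min_similarity) + 1e-9))
        queries = []
        if strand_mode in ("both", "forward"):
            queries.append((np.frombuffer(seq.encode(), np.uint8), "+"))
        if strand_mode in ("both", "reverse"):
            queries.append((np.frombuffer(revcomp(seq).encode(), np.uint8), "-"))
        hits: list[Hit] = []
        for q, strand in queries:
            for name in sorted(self._arrays):
                ref = self._arrays[name]
                n = len(ref) - L + 1
                if n <= 0:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(ref, L)
                mm = (windows != q).sum(axis=1)
                for pos in np.flatnonzero(mm <= max_mm):
                    m = int(mm[pos])
                    hits.append(Hit(name, int(pos), strand, (L - m) / L, m))
        hits.sort(key=lambda h: (-h.identity, h.ref, h.pos, h.strand))
        return hits

    def search(self, seq: str, min_similarity: float = 1.0,
               strand_mode: str = "both") -> list[Hit]:
        if min_similarity >= 1.0:
            return self.exact(seq, strand_mode)
        return self.scan(seq, min_similarity, strand_mode)


def match_reads(
    reads: Sequence[Read],
    reference: dict[str, str],
    min_similarity: float = 1.0,
    strand_mode: str = "both",
    index: ReferenceIndex | None = None,
) -> dict[str, list[Hit]]:
    """All end-to-end placements of each read, ranked by identity."""
    if not 0.0 < min_similarity <= 1.0:
        raise ValueError("min_similarity must be in (0, 1]")
    if not reference:
        raise ValueError("empty reference")
    idx = index or ReferenceIndex(reference)
    cache: dict[str, list[Hit]] = {}
    out = {}
    for r in reads:
        if r.seq not in cache:
            cache[r.seq] = idx.search(r.seq, min_similarity, strand_mode)
        out[r.read_id] = cache[r.seq]
    return out


# ---------------------------------------------------------------------------
# Hierarchical classification
# ---------------------------------------------------------------------------


@dataclass
class ReadAssignment:
    read_id: str
    sequence: str
    length: int
    cls: str  # non_piRNA | cluster | TE | genic | unassigned
    locus: str = ""
    chrom: str = ""
    pos: int = -1
    strand: str = "."
    identity: float = 0.0


@dataclass
class ClassifyPolicy:
    """Options for the hierarchical classifier.

    ``tier_mode='sequential'`` reproduces the non-piRNA → cluster → TE →
    genome order; ``'independent'`` maps cluster and TE tiers separately on
    all reads remaining after non-piRNA removal (between-library comparison
    mode).  ``nonpirna_mode`` selects positional overlap of exact genome
    hits with annotated loci (default) or sequence identity to the locus
    sequences.
    """

    min_similarity: float = 1.0
    tier_mode: str = "sequential"
    nonpirna_mode: str = "positional"
    seed: int = 0


class _Annot:
    """Prebuilt interval trees and indexes for one asset bundle."""

    def __init__(self, assets: GenomeAssets, policy: ClassifyPolicy):
        self.assets = assets
        self.genome_index = ReferenceIndex(assets.sequences)
        self.te_index = (ReferenceIndex(assets.te_consensus)
                         if assets.te_consensus else None)
        self.cluster_trees: dict[str, IntervalTree] = {}
        for loc in assets.clusters:
            self.cluster_trees.setdefault(loc.chrom, IntervalTree()).addi(
                loc.start, loc.end, loc.name)
        self.nonpirna_trees: dict[str, IntervalTree] = {}
        for loc in assets.non_pirna:
            self.nonpirna_trees.setdefault(loc.chrom, IntervalTree()).addi(
                loc.start, loc.end, loc.name)
        self.exon_trees: dict[str, IntervalTree] = {}
        for g in assets.genes:
            tree = self.exon_trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                tree.addi(s, e, g.gene_id)
        self.nonpirna_index = None
        if policy.nonpirna_mode == "sequence" and assets.non_pirna:
            seqs = {
                loc.name: assets.sequences[loc.chrom][loc.start:loc.end]
                for loc in assets.non_pirna
            }
            self.nonpirna_index = ReferenceIndex(seqs, k=12)

    def overlapping(self, trees, hit: Hit, length: int) -> list:
        tree = trees.get(hit.ref)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(hit.pos, hit.pos + length)})


def classify_hierarchical(
    reads: Sequence[Read],
    assets: GenomeAssets,
    policy: ClassifyPolicy | None = None,
    rng: np.random.Generator | None = None,
    annot: "_Annot | None" = None,
) -> list[ReadAssignment]:
    """Assign each read to exactly one class (or unassigned).

    Ambiguity inside a tier is resolved by a uniform seeded draw among
    maximal-identity hits, so identical inputs and seed give identical
    assignments.
    """
    policy = policy or ClassifyPolicy()
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    ann = annot or _Annot(assets, policy)

    # per unique sequence: precompute hits once
    genome_hits: dict[str, list[Hit]] = {}
    te_hits: dict[str, list[Hit]] = {}
    for r in reads:
        if r.seq not in genome_hits:
            genome_hits[r.seq] = ann.genome_index.search(
                r.seq, policy.min_similarity, "both")
            te_hits[r.seq] = (ann.te_index.search(
                r.seq, policy.min_similarity, "both") if ann.te_index else [])

    def best(hits: list[Hit]) -> list[Hit]:
        if not hits:
            return hits
        top = max(h.identity for h in hits)
        return [h for h in hits if h.identity == top]

    def pick(hits: list[Hit]) -> Hit:
        if len(hits) == 1:
            return hits[0]
        return hits[int(rng.integers(0, len(hits)))]

    out: list[ReadAssignment] = []
    for r in reads:
        L = len(r.seq)
        ghits = genome_hits[r.seq]
        gbest = best(ghits)

        # tier 1: non-piRNA removal
        is_np = False
        np_locus = ""
        if policy.nonpirna_mode == "sequence" and ann.nonpirna_index is not None:
            nhits = ann.nonpirna_index.search(r.seq, policy.min_similarity, "both")
            if nhits:
                is_np, np_locus = True, nhits[0].ref
        else:
            for h in gbest:
                loci = ann.overlapping(ann.nonpirna_trees, h, L)
                if loci:
                    is_np, np_locus = True, loci[0]
                    break
        if is_np:
            out.append(ReadAssignment(r.read_id, r.seq, L, "non_piRNA",
                                      locus=np_locus))
            continue

        # tier 2: piRNA clusters (genomic hits inside cluster intervals)
        cl_hits = [h for h in gbest
                   if ann.overlapping(ann.cluster_trees, h, L)]
        te_best = best(te_hits[r.seq])
        if policy.tier_mode == "sequential":
            if cl_hits:
                h = pick(cl_hits)
                name = ann.overlapping(ann.cluster_trees, h, L)[0]
                out.append(ReadAssignment(r.read_id, r.seq, L, "cluster",
                                          locus=name, chrom=h.ref, pos=h.pos,
                                          strand=h.strand, identity=h.identity))
                continue
            if te_best:
                h = pick(te_best)
                out.append(ReadAssignment(r.read_id, r.seq, L, "TE",
                                          locus=h.ref, chrom="", pos=h.pos,
                                          strand=h.strand, identity=h.identity))
                continue
        else:  # independent: claim by whichever matches, cluster named first
            if cl_hits or te_best:
                if cl_hits:
                    h = pick(cl_hits)
                    name = ann.overlapping(ann.cluster_trees, h, L)[0]
                    out.append(ReadAssignment(r.read_id, r.seq, L, "cluster",
                                              locus=name, chrom=h.ref,
                                              pos=h.pos, strand=h.strand,
                                              identity=h.identity))
                else:
                    h = pick(te_best)
                    out.append(ReadAssignment(r.read_id, r.seq, L, "TE",
                                              locus=h.ref, pos=h.pos,
                                              strand=h.strand,
                                              identity=h.identity))
                continue

        # tier 3: genome → genic
        gene_hits = [(h, ann.overlapping(ann.exon_trees, h, L)) for h in gbest]
        gene_hits = [(h, gids) for h, gids in gene_hits if gids]
        gene_ids = sorted({g for _h, gids in gene_hits for g in gids})
        if not gene_hits:
            out.append(ReadAssignment(r.read_id, r.seq, L, "unassigned"))
            continue
        if len(gene_ids) > 1 or any(len(gids) > 1 for _h, gids in gene_hits):
            # best hits span more than one gene: discarded
            out.append(ReadAssignment(r.read_id, r.seq, L, "unassigned",
                                      locus="multi_gene"))
            continue
        h = pick([h for h, _ in gene_hits])
        out.append(ReadAssignment(r.read_id, r.seq, L, "genic",
                                  locus=gene_ids[0], chrom=h.ref, pos=h.pos,
                                  strand=h.strand, identity=h.identity))
    return out


def read_assignments_tsv(path) -> list[ReadAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "chrom": str},
                     keep_default_na=False)
    return [
        ReadAssignment(r.read_id, r.sequence, int(r.length), r.cls,
                       locus=r.locus, chrom=r.chrom, pos=int(r.pos),
                       strand=r.strand, identity=float(r.identity))
        for r in df.itertuples()
    ]


def assignments_frame(assignments: Sequence[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.read_id, a.sequence, a.length, a.cls, a.locus, a.chrom, a.pos,
          a.strand, a.identity) for a in assignments],
        columns=["read_id", "sequence", "length", "cls", "locus", "chrom",
                 "pos", "strand", "identity"],
    )


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


@dataclass
class LibraryProfile:
    """Per-class and per-gene abundances for one library.

    ``genes`` is a DataFrame indexed by gene_id with raw counts (total,
    per region, per strand), RPK, TPM and RPM columns.  RPM uses reads
    remaining after non-piRNA removal as denominator; TPM normalizes
    exon-mapping reads per kilobase so gene TPMs sum to 1e6.
    """

    library: str
    total_raw: int
    size_selected: int
    total_after_nonpirna: int
    class_counts: dict
    genes: pd.DataFrame
    class_rpm: dict = field(default_factory=dict)

    def conservation_ok(self) -> bool:
        return sum(self.class_counts.values()) == self.size_selected


def _read_5p_region(gene: GeneModel, a: ReadAssignment) -> tuple[str | None, bool]:
    """(region of the read's 5'-end base, read is sense to the gene)."""
    five = a.pos if a.strand == "+" else a.pos + a.length - 1
    return gene.region_of(five), a.strand == gene.strand


def quantify(
    assignments: Sequence[ReadAssignment],
    assets: GenomeAssets,
    library: str = "library",
    total_raw: int | None = None,
) -> LibraryProfile:
    """Build a LibraryProfile from classified assignments.

    A read is attributed to the region (5'UTR/CDS/3'UTR) containing its
    5'-end base, and to sense/antisense relative to the gene strand.
    """
    class_counts: dict[str, int] = {}
    for a in assignments:
        class_counts[a.cls] = class_counts.get(a.cls, 0) + 1
    size_selected = len(assignments)
    denom = size_selected - class_counts.get("non_piRNA", 0)

    gene_by_id = {g.gene_id: g for g in assets.genes}
    idx = sorted(gene_by_id)
    cols = ["count", "utr5", "cds", "utr3", "sense", "antisense"]
    acc = {gid: dict.fromkeys(cols, 0) for gid in idx}
    for a in assignments:
        if a.cls != "genic":
            continue
        g = gene_by_id[a.locus]
        region, sense = _read_5p_region(g, a)
        row = acc[a.locus]
        row["count"] += 1
        if region is not None:
            row[region] += 1
        row["sense" if sense else "antisense"] += 1
    genes = pd.DataFrame.from_dict(acc, orient="index", columns=cols)
    genes.index.name = "gene_id"

    exon_kb = pd.Series({gid: gene_by_id[gid].exon_length / 1e3 for gid in idx})
    if (exon_kb <= 0).any():
        raise ValueError("gene with zero exon length")
    genes["rpk"] = genes["count"] / exon_kb
    rpk_sum = genes["rpk"].sum()
    genes["tpm"] = genes["rpk"] * 1e6 / rpk_sum if rpk_sum > 0 else 0.0
    genes["rpm"] = genes["count"] * 1e6 / denom if denom > 0 else 0.0

    class_rpm = {
        cls: n * 1e6 / denom if denom > 0 else 0.0
        for cls, n in class_counts.items()
        if cls != "non_piRNA"
    }
    return LibraryProfile(
        library=library,
        total_raw=total_raw if total_raw is not None else size_selected,
        size_selected=size_selected,
        total_after_nonpirna=denom,
        class_counts=class_counts,
        genes=genes,
        class_rpm=class_rpm,
    )


def quantify_transcript_reads(
    reads: Sequence[Read],
    assets: GenomeAssets,
    library: str = "mrna",
    index: ReferenceIndex | None = None,
) -> pd.DataFrame:
    """Per-gene counts/RPK/TPM for transcript-space reads (mRNA-seq or
    degradome).  Reads matching transcripts of more than one gene are
    discarded."""
    tx_seqs = {gid: t.seq for gid, t in sorted(assets.transcripts.items())}
    idx = index or ReferenceIndex(tx_seqs)
    counts = dict.fromkeys(tx_seqs, 0)
    cache: dict[str, str | None] = {}
    for r in reads:
        if r.seq not in cache:
            hits = idx.search(r.seq, 1.0, "forward")
            gids = sorted({h.ref for h in hits})
            cache[r.seq] = gids[0] if len(gids) == 1 else None
        gid = cache[r.seq]
        if gid is not None:
            counts[gid] += 1
    df = pd.DataFrame({"count": pd.Series(counts)})
    df.index.name = "gene_id"
    exon_kb = pd.Series({g.gene_id: g.exon_length / 1e3 for g in assets.genes})
    df["rpk"] = df["count"] / exon_kb
    s = df["rpk"].sum()
    df["tpm"] = df["rpk"] * 1e6 / s if s > 0 else 0.0
    return df.sort_index()


def coverage_from_assignments(
    assignments: Sequence[ReadAssignment],
    assets: GenomeAssets,
    total_after_nonpirna: int | None = None,
    strand_split: bool = False,
) -> CoverageTrack:
    """Per-base depth over positioned read spans with RPM scaling."""
    if total_after_nonpirna is None:
        total_after_nonpirna = sum(
            1 for a in assignments if a.cls != "non_piRNA"
        )
    values: dict = {}
    for chrom, seq in assets.sequences.items():
        if strand_split:
            values[(chrom, "+")] = np.zeros(len(seq))
            values[(chrom, "-")] = np.zeros(len(seq))
        else:
            values[chrom] = np.zeros(len(seq))
    for a in assignments:
        if a.pos < 0 or a.chrom not in assets.sequences:
            continue
        key = (a.chrom, a.strand) if strand_split else a.chrom
        values[key][a.pos:a.pos + a.length] += 1
    scale = 1e6 / total_after_nonpirna if total_after_nonpirna else 1.0
    return CoverageTrack(values=values, scaling_factor=scale)
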