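"""Synthetic reference assets and small-RNA libraries with planted ground truth.

The generator emulates the features of a testis small-RNA compartment that the
downstream analyses exploit:

* a toy genome carrying protein-coding genes with 5'UTR/CDS/3'UTR/intron
  structure, piRNA cluster loci (seeded with transposon fragments),
  transposon consensus sequences, and annotated non-piRNA loci
  (rRNA/tRNA/miRNA/sn/snoRNA);
* *host genes* that produce 23–29-nt piRNAs with a 24–26-nt mode, 5'-uridine
  bias, sense-strand dominance, CDS-biased origin and rare exon-junction
  reads, alongside *decoy genes* that only shed broad 18–29-nt mRNA decay
  fragments whose rate scales with mRNA level;
* immunoprecipitation libraries in which piRNA classes (host/cluster/TE) are
  enriched over the decay background by a per-protein factor;
* planted trigger small RNAs whose responders begin exactly at the position
  giving a 10-nt 5'-to-5' complementary overlap, with the trigger's 11th
  nucleotide pairing the transcript base 5' of the cleavage site;
* head-to-tail phased read trains (next 5' end one base past the previous
  3' end) with a uridine preference at train boundaries;
* mutant libraries with class-specific depletion factors;
* matched mRNA-seq and degradome libraries, the latter with 5' ends at the
  planted cleavage positions plus a uniform background.

Every read is logged in a truth table; identical spec + seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GenomeAssets,
    Locus,
    Read,
    Transcript,
    TriggerRecord,
    child_rng,
    revcomp,
)

__all__ = [
    "SimulationSpec",
    "build_toy_assets",
    "simulate_srna_library",
    "simulate_mrna_and_degradome",
    "host_gene_ids",
    "phased_gene_ids",
    "expression_levels",
    "planted_responder_sites",
    "simulate_spectral_counts",
]

_BASES = np.array(list("ACGT"))

# fixed sub-stream keys so per-gene parameters agree across libraries
_KEY_GENOME = 101
_KEY_EXPRESSION = 102
_KEY_HOSTWEIGHT = 103


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with defaults defining the
    standard simulated conditions.

    Counts in ``class_read_counts`` are raw per-library read numbers before
    adapter trimming/size selection; ``decay`` fragments draw lengths from a
    short-skewed (geometrically decreasing) 18–29-nt ladder, so only ~28%
    of them survive the 23–29-nt piRNA window.
    """

    seed: int = 0

    # --- toy genome -------------------------------------------------------
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_host_genes: int = 20
    n_decoy_genes: int = 200
    utr5_range: tuple[int, int] = (100, 200)
    cds_range: tuple[int, int] = (900, 1400)
    utr3_range: tuple[int, int] = (150, 350)
    n_introns_range: tuple[int, int] = (1, 3)
    intron_range: tuple[int, int] = (60, 200)
    intergenic_range: tuple[int, int] = (50, 400)
    n_cluster_loci: int = 3
    cluster_length: int = 5_000
    n_te_families: int = 5
    te_length: int = 3_000
    n_non_pirna_loci: int = 15
    non_pirna_length_range: tuple[int, int] = (80, 500)

    # --- planted structure ------------------------------------------------
    n_phased_genes: int = 4
    plant_repeat_gene: bool = True
    repeat_unit_length: int = 300
    repeat_copies: int = 3
    repeat_gene_sense_fraction: float = 0.1
    trigger_responder_counts: tuple[int, ...] = (200, 150, 100, 50, 25, 5)
    n_decoy_triggers: int = 4

    # --- expression model -------------------------------------------------
    expression_sigma: float = 0.5
    host_expression_scale: float = 0.05
    host_weight_range: tuple[float, float] = (0.7, 1.3)

    # --- sRNA library composition ----------------------------------------
    class_read_counts: dict = field(
        default_factory=lambda: {
            "host_pirna": 6_000,
            "decay": 37_000,
            "cluster": 4_000,
            "te": 3_000,
            "non_pirna": 3_000,
        }
    )
    pirna_len_dist: dict = field(
        default_factory=lambda: {
            23: 0.05, 24: 0.25, 25: 0.30, 26: 0.25, 27: 0.10, 28: 0.04, 29: 0.01,
        }
    )
    first_nt_u_prob: float = 0.8
    sense_fraction: float = 0.95
    junction_read_fraction: float = 0.05
    junction_anchor: int = 4
    region_read_fractions: dict = field(
        default_factory=lambda: {"utr5": 0.05, "cds": 0.85, "utr3": 0.10}
    )
    decay_len_range: tuple[int, int] = (18, 29)
    decay_len_geom: float = 0.8  # per-nt weight ratio: short-skewed ladder
    ip_enrichment: dict = field(default_factory=lambda: {"Aub": 20.0, "Piwi": 3.0})
    depletion: dict = field(default_factory=dict)
    phased_skip_prob: float = 0.15

    # --- mRNA / degradome -------------------------------------------------
    mrna_depth: int = 50_000
    mrna_read_length: int = 50
    degradome_background: int = 5_000
    degradome_site_reads: int = 50
    degradome_read_length: int = 30

    @classmethod
    def default(cls) -> "SimulationSpec":
        """The standard screen conditions (20 hosts, 200 decoys)."""
        return cls()

    @classmethod
    def mutant_default(cls) -> "SimulationSpec":
        """Aub-IP-like composition for mutant comparisons.

        Cluster/TE piRNAs dominate the library, as in real Aub-bound piRNA
        data, so the exon-mapper class is a small share of the RPM
        denominator and class-specific depletion leaves cluster/TE RPM
        essentially unchanged.
        """
        return cls(
            class_read_counts={
                "host_pirna": 4_000,
                "decay": 2_000,
                "cluster": 55_000,
                "te": 25_000,
                "non_pirna": 3_000,
            },
            n_phased_genes=0,
            trigger_responder_counts=(),
            n_decoy_triggers=0,
        )

    @classmethod
    def small(cls) -> "SimulationSpec":
        """A down-scaled spec for fast unit tests."""
        return cls(
            n_chroms=1,
            chrom_length=80_000,
            n_host_genes=4,
            n_decoy_genes=12,
            n_cluster_loci=1,
            n_te_families=2,
            n_non_pirna_loci=4,
            n_phased_genes=1,
            trigger_responder_counts=(40, 5),
            n_decoy_triggers=1,
            class_read_counts={
                "host_pirna": 1_500,
                "decay": 3_000,
                "cluster": 600,
                "te": 400,
                "non_pirna": 400,
            },
            mrna_depth=5_000,
            degradome_background=1_000,
        )

    def validate(self) -> None:
        for name, p in (
            ("first_nt_u_prob", self.first_nt_u_prob),
            ("sense_fraction", self.sense_fraction),
            ("junction_read_fraction", self.junction_read_fraction),
            ("phased_skip_prob", self.phased_skip_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if any(c < 0 for c in self.class_read_counts.values()):
            raise ValueError("read counts must be >= 0")
        if any(f <= 0 for f in self.depletion.values()):
            raise ValueError("depletion factors must be > 0")
        if abs(sum(self.pirna_len_dist.values()) - 1.0) > 1e-9:
            raise ValueError("pirna_len_dist must sum to 1")


def _stable_key(label: str) -> int:
    """Process-stable small-integer key for a text label."""
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


def host_gene_ids(spec: SimulationSpec) -> list[str]:
    return [f"host{i + 1:02d}" for i in range(spec.n_host_genes)]


def phased_gene_ids(spec: SimulationSpec) -> list[str]:
    return host_gene_ids(spec)[: spec.n_phased_genes]


def _repeat_gene_id(spec: SimulationSpec) -> str | None:
    """The muc14A-like repeat-bearing, antisense-dominant host gene."""
    if not spec.plant_repeat_gene:
        return None
    idx = spec.n_phased_genes  # first non-phased host
    if idx >= spec.n_host_genes:
        return None
    return host_gene_ids(spec)[idx]


def expression_levels(spec: SimulationSpec) -> pd.Series:
    """Deterministic per-gene mRNA expression weights (lognormal).

    Host genes are scaled down by ``host_expression_scale``: piRNA
    production is modeled as uncoupled from mRNA abundance.
    """
    rng = child_rng(spec.seed, _KEY_EXPRESSION)
    ids = host_gene_ids(spec) + [
        f"dec{i + 1:03d}" for i in range(spec.n_decoy_genes)
    ]
    levels = np.exp(rng.normal(0.0, spec.expression_sigma, size=len(ids)))
    levels[: spec.n_host_genes] *= spec.host_expression_scale
    return pd.Series(levels, index=ids)


def _host_weights(spec: SimulationSpec) -> pd.Series:
    rng = child_rng(spec.seed, _KEY_HOSTWEIGHT)
    lo, hi = spec.host_weight_range
    ids = host_gene_ids(spec)
    return pd.Series(rng.uniform(lo, hi, size=len(ids)), index=ids)


# ---------------------------------------------------------------------------
# Asset construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _make_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, cursor: int,
    spec: SimulationSpec, strand: str,
) -> tuple[GeneModel, int]:
    """Lay out one gene starting at ``cursor``; return (gene, new cursor)."""
    u5 = int(rng.integers(*spec.utr5_range))
    cds = int(rng.integers(*spec.cds_range))
    u3 = int(rng.integers(*spec.utr3_range))
    tlen = u5 + cds + u3
    n_introns = int(rng.integers(spec.n_introns_range[0], spec.n_introns_range[1] + 1))
    # split the mature transcript into exons at internal cut points
    cuts = sorted(rng.choice(np.arange(40, tlen - 40), size=n_introns, replace=False))
    exon_lens = np.diff([0] + [int(c) for c in cuts] + [tlen])
    intron_lens = rng.integers(*spec.intron_range, size=n_introns)
    exons: list[tuple[int, int]] = []
    pos = cursor
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_introns:
            pos += int(intron_lens[i])
    # region boundaries in plus-strand transcript coordinates
    if strand == "+":
        bounds = [("utr5_span", 0, u5), ("cds_span", u5, u5 + cds),
                  ("utr3_span", u5 + cds, tlen)]
    else:  # 5'UTR is at the right end of the plus-strand layout
        bounds = [("utr3_span", 0, u3), ("cds_span", u3, u3 + cds),
                  ("utr5_span", u3 + cds, tlen)]
    spans: dict[str, list[tuple[int, int]]] = {k: [] for k, _, _ in bounds}
    off = 0
    for es, ee in exons:
        elen = ee - es
        for key, a, b in bounds:
            lo, hi = max(a, off), min(b, off + elen)
            if lo < hi:
                spans[key].append((es + (lo - off), es + (hi - off)))
        off += elen
    gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     exons=exons, **spans)
    return gene, pos


def build_toy_assets(spec: SimulationSpec) -> GenomeAssets:
    """Build a deterministic toy reference bundle from a simulation spec."""
    spec.validate()
    rng = child_rng(spec.seed, _KEY_GENOME)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    seqs = {c: np.array(list(_random_seq(rng, spec.chrom_length))) for c in chrom_names}

    te = {f"TE{i + 1}": _random_seq(rng, spec.te_length)
          for i in range(spec.n_te_families)}

    gene_ids = host_gene_ids(spec) + [
        f"dec{i + 1:03d}" for i in range(spec.n_decoy_genes)
    ]
    placement = list(gene_ids)
    rng.shuffle(placement)

    repeat_gid = _repeat_gene_id(spec)
    genes: list[GeneModel] = []
    clusters: list[Locus] = []
    non_pirna: list[Locus] = []
    cursors = {c: 100 for c in chrom_names}
    ci = 0

    def _advance(chrom: str, n: int) -> int:
        start = cursors[chrom] + int(rng.integers(*spec.intergenic_range))
        if start + n > spec.chrom_length - 100:
            need = start + n - spec.chrom_length + 200
            raise ValueError(
                f"chromosome {chrom} too short to place loci; increase "
                f"chrom_length by ≥{need} bp or reduce locus counts"
            )
        cursors[chrom] = start + n
        return start

    # piRNA clusters, each seeded with a transposon fragment (TE remnant)
    for i in range(spec.n_cluster_loci):
        chrom = chrom_names[ci % len(chrom_names)]
        ci += 1
        start = _advance(chrom, spec.cluster_length)
        clusters.append(Locus(chrom, start, start + spec.cluster_length,
                              f"cluster{i + 1}", "+", "cluster"))
        frag = te[f"TE{(i % spec.n_te_families) + 1}"][:500]
        fpos = start + 1000
        seqs[chrom][fpos:fpos + len(frag)] = list(frag)

    # non-piRNA loci
    kinds = ["rRNA", "tRNA", "miRNA", "snRNA", "snoRNA"]
    for i in range(spec.n_non_pirna_loci):
        chrom = chrom_names[ci % len(chrom_names)]
        ci += 1
        length = int(rng.integers(*spec.non_pirna_length_range))
        start = _advance(chrom, length)
        kind = kinds[i % len(kinds)]
        non_pirna.append(Locus(chrom, start, start + length,
                               f"{kind.lower()}{i + 1}", "+", kind))

    # genes
    for gid in placement:
        chrom = chrom_names[ci % len(chrom_names)]
        ci += 1
        strand = "+" if (gid == repeat_gid or rng.random() < 0.5) else "-"
        # reserve worst-case span, then lay out
        worst = (spec.utr5_range[1] + spec.cds_range[1] + spec.utr3_range[1]
                 + spec.n_introns_range[1] * spec.intron_range[1])
        start = _advance(chrom, worst)
        cursors[chrom] = start  # _make_gene advances precisely
        gene, end = _make_gene(rng, gid, chrom, start, spec, strand)
        cursors[chrom] = end
        genes.append(gene)

    genes.sort(key=lambda g: g.gene_id)
    sequences = {c: "".join(a) for c, a in seqs.items()}
    assets = GenomeAssets(sequences=sequences, genes=genes, clusters=clusters,
                          te_consensus=te, non_pirna=non_pirna)

    # plant a tandem repeat inside the repeat gene's CDS (muc14A-like)
    if repeat_gid is not None:
        gene = assets.gene(repeat_gid)
        tx = assets.transcripts[repeat_gid]
        u5 = gene.region_lengths()["utr5"]
        unit = _random_seq(rng, spec.repeat_unit_length)
        arr = np.array(list(sequences[gene.chrom]))
        for c in range(spec.repeat_copies):
            t0 = u5 + 50 + c * spec.repeat_unit_length
            for j, base in enumerate(unit):
                arr[gene.transcript_to_genomic(t0 + j)] = base  # '+' strand gene
        sequences[gene.chrom] = "".join(arr)
        assets = GenomeAssets(sequences=sequences, genes=genes,
                              clusters=clusters, te_consensus=te,
                              non_pirna=non_pirna)

    # planted triggers: 21-nt siRNAs antisense to host CDS sites
    triggers: list[TriggerRecord] = []
    hosts = host_gene_ids(spec)
    site_hosts = [g for g in hosts
                  if g not in phased_gene_ids(spec) and g != repeat_gid]
    if spec.trigger_responder_counts and not site_hosts:
        raise ValueError("no non-phased host genes available for trigger sites")
    for i, _count in enumerate(spec.trigger_responder_counts):
        gid = site_hosts[i % len(site_hosts)]
        gene = assets.gene(gid)
        tx = assets.transcripts[gid]
        u5 = gene.region_lengths()["utr5"]
        p = u5 + 120 + 60 * (i // len(site_hosts))  # responder 5' end

        def usable(pos: int) -> bool:
            # uridine 5' end, and responder/guide windows clear of
            # exon-exon junctions so the reads map contiguously to genome
            if tx.seq[pos] != "T":
                return False
            return not any(pos - 11 < j < pos + 35 for j in tx.junctions)

        while p < len(tx.seq) - 40 and not usable(p):
            p += 1
        trig = revcomp(tx.seq[p - 11:p + 10])
        triggers.append(TriggerRecord(f"sirna_t{i + 1}", trig, "siRNA"))
    rng_dec = child_rng(spec.seed, _KEY_GENOME, 7)
    for i in range(spec.n_decoy_triggers):
        triggers.append(
            TriggerRecord(f"sirna_d{i + 1}", _random_seq(rng_dec, 21), "siRNA")
        )
    assets.triggers = triggers
    assets.validate()
    return assets


def planted_responder_sites(
    assets: GenomeAssets, spec: SimulationSpec
) -> list[tuple[TriggerRecord, str, int]]:
    """Recover (trigger, host gene, responder 5' transcript offset) for every
    trigger whose full 21-nt antisense match lies in a host transcript."""
    sites = []
    hosts = set(host_gene_ids(spec))
    for trig in assets.triggers:
        target = revcomp(trig.seq)  # transcript [p-11, p+10)
        for gid in sorted(hosts):
            tx = assets.transcripts[gid]
            j = tx.seq.find(target)
            if j >= 0:
                sites.append((trig, gid, j + 11))
                break
    return sites


# ---------------------------------------------------------------------------
# sRNA library simulation
# ---------------------------------------------------------------------------


def _len_sampler(spec: SimulationSpec):
    lens = np.array(sorted(spec.pirna_len_dist), dtype=int)
    probs = np.array([spec.pirna_len_dist[int(l)] for l in lens])
    probs = probs / probs.sum()
    return lens, probs


def _truth_row(read_id, library, origin, gene_id, locus, strand, chrom,
               start, end, length, is_junction=False, responder_of="",
               phased_train=-1):
    return (read_id, library, origin, gene_id, locus, strand, chrom,
            int(start), int(end), int(length), bool(is_junction),
            responder_of, int(phased_train))

_TRUTH_COLS = ["read_id", "library", "origin", "gene_id", "locus", "strand",
               "chrom", "start", "end", "length", "is_junction",
               "responder_of", "phased_train"]


def _genomic_span(gene: GeneModel, t_start: int, t_end_incl: int) -> tuple[int, int]:
    a = gene.transcript_to_genomic(t_start)
    b = gene.transcript_to_genomic(t_end_incl)
    lo, hi = min(a, b), max(a, b)
    return lo, hi + 1


def _draw_with_first_nt(rng, cand: np.ndarray, first: np.ndarray,
                        want_u: bool) -> int:
    """Draw a start position conditioning on the first-base class.

    ``want_u`` selects among uridine starts, otherwise among the rest, so
    the marginal 5'U fraction equals the planted probability exactly.
    Falls back to the full candidate set when the requested class is empty.
    """
    pool = cand[first] if want_u else cand[~first]
    if len(pool) == 0:
        pool = cand
    return int(pool[rng.integers(0, len(pool))])


def _sample_host_read(rng, spec, gene: GeneModel, tx: Transcript,
                      lens, lprobs, sense_fraction: float):
    """One host-gene piRNA: (t_start, length, sense, is_junction)."""
    tlen = len(tx.seq)
    L = int(rng.choice(lens, p=lprobs))
    sense = rng.random() < sense_fraction
    want_u = rng.random() < spec.first_nt_u_prob
    if tx.junctions and rng.random() < spec.junction_read_fraction:
        j = int(tx.junctions[rng.integers(0, len(tx.junctions))])
        lo = max(0, j - L + spec.junction_anchor)
        hi = min(tlen - L, j - spec.junction_anchor)
        if lo <= hi:
            cand = np.arange(lo, hi + 1)
            first = (np.array([tx.seq[c] for c in cand]) == "T" if sense else
                     np.array([tx.seq[c + L - 1] for c in cand]) == "A")
            s = _draw_with_first_nt(rng, cand, first, want_u)
            return s, L, sense, True
    # region-directed start
    r = rng.random()
    regions = spec.region_read_fractions
    u5, cds, u3 = (gene.region_lengths()[k] for k in ("utr5", "cds", "utr3"))
    if r < regions["utr5"]:
        lo, hi = 0, u5
    elif r < regions["utr5"] + regions["cds"]:
        lo, hi = u5, u5 + cds
    else:
        lo, hi = u5 + cds, tlen
    hi = min(hi, tlen - L + 1)
    lo = min(lo, hi - 1) if hi > 0 else 0
    cand = np.arange(lo, max(hi, lo + 1))
    seq_arr = np.frombuffer(tx.seq.encode(), dtype="S1")
    if sense:
        first = seq_arr[cand] == b"T"
    else:
        first = seq_arr[cand + L - 1] == b"A"
    s = _draw_with_first_nt(rng, cand, first, want_u)
    return s, L, sense, False


def _phased_train(rng, spec, tx: Transcript, lens, lprobs) -> list[tuple[int, int]]:
    """One head-to-tail train tiling the transcript: list of (t_start, length).

    The next 5' base is preferred to be uridine (Zuc-like cleavage 5' of U);
    occasional skips of 2–30 nt break the d=1 geometry at phased_skip_prob.
    """
    tlen = len(tx.seq)
    starts_t = [i for i, b in enumerate(tx.seq[:60]) if b == "T"]
    pos = starts_t[0] if starts_t else 0
    out = []
    u_boost = 40.0  # multiplicative preference for a uridine at the next 5'
    while pos + int(lens.max()) < tlen:
        w = np.array([
            spec.pirna_len_dist[int(L)]
            * (u_boost if tx.seq[pos + L] == "T" else 1.0)
            for L in lens
        ])
        L = int(rng.choice(lens, p=w / w.sum()))
        out.append((pos, L))
        pos += L
        if rng.random() < spec.phased_skip_prob:
            pos += int(rng.integers(2, 31))
            # Zuc-like resumption: the next piRNA starts at a uridine
            limit = min(pos + 30, tlen - 1)
            while pos < limit and tx.seq[pos] != "T":
                pos += 1
    return out


def simulate_srna_library(
    assets: GenomeAssets,
    spec: SimulationSpec,
    library: str,
    ip: str | None = None,
    depletion: dict | None = None,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate one small-RNA library.

    ``ip`` names an immunoprecipitated protein ('Aub' or 'Piwi'): piRNA
    classes (host/cluster/TE) are enriched by ``spec.ip_enrichment[ip]``
    relative to the decay and non-piRNA background.  ``depletion`` maps
    origin classes to multiplicative factors (mutant conditions); it
    overrides ``spec.depletion``.
    """
    spec.validate()
    rng = child_rng(spec.seed, _stable_key(library))
    depletion = dict(spec.depletion if depletion is None else depletion)
    lens, lprobs = _len_sampler(spec)
    hosts = host_gene_ids(spec)
    phased = set(phased_gene_ids(spec))
    repeat_gid = _repeat_gene_id(spec)
    expr = expression_levels(spec)
    hw = _host_weights(spec)

    weights = {}
    ipf = spec.ip_enrichment.get(ip, 1.0) if ip else 1.0
    for cls, n in spec.class_read_counts.items():
        w = float(n) * depletion.get(cls, 1.0)
        if cls in ("host_pirna", "cluster", "te"):
            w *= ipf
        weights[cls] = w
    classes = sorted(weights)
    depth = int(sum(spec.class_read_counts.values()))
    wvec = np.array([weights[c] for c in classes], dtype=float)
    counts = rng.multinomial(depth, wvec / wvec.sum())
    n_by_class = dict(zip(classes, (int(c) for c in counts)))

    reads: list[Read] = []
    rows: list[tuple] = []
    serial = 0

    def emit(seq: str, **kw) -> None:
        nonlocal serial
        rid = f"{library}:{serial:07d}"
        serial += 1
        reads.append(Read(rid, seq))
        rows.append(_truth_row(rid, library, **kw))

    # ---- host-gene piRNAs -------------------------------------------------
    n_host = n_by_class.get("host_pirna", 0)
    gw = hw.to_numpy()
    per_gene = rng.multinomial(n_host, gw / gw.sum()) if n_host else np.zeros(len(hosts), int)
    train_counter = 0
    for gid, n_g in zip(hosts, per_gene):
        if n_g == 0:
            continue
        gene = assets.gene(gid)
        tx = assets.transcripts[gid]
        if gid in phased:
            train = _phased_train(rng, spec, tx, lens, lprobs)
            train_counter += 1
            alloc = rng.multinomial(n_g, np.full(len(train), 1.0 / len(train)))
            for (s, L), c in zip(train, alloc):
                seq = tx.seq[s:s + L]
                glo, ghi = _genomic_span(gene, s, s + L - 1)
                for _ in range(int(c)):
                    emit(seq, origin="host_pirna", gene_id=gid, locus=gid,
                         strand=gene.strand, chrom=gene.chrom, start=glo,
                         end=ghi, length=L, phased_train=train_counter)
            continue
        sf = (spec.repeat_gene_sense_fraction if gid == repeat_gid
              else spec.sense_fraction)
        for _ in range(int(n_g)):
            s, L, sense, junc = _sample_host_read(rng, spec, gene, tx,
                                                  lens, lprobs, sf)
            seq = tx.seq[s:s + L] if sense else revcomp(tx.seq[s:s + L])
            strand = gene.strand if sense else ("-" if gene.strand == "+" else "+")
            glo, ghi = _genomic_span(gene, s, s + L - 1)
            emit(seq, origin="host_pirna", gene_id=gid, locus=gid,
                 strand=strand, chrom=gene.chrom, start=glo, end=ghi,
                 length=L, is_junction=junc)

    # ---- planted responders ----------------------------------------------
    # responders are host-class piRNAs: they follow the realized host-class
    # sampling factor (IP enrichment, depletion, depth renormalization)
    sites = planted_responder_sites(assets, spec)
    base_host = spec.class_read_counts.get("host_pirna", 0)
    host_scale = (n_host / base_host) if base_host else 0.0
    for (trig, gid, p), n_resp in zip(sites, spec.trigger_responder_counts):
        gene = assets.gene(gid)
        tx = assets.transcripts[gid]
        n_eff = int(round(n_resp * host_scale))
        for _ in range(n_eff):
            L = int(rng.choice(lens, p=lprobs))
            L = min(L, len(tx.seq) - p)
            seq = tx.seq[p:p + L]
            glo, ghi = _genomic_span(gene, p, p + L - 1)
            emit(seq, origin="host_pirna", gene_id=gid, locus=gid,
                 strand=gene.strand, chrom=gene.chrom, start=glo, end=ghi,
                 length=L, responder_of=trig.name)

    # ---- decay fragments (rate ∝ mRNA level) ------------------------------
    n_decay = n_by_class.get("decay", 0)
    ev = expr.to_numpy()
    per_gene = rng.multinomial(n_decay, ev / ev.sum()) if n_decay else np.zeros(len(expr), int)
    dmin, dmax = spec.decay_len_range
    dlens = np.arange(dmin, dmax + 1)
    dprobs = spec.decay_len_geom ** (dlens - dmin)
    dprobs = dprobs / dprobs.sum()
    for gid, n_g in zip(expr.index, per_gene):
        if n_g == 0:
            continue
        gene = assets.gene(gid)
        tx = assets.transcripts[gid]
        tlen = len(tx.seq)
        Ls = rng.choice(dlens, p=dprobs, size=int(n_g))
        for L in Ls:
            L = int(min(L, tlen))
            s = int(rng.integers(0, tlen - L + 1))
            glo, ghi = _genomic_span(gene, s, s + L - 1)
            emit(tx.seq[s:s + L], origin="decay", gene_id=gid, locus=gid,
                 strand=gene.strand, chrom=gene.chrom, start=glo, end=ghi,
                 length=L)

    # ---- cluster piRNAs ---------------------------------------------------
    n_cluster = n_by_class.get("cluster", 0)
    if n_cluster and assets.clusters:
        clens = np.array([c.end - c.start for c in assets.clusters], float)
        alloc = rng.multinomial(n_cluster, clens / clens.sum())
        for loc, n_c in zip(assets.clusters, alloc):
            cseq = assets.sequences[loc.chrom][loc.start:loc.end]
            for _ in range(int(n_c)):
                L = int(rng.choice(lens, p=lprobs))
                s = int(rng.integers(0, len(cseq) - L + 1))
                sense = bool(rng.random() < 0.5)
                seq = cseq[s:s + L] if sense else revcomp(cseq[s:s + L])
                emit(seq, origin="cluster", gene_id="", locus=loc.name,
                     strand="+" if sense else "-", chrom=loc.chrom,
                     start=loc.start + s, end=loc.start + s + L, length=L)

    # ---- TE piRNAs --------------------------------------------------------
    n_te = n_by_class.get("te", 0)
    if n_te and assets.te_consensus:
        names = sorted(assets.te_consensus)
        alloc = rng.multinomial(n_te, np.full(len(names), 1.0 / len(names)))
        for name, n_t in zip(names, alloc):
            tseq = assets.te_consensus[name]
            for _ in range(int(n_t)):
                L = int(rng.choice(lens, p=lprobs))
                s = int(rng.integers(0, len(tseq) - L + 1))
                sense = bool(rng.random() < 0.5)
                seq = tseq[s:s + L] if sense else revcomp(tseq[s:s + L])
                emit(seq, origin="te", gene_id="", locus=name,
                     strand="+" if sense else "-", chrom="", start=s,
                     end=s + L, length=L)

    # ---- non-piRNA reads --------------------------------------------------
    n_np = n_by_class.get("non_pirna", 0)
    if n_np and assets.non_pirna:
        alloc = rng.multinomial(n_np, np.full(len(assets.non_pirna),
                                              1.0 / len(assets.non_pirna)))
        for loc, n_l in zip(assets.non_pirna, alloc):
            lseq = assets.sequences[loc.chrom][loc.start:loc.end]
            for _ in range(int(n_l)):
                L = int(rng.integers(20, 30))
                L = min(L, len(lseq))
                s = int(rng.integers(0, len(lseq) - L + 1))
                emit(lseq[s:s + L], origin="non_pirna", gene_id="",
                     locus=loc.name, strand="+", chrom=loc.chrom,
                     start=loc.start + s, end=loc.start + s + L, length=L)

    truth = pd.DataFrame(rows, columns=_TRUTH_COLS)
    return reads, truth


# ---------------------------------------------------------------------------
# mRNA-seq and degradome
# ---------------------------------------------------------------------------


def simulate_mrna_and_degradome(
    assets: GenomeAssets, spec: SimulationSpec
) -> tuple[list[Read], list[Read], pd.DataFrame]:
    """Simulate an mRNA-seq and a degradome library.

    mRNA reads are sampled proportional to per-gene expression.  Degradome
    5' ends sit at the planted cleavage positions (the base paired by guide
    nucleotides 10/11, i.e. the planted responder 5' ends) on top of a
    uniform background.
    """
    spec.validate()
    rng = child_rng(spec.seed, _stable_key("mrna_degradome"))
    expr = expression_levels(spec)
    rl = spec.mrna_read_length
    rows: list[tuple] = []
    mrna: list[Read] = []
    deg: list[Read] = []

    ev = expr.to_numpy()
    alloc = rng.multinomial(spec.mrna_depth, ev / ev.sum())
    i = 0
    for gid, n_g in zip(expr.index, alloc):
        gene = assets.gene(gid)
        tx = assets.transcripts[gid]
        tlen = len(tx.seq)
        for _ in range(int(n_g)):
            L = min(rl, tlen)
            s = int(rng.integers(0, tlen - L + 1))
            rid = f"mrna:{i:07d}"
            i += 1
            mrna.append(Read(rid, tx.seq[s:s + L]))
            rows.append(_truth_row(rid, "mrna", "mrna", gid, gid, gene.strand,
                                   gene.chrom, s, s + L, L))

    # degradome background
    i = 0
    alloc = rng.multinomial(spec.degradome_background, ev / ev.sum())
    for gid, n_g in zip(expr.index, alloc):
        gene = assets.gene(gid)
        tx = assets.transcripts[gid]
        tlen = len(tx.seq)
        for _ in range(int(n_g)):
            s = int(rng.integers(0, max(tlen - 18, 1)))
            L = min(spec.degradome_read_length, tlen - s)
            rid = f"deg:{i:07d}"
            i += 1
            deg.append(Read(rid, tx.seq[s:s + L]))
            rows.append(_truth_row(rid, "degradome", "deg_background", gid,
                                   gid, gene.strand, gene.chrom, s, s + L, L))

    # planted cleavage products
    for (trig, gid, p), _n in zip(planted_responder_sites(assets, spec),
                                  spec.trigger_responder_counts):
        gene = assets.gene(gid)
        tx = assets.transcripts[gid]
        L = min(spec.degradome_read_length, len(tx.seq) - p)
        for _ in range(spec.degradome_site_reads):
            rid = f"deg:{i:07d}"
            i += 1
            deg.append(Read(rid, tx.seq[p:p + L]))
            rows.append(_truth_row(rid, "degradome", "deg_cleavage", gid, gid,
                                   gene.strand, gene.chrom, p, p + L, L,
                                   responder_of=trig.name))

    truth = pd.DataFrame(rows, columns=_TRUTH_COLS)
    return mrna, deg, truth


# ---------------------------------------------------------------------------
# Proximity-labeling spectral counts
# ---------------------------------------------------------------------------


def simulate_spectral_counts(
    n_null: int = 500,
    bait_runs: Sequence[str] = ("bait1", "bait2"),
    control_runs: Sequence[str] = ("ctl1", "ctl2", "ctl3", "ctl4"),
    null_lambda: float = 50.0,
    planted_fold: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spectral-count table with one planted bait-enriched protein among
    Poisson-null background binders.  Row ``planted`` is the true interactor."""
    rng = child_rng(seed, _stable_key("spectral"))
    runs = list(bait_runs) + list(control_runs)
    lam = rng.gamma(4.0, null_lambda / 4.0, size=n_null)
    data = {run: rng.poisson(lam) for run in runs}
    df = pd.DataFrame(data, index=[f"null{i + 1:03d}" for i in range(n_null)])
    planted = {run: rng.poisson(null_lambda * (planted_fold if run in bait_runs else 1.0))
               for run in runs}
    df.loc["planted"] = pd.Series(planted)
    return df.astype(int)
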