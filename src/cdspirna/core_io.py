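"""Shared domain types, format I/O, coordinate conventions, and seeded randomness.

Conventions
-----------
* Internal coordinates are 0-based, half-open ``[start, end)``.
* GFF3 I/O uses the standard 1-based, closed dialect; BED and bedgraph use
  0-based half-open.
* Sequences are stored in the DNA alphabet (A/C/G/T); U is converted to T on
  input.  Complementarity and G-U wobble rules are defined on DNA, so a
  G·U pair is written G·T.
* All stochastic steps draw from one :func:`seeded_rng` stream per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("cdspirna")

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement on the DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna(seq: str) -> str:
    """Canonicalize a nucleotide string: uppercase, U→T."""
    return seq.upper().replace("U", "T")


class MalformedRecordError(ValueError):
    """Raised when an input file cannot be parsed, with file/line context."""


class Read(NamedTuple):
    """A small-RNA read (identifier plus canonical DNA sequence)."""

    read_id: str
    seq: str


# ---------------------------------------------------------------------------
# Gene models and reference assets
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(ivs)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _interval_union_length(ivs: Sequence[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def _contained(inner: Sequence[Interval], outer: Sequence[Interval]) -> bool:
    """True if every base of ``inner`` lies inside the union of ``outer``."""
    outer = _merge_intervals(outer)
    for s, e in inner:
        ok = any(os <= s and e <= oe for os, oe in outer)
        if not ok:
            return False
    return True


@dataclass
class GeneModel:
    """A single-isoform gene model with UTR/CDS structure.

    ``exons`` are sorted, non-overlapping genomic intervals; ``cds_span``,
    ``utr5_span`` and ``utr3_span`` partition the exon union.  Introns are the
    gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds_span: list[Interval]
    utr5_span: list[Interval] = field(default_factory=list)
    utr3_span: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds_span = sorted(tuple(iv) for iv in self.cds_span)
        self.utr5_span = sorted(tuple(iv) for iv in self.utr5_span)
        self.utr3_span = sorted(tuple(iv) for iv in self.utr3_span)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def region_lengths(self) -> dict[str, int]:
        return {
            "utr5": _interval_union_length(self.utr5_span),
            "cds": _interval_union_length(self.cds_span),
            "utr3": _interval_union_length(self.utr3_span),
        }

    @property
    def exon_length(self) -> int:
        return _interval_union_length(self.exons)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] > self.exons[i + 1][0]:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for name, span in (
            ("CDS", self.cds_span),
            ("5'UTR", self.utr5_span),
            ("3'UTR", self.utr3_span),
        ):
            if not _contained(span, self.exons):
                raise ValueError(f"{self.gene_id}: {name} outside exons")
        covered = _merge_intervals(
            list(self.cds_span) + list(self.utr5_span) + list(self.utr3_span)
        )
        if _interval_union_length(covered) != self.exon_length:
            raise ValueError(
                f"{self.gene_id}: UTR5/CDS/UTR3 do not partition the exon union"
            )

    def region_of(self, gpos: int) -> str | None:
        """Region label ('utr5'/'cds'/'utr3') containing genomic base ``gpos``."""
        for name, span in (
            ("utr5", self.utr5_span),
            ("cds", self.cds_span),
            ("utr3", self.utr3_span),
        ):
            if any(s <= gpos < e for s, e in span):
                return name
        return None

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Transcript offset (5'→3' on the gene strand) of genomic base ``gpos``."""
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                plus_off = off + (gpos - s)
                if self.strand == "+":
                    return plus_off
                return self.exon_length - 1 - plus_off
            off += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic position of transcript base ``tpos`` (strand-aware)."""
        if not 0 <= tpos < self.exon_length:
            raise IndexError(tpos)
        plus_off = tpos if self.strand == "+" else self.exon_length - 1 - tpos
        for s, e in self.exons:
            if plus_off < e - s:
                return s + plus_off
            plus_off -= e - s
        raise AssertionError("unreachable")


@dataclass
class Transcript:
    """Spliced transcript sequence with exon-junction offsets.

    ``junctions`` are transcript offsets such that bases ``j-1`` and ``j``
    come from different exons.
    """

    gene_id: str
    seq: str
    junctions: list[int]


@dataclass
class Locus:
    """A named annotated genomic interval (cluster or non-piRNA locus)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "+"
    kind: str = ""


@dataclass
class TriggerRecord:
    """A candidate trigger small RNA (siRNA or miRNA strand)."""

    name: str
    seq: str
    kind: str = "siRNA"  # 'siRNA' or 'miRNA'


@dataclass
class GenomeAssets:
    """Reference bundle: genome, gene models, transcripts and annotations."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    clusters: list[Locus] = field(default_factory=list)
    te_consensus: dict[str, str] = field(default_factory=dict)
    non_pirna: list[Locus] = field(default_factory=list)
    triggers: list[TriggerRecord] = field(default_factory=list)
    n_rejected_genes: int = 0
    transcripts: dict[str, Transcript] = field(init=False)

    def __post_init__(self) -> None:
        self.transcripts = {
            g.gene_id: self._splice(g) for g in self.genes
        }

    def _splice(self, gene: GeneModel) -> Transcript:
        chrom = self.sequences[gene.chrom]
        parts = [chrom[s:e] for s, e in gene.exons]
        seq = "".join(parts)
        juncs = list(np.cumsum([len(p) for p in parts])[:-1])
        if gene.strand == "-":
            seq = revcomp(seq)
            juncs = [len(seq) - j for j in juncs]
        return Transcript(gene.gene_id, seq, sorted(int(j) for j in juncs))

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate(self) -> None:
        for g in self.genes:
            g.validate()
            if g.chrom not in self.sequences:
                raise ValueError(f"{g.gene_id}: unknown chrom {g.chrom}")
            if g.span[1] > len(self.sequences[g.chrom]):
                raise ValueError(f"{g.gene_id}: exceeds chromosome length")
        for loc in list(self.clusters) + list(self.non_pirna):
            if loc.chrom not in self.sequences:
                raise ValueError(f"{loc.name}: unknown chrom {loc.chrom}")
            if not (0 <= loc.start < loc.end <= len(self.sequences[loc.chrom])):
                raise ValueError(f"{loc.name}: interval outside chromosome")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: Path | str) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: Path | str) -> list[Read]:
    return [Read(rec.id, dna(str(rec.seq))) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Read], path: Path | str, quality: int = 40) -> None:
    """Write reads as Phred+33 FASTQ with a constant quality score."""
    with open(path, "w") as fh:
        qchar = chr(quality + 33)
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qchar * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_REGION = {
    "five_prime_UTR": "utr5_span",
    "CDS": "cds_span",
    "three_prime_UTR": "utr3_span",
}


def write_gff3(genes: Sequence[GeneModel], path: Path | str) -> None:
    """Write gene models as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tcdspirna\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ftype, spans in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5_span),
                ("CDS", g.cds_span),
                ("three_prime_UTR", g.utr3_span),
            ):
                for fs, fe in spans:
                    fh.write(
                        f"{g.chrom}\tcdspirna\t{ftype}\t{fs + 1}\t{fe}\t.\t"
                        f"{g.strand}\t.\tParent={g.gene_id}\n"
                    )


def read_gff3(path: Path | str) -> tuple[list[GeneModel], int]:
    """Parse gene models from GFF3.

    Returns (accepted genes in deterministic gene_id order, number rejected).
    Genes whose CDS/UTR features violate the exon-structure invariants are
    rejected with a warning rather than aborting the load.
    """
    raw: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise MalformedRecordError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                s, e = int(start) - 1, int(end)  # 1-based closed → 0-based half-open
            except ValueError as err:
                raise MalformedRecordError(
                    f"{path}:{lineno}: bad coordinates"
                ) from err
            if s < 0 or e <= s:
                raise MalformedRecordError(f"{path}:{lineno}: bad interval")
            adict = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = adict.get("ID")
                if gid is None:
                    raise MalformedRecordError(f"{path}:{lineno}: gene without ID")
                raw.setdefault(
                    gid,
                    {"chrom": chrom, "strand": strand, "exons": [],
                     "cds_span": [], "utr5_span": [], "utr3_span": []},
                )
                if gid not in order:
                    order.append(gid)
            elif ftype == "exon" or ftype in _GFF_REGION:
                gid = adict.get("Parent")
                if gid is None or gid not in raw:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: feature without known Parent"
                    )
                key = "exons" if ftype == "exon" else _GFF_REGION[ftype]
                raw[gid][key].append((s, e))
    genes: list[GeneModel] = []
    n_rejected = 0
    for gid in sorted(order):
        d = raw[gid]
        try:
            g = GeneModel(gene_id=gid, **d)
            g.validate()
        except ValueError as err:
            log.warning("rejecting gene %s: %s", gid, err)
            n_rejected += 1
            continue
        genes.append(g)
    return genes, n_rejected


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(loci: Sequence[Locus], path: Path | str) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            name = f"{loc.name}|{loc.kind}" if loc.kind else loc.name
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{name}\t0\t{loc.strand}\n"
            )


def read_bed(path: Path | str) -> list[Locus]:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise MalformedRecordError(f"{path}:{lineno}: expected ≥3 columns")
            name = cols[3] if len(cols) > 3 else f"locus{lineno}"
            strand = cols[5] if len(cols) > 5 else "+"
            kind = ""
            if "|" in name:
                name, kind = name.split("|", 1)
            loci.append(Locus(cols[0], int(cols[1]), int(cols[2]), name, strand, kind))
    return loci


# ---------------------------------------------------------------------------
# Coverage tracks / bedgraph
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-base depth arrays with a library-size scaling factor.

    Keys are chromosome names (optionally ``(chrom, strand)`` for
    strand-split tracks); values are non-negative depth arrays.  The
    scaling factor is typically 1e6 / reads-after-non-piRNA-removal.
    """

    values: dict
    scaling_factor: float = 1.0

    def scaled(self, key) -> np.ndarray:
        return np.asarray(self.values[key], dtype=float) * self.scaling_factor


def _track_key_str(key) -> str:
    if isinstance(key, tuple):
        return f"{key[0]}{key[1]}"
    return str(key)


def write_bedgraph(track: CoverageTrack, out: Path | str) -> None:
    """Write a bedgraph with runs of equal nonzero value merged."""
    with open(out, "w") as fh:
        for key in track.values:
            chrom = _track_key_str(key)
            vals = track.scaled(key)
            if len(vals) == 0:
                continue
            # change points between runs of equal value
            breaks = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def union_bedgraph(tracks: dict[str, CoverageTrack]) -> "pd.DataFrame":
    """Positionwise union table of several coverage tracks (unionbedg-style).

    Rows are maximal runs over which every track is constant; one value
    column per track label.  Only runs where at least one track is nonzero
    are emitted.
    """
    import pandas as pd

    labels = list(tracks)
    keys = sorted({k for t in tracks.values() for k in t.values},
                  key=_track_key_str)
    rows = []
    for key in keys:
        arrs = []
        length = max(len(t.values.get(key, ())) for t in tracks.values())
        for lab in labels:
            t = tracks[lab]
            if key in t.values:
                a = t.scaled(key)
                arrs.append(np.pad(a, (0, length - len(a))))
            else:
                arrs.append(np.zeros(length))
        stack = np.vstack(arrs)
        if length == 0:
            continue
        breaks = np.flatnonzero((np.diff(stack, axis=1) != 0).any(axis=0)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [length]])
        for s, e in zip(starts, ends):
            vals = stack[:, s]
            if (vals != 0).any():
                rows.append((_track_key_str(key), int(s), int(e), *vals))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", *labels])


def read_bedgraph(path: Path | str) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            c, s, e, v = line.split("\t")
            out.append((c, int(s), int(e), float(v)))
    return out


# ---------------------------------------------------------------------------
# Config / RNG
# ---------------------------------------------------------------------------


def seeded_rng(seed: int) -> np.random.Generator:
    """One reproducible random stream per run; the seed is logged."""
    log.info("random seed: %d", seed)
    return np.random.default_rng(seed)


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """A deterministic child stream keyed by small integers (e.g. library index)."""
    return np.random.default_rng([int(seed)] + [int(k) for k in keys])


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# Asset bundle I/O
# ---------------------------------------------------------------------------


def write_assets(assets: GenomeAssets, out_dir: Path | str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(assets.sequences, out / "genome.fa")
    write_gff3(assets.genes, out / "genes.gff3")
    write_bed(assets.clusters, out / "clusters.bed")
    write_bed(assets.non_pirna, out / "non_pirna.bed")
    write_fasta(assets.te_consensus, out / "te_consensus.fa")
    write_fasta(
        {f"{t.name}|{t.kind}": t.seq for t in assets.triggers},
        out / "triggers.fa",
    )


def load_assets(
    genome_fasta: Path | str,
    annotations: dict[str, Path | str] | None = None,
    config: dict | None = None,
) -> GenomeAssets:
    """Load a reference bundle from standard files.

    ``annotations`` maps keys ``genes`` (GFF3), ``clusters`` (BED),
    ``non_pirna`` (BED), ``te_consensus`` (FASTA), ``triggers`` (FASTA) to
    paths; missing keys yield empty annotation sets.  When ``genome_fasta``
    is a directory, the conventional file names written by
    :func:`write_assets` are used.
    """
    genome_fasta = Path(genome_fasta)
    annotations = dict(annotations or {})
    if genome_fasta.is_dir():
        d = genome_fasta
        genome_fasta = d / "genome.fa"
        for key, name in (
            ("genes", "genes.gff3"),
            ("clusters", "clusters.bed"),
            ("non_pirna", "non_pirna.bed"),
            ("te_consensus", "te_consensus.fa"),
            ("triggers", "triggers.fa"),
        ):
            if (d / name).exists():
                annotations.setdefault(key, d / name)
    sequences = read_fasta(genome_fasta)
    genes: list[GeneModel] = []
    n_rejected = 0
    if "genes" in annotations:
        genes, n_rejected = read_gff3(annotations["genes"])
    clusters = read_bed(annotations["clusters"]) if "clusters" in annotations else []
    non_pirna = read_bed(annotations["non_pirna"]) if "non_pirna" in annotations else []
    te = read_fasta(annotations["te_consensus"]) if "te_consensus" in annotations else {}
    triggers: list[TriggerRecord] = []
    if "triggers" in annotations:
        for name, seq in read_fasta(annotations["triggers"]).items():
            kind = "siRNA"
            if "|" in name:
                name, kind = name.split("|", 1)
            triggers.append(TriggerRecord(name, seq, kind))
    assets = GenomeAssets(
        sequences=sequences,
        genes=genes,
        clusters=clusters,
        te_consensus=te,
        non_pirna=non_pirna,
        triggers=triggers,
        n_rejected_genes=n_rejected,
    )
    assets.validate()
    return assets
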