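"""5'-to-5' 10-nt complementary-overlap pairing between small-RNA sets.

Ping-pong geometry: a trigger piRNA directs cleavage of a target across the
bases bound by its 10th/11th nucleotides, so the responder piRNA produced
from the 3' cleavage fragment shares a 10-nt 5'-to-5' complementary overlap
with the trigger: ``responder[0:10] == revcomp(trigger[0:10])``.

Modes:

* :func:`find_overlap_pairs` — the plain 10-nt rule between trigger and
  responder read groups, with optional G·U wobble pairs and a minimum
  summed responder read count per trigger (strictly greater than).
* :func:`cleavage_pairs` — additionally anchors each responder fragment on a
  transcript and, when requested, demands Watson-Crick pairing of the
  guide's 11th nucleotide to the transcript base immediately 5' of the
  fragment's 5' end (cleavage competence).
* :func:`pair_degradome` — cleavage pairing with degradome fragments as
  responders.
* :func:`scan_mirna_sites` — seed-match (miRNA nt 2–8) target-site scan.
* :func:`filter_ago2_sorted` — retain miRNA strands with Ago2 sorting
  preference (RPM Ago1 < Ago2, strictly, and detectable).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_io import Read, revcomp

__all__ = [
    "ReadGroup",
    "OverlapPair",
    "group_reads",
    "find_overlap_pairs",
    "cleavage_pairs",
    "pair_degradome",
    "filter_ago2_sorted",
    "scan_mirna_sites",
    "pairs_frame",
]

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}
# DNA alphabet: the G·U wobble pair is G·T
_WOBBLE_OK = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class ReadGroup:
    """Identical reads collapsed to one sequence with a count."""

    seq: str
    count: int = 1
    label: str = ""


@dataclass
class OverlapPair:
    trigger: ReadGroup
    responder: ReadGroup
    overlap_len: int = 10
    wobble_free: bool = True
    g11_paired: bool | None = None  # None = not applicable
    gene_id: str = ""
    position: int = -1  # responder 5' offset on the transcript


def group_reads(reads: Iterable[Read | str], label: str = "") -> list[ReadGroup]:
    """One group per distinct sequence; counts sum to the input size."""
    seqs = [r.seq if isinstance(r, Read) else str(r) for r in reads]
    counts = Counter(seqs)
    return [ReadGroup(seq, n, label) for seq, n in sorted(counts.items())]


def _pairs_at(trigger_base: str, responder_base: str, allow_gu: bool) -> bool:
    if _WC.get(trigger_base) == responder_base:
        return True
    return allow_gu and (trigger_base, responder_base) in _WOBBLE_OK


def _overlap_ok(trigger: str, responder: str, allow_gu: bool) -> tuple[bool, bool]:
    """(pairs over the 10-nt overlap, all pairs are Watson-Crick).

    Antiparallel geometry: trigger position i pairs responder position 9-i.
    """
    wobble_free = True
    for i in range(10):
        t, r = trigger[i], responder[9 - i]
        if _WC.get(t) == r:
            continue
        if allow_gu and (t, r) in _WOBBLE_OK:
            wobble_free = False
            continue
        return False, False
    return True, wobble_free


def _compatible_prefixes(trigger: str, allow_gu: bool) -> Iterable[str]:
    """All responder 10-mers pairing positions 1–10 of the trigger."""
    per_pos = []
    for i in range(10):
        t = trigger[9 - i]  # responder position i pairs trigger position 9-i
        opts = [_WC[t]] if t in _WC else []
        if allow_gu:
            opts += [r for (tb, r) in _WOBBLE_OK if tb == t]
        per_pos.append(opts)
    for combo in itertools.product(*per_pos):
        yield "".join(combo)


def find_overlap_pairs(
    triggers: Sequence[ReadGroup],
    responders: Sequence[ReadGroup],
    min_responder_reads: int = 10,
    allow_gu: bool = False,
    self_pair: bool = False,
) -> list[OverlapPair]:
    """All trigger/responder pairs satisfying the 10-nt 5'-to-5' rule.

    A trigger's pairs are reported only when its summed paired responder
    reads strictly exceed ``min_responder_reads``.  Responders are indexed
    by their first 10 nucleotides, so the search is linear in the input;
    sequences shorter than 10 nt are skipped with a warning count.
    With ``self_pair`` the trigger set is paired against itself
    (piRNA–piRNA mode) excluding identical-sequence self matches.
    """
    if self_pair:
        responders = triggers
    by_prefix: dict[str, list[ReadGroup]] = {}
    for g in responders:
        if len(g.seq) < 10:
            continue
        by_prefix.setdefault(g.seq[:10], []).append(g)

    out: list[OverlapPair] = []
    for trig in triggers:
        if len(trig.seq) < 10:
            continue
        matches: list[tuple[ReadGroup, bool]] = []
        for prefix in _compatible_prefixes(trig.seq, allow_gu):
            for resp in by_prefix.get(prefix, ()):
                if self_pair and resp.seq == trig.seq:
                    continue
                ok, wf = _overlap_ok(trig.seq, resp.seq, allow_gu)
                assert ok
                matches.append((resp, wf))
        total = sum(r.count for r, _ in matches)
        if total > min_responder_reads:
            for resp, wf in matches:
                out.append(OverlapPair(trig, resp, wobble_free=wf))
    return out


def _locate_fragment(seq: str, transcripts: dict[str, str]) -> list[tuple[str, int]]:
    """All exact 5'-anchored placements of a fragment on the transcripts."""
    out = []
    for gid in sorted(transcripts):
        tx = transcripts[gid]
        j = tx.find(seq)
        while j >= 0:
            out.append((gid, j))
            j = tx.find(seq, j + 1)
    return out


def cleavage_pairs(
    guides: Sequence[ReadGroup],
    fragments: Sequence[ReadGroup],
    transcripts: dict[str, str],
    require_g11: bool = True,
    min_group_reads: int = 10,
    allow_gu: bool = False,
) -> tuple[list[OverlapPair], int]:
    """Cleavage-competent overlap pairing of guides against transcript-anchored
    fragments.

    With ``require_g11`` a pair additionally needs the guide's 11th
    nucleotide to be Watson-Crick complementary to the transcript base
    immediately 5' of the fragment's 5' end — the base the guide's t11
    occupies under cleavage between target positions t10/t11.  Returns
    (pairs, number of fragments not locatable on any transcript).  The
    ``min_group_reads`` filter is the same summed-responder rule as
    :func:`find_overlap_pairs` (strictly greater than).
    """
    located: list[tuple[ReadGroup, list[tuple[str, int]]]] = []
    n_unlocated = 0
    for frag in fragments:
        places = _locate_fragment(frag.seq, transcripts)
        if places:
            located.append((frag, places))
        else:
            n_unlocated += 1

    by_prefix: dict[str, list[tuple[ReadGroup, list[tuple[str, int]]]]] = {}
    for frag, places in located:
        if len(frag.seq) >= 10:
            by_prefix.setdefault(frag.seq[:10], []).append((frag, places))

    out: list[OverlapPair] = []
    for guide in guides:
        if len(guide.seq) < 10:
            continue
        matches = []
        for prefix in _compatible_prefixes(guide.seq, allow_gu):
            for frag, places in by_prefix.get(prefix, ()):
                ok, wf = _overlap_ok(guide.seq, frag.seq, allow_gu)
                assert ok
                kept_places = []
                g11: bool | None = None
                if require_g11:
                    if len(guide.seq) < 11:
                        continue
                    g11 = False
                    for gid, pos in places:
                        if pos == 0:
                            continue  # no 5' base to pair
                        upstream = transcripts[gid][pos - 1]
                        if _WC.get(guide.seq[10]) == upstream:
                            kept_places.append((gid, pos))
                    if not kept_places:
                        continue
                    g11 = True
                else:
                    kept_places = places
                matches.append((frag, wf, g11, kept_places))
        total = sum(f.count for f, _, _, _ in matches)
        if total > min_group_reads:
            for frag, wf, g11, places in matches:
                gid, pos = places[0]
                out.append(OverlapPair(guide, frag, wobble_free=wf,
                                       g11_paired=g11, gene_id=gid,
                                       position=pos))
    return out, n_unlocated


def pair_degradome(
    guides: Sequence[ReadGroup],
    degradome_reads: Iterable[Read | str] | Sequence[ReadGroup],
    transcripts: dict[str, str],
    require_g11: bool = True,
    min_group_reads: int = 10,
) -> tuple[list[OverlapPair], int]:
    """Pair guide piRNAs with degradome fragments (cleavage mode)."""
    items = list(degradome_reads)
    if items and isinstance(items[0], ReadGroup):
        groups = items  # already grouped
    else:
        groups = group_reads(items, label="degradome")
    return cleavage_pairs(guides, groups, transcripts,
                          require_g11=require_g11,
                          min_group_reads=min_group_reads)


def filter_ago2_sorted(mirna_table: pd.DataFrame) -> pd.DataFrame:
    """Retain miRNA strands detectable in the library and sorted to Ago2.

    Expects columns ``rpm_ago1`` and ``rpm_ago2``; a strand is kept iff
    max(RPM) > 0 and RPM(Ago1) < RPM(Ago2) strictly.
    """
    for col in ("rpm_ago1", "rpm_ago2"):
        if col not in mirna_table.columns:
            raise ValueError(f"missing column {col}")
    detectable = mirna_table[["rpm_ago1", "rpm_ago2"]].max(axis=1) > 0
    sorted_to_ago2 = mirna_table["rpm_ago1"] < mirna_table["rpm_ago2"]
    return mirna_table[detectable & sorted_to_ago2]


def scan_mirna_sites(
    mirna: str, target: str, rule: str = "seed_2_8"
) -> list[int]:
    """Offsets of seed-complementary target sites (miRNA nt 2–8).

    The caller supplies the strand to scan (sense or antisense sequence).
    ``seed_2_8_plus_3p`` additionally requires a 4-nt 3'-supplementary
    match (miRNA nt 13–16) at the geometric offset.
    """
    if rule not in ("seed_2_8", "seed_2_8_plus_3p"):
        raise ValueError(f"unknown rule {rule!r}")
    seed = mirna[1:8]
    probe = revcomp(seed)
    sites = []
    j = target.find(probe)
    while j >= 0:
        ok = True
        if rule == "seed_2_8_plus_3p" and len(mirna) >= 16:
            supp = revcomp(mirna[12:16])
            # miRNA nt 13-16 pair target bases upstream of the seed match
            s = j - 9  # seed nt8 sits at j; nt13..16 pair 5..8 nt further 5'
            ok = 0 <= s and target[s:s + 4] == supp
        if ok:
            sites.append(j)
        j = target.find(probe, j + 1)
    return sites


def pairs_frame(pairs: Sequence[OverlapPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.trigger.seq, p.trigger.count, p.responder.seq, p.responder.count,
          p.overlap_len, p.wobble_free, p.g11_paired, p.gene_id, p.position)
         for p in pairs],
        columns=["trigger_seq", "trigger_count", "responder_seq",
                 "responder_count", "overlap_len", "wobble_free",
                 "g11_paired", "gene_id", "position"],
    )
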