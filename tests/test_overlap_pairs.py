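"""Ping-pong overlap pairing against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cdspirna.core_io import revcomp
from cdspirna.overlap_pairs import (
    OverlapPair,
    ReadGroup,
    cleavage_pairs,
    filter_ago2_sorted,
    find_overlap_pairs,
    group_reads,
    pair_degradome,
    scan_mirna_sites,
)

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_pairs(triggers, responders, min_responder_reads=10,
                      allow_gu=False, self_pair=False):
    """O(n*m) all-pairs comparator used as the independent oracle."""
    if self_pair:
        responders = triggers
    out = []
    for trig in triggers:
        if len(trig.seq) < 10:
            continue
        matches = []
        for resp in responders:
            if len(resp.seq) < 10 or (self_pair and resp.seq == trig.seq):
                continue
            ok, wobble_free = True, True
            for i in range(10):
                t, r = trig.seq[i], resp.seq[9 - i]
                if _WC[t] == r:
                    continue
                if allow_gu and (t, r) in {("G", "T"), ("T", "G")}:
                    wobble_free = False
                    continue
                ok = False
                break
            if ok:
                matches.append((resp, wobble_free))
        if sum(r.count for r, _ in matches) > min_responder_reads:
            out.extend((trig.seq, r.seq, wf) for r, wf in matches)
    return set(out)


def as_set(pairs):
    return {(p.trigger.seq, p.responder.seq, p.wobble_free) for p in pairs}


def random_groups(rng, n, length=(21, 29), counts=(1, 30), label=""):
    bases = np.array(list("ACGT"))
    groups, seen = [], set()
    while len(groups) < n:
        L = int(rng.integers(length[0], length[1] + 1))
        seq = "".join(bases[rng.integers(0, 4, L)])
        if seq in seen:
            continue
        seen.add(seq)
        groups.append(ReadGroup(seq, int(rng.integers(*counts)), label))
    return groups


class TestGroupReads:
    def test_collapses_identical_sequences(self):
        groups = group_reads(["AAAA", "AAAA", "CCCC"])
        assert {(g.seq, g.count) for g in groups} == {("AAAA", 2), ("CCCC", 1)}

    def test_distinct_reads_give_unit_groups(self):
        groups = group_reads(["AAAA", "CCCC", "GGGG"])
        assert all(g.count == 1 for g in groups) and len(groups) == 3

    def test_empty_input(self):
        assert group_reads([]) == []


class TestFindOverlapPairs:
    def test_constructed_complement_pairs(self):
        trig = ReadGroup("ACGTACGTACTTTTTTTTTTTT", 1)
        resp = ReadGroup("GTACGTACGTAAAACCCCGGGGTTT", 20)
        pairs = find_overlap_pairs([trig], [resp])
        assert len(pairs) == 1
        p = pairs[0]
        assert p.responder.seq[:10] == revcomp(p.trigger.seq[:10])
        assert p.wobble_free

    def test_gu_wobble_rule(self):
        # trigger pos 1 G pairing responder pos 10 T is a G-U pair
        trig = ReadGroup("GCGTACGTACTTTTTTTTTTTT", 1)
        resp_seq = "GTACGTACGT" + "AAAACCCCGG"
        resp_seq = resp_seq[:9] + "T" + resp_seq[10:]  # pos10 pairs trig pos1
        resp = ReadGroup(resp_seq, 50)
        assert find_overlap_pairs([trig], [resp], allow_gu=False) == []
        pairs = find_overlap_pairs([trig], [resp], allow_gu=True)
        assert len(pairs) == 1 and not pairs[0].wobble_free

    @pytest.mark.parametrize("count,reported", [(10, False), (11, True)])
    def test_strictly_more_than_ten_reads(self, count, reported):
        trig = ReadGroup("ACGTACGTACTTTTTTTTTTTT", 1)
        resp = ReadGroup("GTACGTACGTAAAACCCCGGGGTTT", count)
        pairs = find_overlap_pairs([trig], [resp])
        assert bool(pairs) is reported

    @pytest.mark.parametrize("allow_gu", [False, True])
    @pytest.mark.parametrize("min_reads", [0, 10])
    def test_matches_brute_force_on_random_groups(self, allow_gu, min_reads):
        rng = np.random.default_rng(123)
        triggers = random_groups(rng, 300, label="t")
        responders = random_groups(rng, 300, label="r")
        # plant complements so the comparison is not vacuously empty
        planted = []
        for i, trig in enumerate(triggers[:30]):
            seq = revcomp(trig.seq[:10]) + "ACGTACGTACGTAC"[: 10 + (i % 5)]
            planted.append(ReadGroup(seq, int(rng.integers(1, 30)), "r"))
        responders = responders + planted
        got = as_set(find_overlap_pairs(triggers, responders,
                                        min_responder_reads=min_reads,
                                        allow_gu=allow_gu))
        want = brute_force_pairs(triggers, responders,
                                 min_responder_reads=min_reads,
                                 allow_gu=allow_gu)
        assert got == want

    def test_gu_output_is_superset_of_strict_output(self):
        rng = np.random.default_rng(7)
        triggers = random_groups(rng, 200, label="t")
        responders = random_groups(rng, 200, label="r")
        for trig in triggers[:20]:
            prefix = list(revcomp(trig.seq[:10]))
            # mutate one position to the wobble partner where possible
            for j, b in enumerate(prefix):
                t = trig.seq[9 - j]
                if t == "G":
                    prefix[j] = "T"
                    break
                if t == "T":
                    prefix[j] = "G"
                    break
            responders.append(ReadGroup("".join(prefix) + "AACCGGTTAA", 15, "r"))
        strict = as_set(find_overlap_pairs(triggers, responders,
                                           min_responder_reads=0))
        loose = as_set(find_overlap_pairs(triggers, responders,
                                          min_responder_reads=0, allow_gu=True))
        assert {(t, r) for t, r, _ in strict} <= {(t, r) for t, r, _ in loose}
        assert len(loose) > len(strict)

    def test_reported_pairs_satisfy_rule_independently(self, screen_exp):
        from cdspirna.pipeline import trigger_recovery

        genic = [a for a in screen_exp.assignments["aub_ip_rep1"]
                 if a.cls == "genic"]
        responders = group_reads([a.sequence for a in genic])
        triggers = [ReadGroup(t.seq, 1, t.name)
                    for t in screen_exp.assets.triggers]
        for p in find_overlap_pairs(triggers, responders):
            assert p.responder.seq[:10] == revcomp(p.trigger.seq[:10])


def make_cleavage_case(rng, g11_match=True):
    """A transcript, a guide complementary over its t1-t11, and the 3'
    fragment starting at the cleavage position."""
    bases = np.array(list("ACGT"))
    tx = "".join(bases[rng.integers(0, 4, 300)])
    p = int(rng.integers(30, 250))  # cleavage position / fragment 5' end
    guide = revcomp(tx[p - 1:p + 10]) if g11_match else None
    if not g11_match:
        # guide nt 11 deliberately mismatched to the base at p-1
        good = revcomp(tx[p - 1:p + 10])
        bad11 = {"A": "C", "C": "A", "G": "T", "T": "G"}[good[10]]
        guide = good[:10] + bad11 + good[11:]
    guide = guide + "".join(bases[rng.integers(0, 4, 10)])  # 3' tail
    frag = tx[p:p + 25]
    return tx, guide, frag, p


class TestCleavagePairs:
    def test_constructed_cleavage_site_reported(self):
        rng = np.random.default_rng(0)
        tx, guide, frag, p = make_cleavage_case(rng)
        pairs, n_unloc = cleavage_pairs([ReadGroup(guide, 1)],
                                        [ReadGroup(frag, 20)], {"g": tx})
        assert n_unloc == 0
        assert len(pairs) == 1
        assert pairs[0].g11_paired is True
        assert pairs[0].gene_id == "g" and pairs[0].position == p

    def test_mutated_upstream_base_excluded_when_g11_required(self):
        rng = np.random.default_rng(1)
        tx, guide, frag, p = make_cleavage_case(rng, g11_match=False)
        pairs, _ = cleavage_pairs([ReadGroup(guide, 1)],
                                  [ReadGroup(frag, 20)], {"g": tx})
        assert pairs == []
        pairs, _ = cleavage_pairs([ReadGroup(guide, 1)],
                                  [ReadGroup(frag, 20)], {"g": tx},
                                  require_g11=False)
        assert len(pairs) == 1

    def test_without_g11_reduces_to_find_overlap_pairs(self):
        """Mode equivalence on 200 random transcript-anchored cases."""
        rng = np.random.default_rng(2)
        guides, frags, txs = [], [], {}
        for i in range(200):
            tx, guide, frag, _p = make_cleavage_case(rng)
            txs[f"g{i}"] = tx
            guides.append(ReadGroup(guide, 1, f"t{i}"))
            frags.append(ReadGroup(frag, int(rng.integers(1, 40)), f"f{i}"))
        got, n_unloc = cleavage_pairs(guides, frags, txs, require_g11=False,
                                      min_group_reads=10)
        assert n_unloc == 0
        want = find_overlap_pairs(guides, frags, min_responder_reads=10)
        assert as_set(got) == as_set(want)

    def test_unlocatable_fragment_skipped_and_counted(self):
        rng = np.random.default_rng(3)
        tx, guide, frag, _p = make_cleavage_case(rng)
        alien = ReadGroup("ACGT" * 6, 50)
        _pairs, n_unloc = cleavage_pairs([ReadGroup(guide, 1)],
                                         [ReadGroup(frag, 20), alien],
                                         {"g": tx})
        assert n_unloc == 1


class TestPairDegradome:
    def test_planted_cleavage_recovered_from_simulation(self, screen_exp):
        from cdspirna import synthetic_data as syn
        from cdspirna.core_io import Read

        exp = screen_exp
        sites = syn.planted_responder_sites(exp.assets, exp.spec)
        tx_seqs = {g: t.seq for g, t in exp.assets.transcripts.items()}
        guides = [ReadGroup(t.seq, 50, t.name) for t, _g, _p in sites]
        pairs, _ = pair_degradome(guides, exp.reads["degradome"], tx_seqs)
        recovered = {(p.gene_id, p.position) for p in pairs}
        assert {(g, p) for _t, g, p in sites} <= recovered

    def test_background_only_degradome_yields_no_pairs(self):
        import dataclasses

        from cdspirna import synthetic_data as syn

        spec = dataclasses.replace(syn.SimulationSpec.small(),
                                   degradome_site_reads=0)
        assets = syn.build_toy_assets(spec)
        _m, deg, _t = syn.simulate_mrna_and_degradome(assets, spec)
        sites = syn.planted_responder_sites(assets, spec)
        guides = [ReadGroup(t.seq, 50, t.name) for t, _g, _p in sites]
        tx_seqs = {g: t.seq for g, t in assets.transcripts.items()}
        pairs, _ = pair_degradome(guides, deg, tx_seqs)
        assert pairs == []

    def test_pairing_is_not_symmetric_under_relabeling(self):
        rng = np.random.default_rng(4)
        tx, guide, frag, _p = make_cleavage_case(rng)
        fwd, _ = cleavage_pairs([ReadGroup(guide, 20)], [ReadGroup(frag, 20)],
                                {"g": tx}, require_g11=False,
                                min_group_reads=0)
        rev, _ = cleavage_pairs([ReadGroup(frag, 20)], [ReadGroup(guide, 20)],
                                {"g": tx}, require_g11=False,
                                min_group_reads=0)
        assert len(fwd) == 1
        assert rev == []  # the guide is not transcript-anchored


class TestAgo2Filter:
    def test_examples(self):
        df = pd.DataFrame(
            {"rpm_ago1": [5.0, 50.0, 7.0, 0.0],
             "rpm_ago2": [50.0, 5.0, 7.0, 0.0]},
            index=["kept", "ago1_pref", "tie", "undetectable"],
        )
        kept = filter_ago2_sorted(df)
        assert list(kept.index) == ["kept"]


class TestScanMirnaSites:
    def test_embedded_seed_complement_found(self):
        mirna = "TGAGGTAGTAGGTTGTATAGTT"
        probe = revcomp(mirna[1:8])
        target = "A" * 40 + probe + "C" * 40
        assert scan_mirna_sites(mirna, target) == [40]

    def test_random_target_hit_rate_matches_expectation(self):
        """Expected seed matches in random sequence ≈ L / 4^7."""
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        mirna = "TGAGGTAGTAGGTTGTATAGTT"
        L = 200_000
        n_rep = 10
        hits = [len(scan_mirna_sites(
            mirna, "".join(bases[rng.integers(0, 4, L)]))) for _ in range(n_rep)]
        expected = L / 4 ** 7
        # Poisson mean ~12.2 per replicate; the mean of 10 replicates is
        # within 5 standard errors
        se = np.sqrt(expected / n_rep)
        assert abs(np.mean(hits) - expected) < 5 * se

    def test_antisense_only_sites(self):
        mirna = "TGAGGTAGTAGGTTGTATAGTT"
        probe = revcomp(mirna[1:8])
        antisense = "G" * 30 + probe + "G" * 30 + probe + "G" * 10
        sense = revcomp(antisense)
        assert len(scan_mirna_sites(mirna, sense)) == 0
        assert len(scan_mirna_sites(mirna, antisense)) == 2
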