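"""Trimming, matching, hierarchical classification and normalization."""

import numpy as np
import pytest

from cdspirna.classify_map import (
    ADAPTER_ILLUMINA,
    ClassifyPolicy,
    ReferenceIndex,
    classify_hierarchical,
    coverage_from_assignments,
    match_reads,
    quantify,
    size_select,
    trim_adapter,
)
from cdspirna.core_io import Read, revcomp


def _reads(*seqs):
    return [Read(f"r{i}", s) for i, s in enumerate(seqs)]


class TestTrimAndSize:
    def test_keeps_prefix_before_leftmost_adapter(self):
        res = trim_adapter(_reads("ACGT" + ADAPTER_ILLUMINA + "NNN"),
                           ADAPTER_ILLUMINA)
        assert [r.seq for r in res.reads] == ["ACGT"]

    def test_adapterless_read_kept_whole_and_flagged(self):
        res = trim_adapter(_reads("ACGTACGTACGT"), ADAPTER_ILLUMINA)
        assert [r.seq for r in res.reads] == ["ACGTACGTACGT"]
        assert res.n_no_adapter == 1 and res.no_adapter_ids == ["r0"]

    def test_read_starting_with_adapter_dropped(self):
        res = trim_adapter(_reads(ADAPTER_ILLUMINA + "ACGT"), ADAPTER_ILLUMINA)
        assert res.reads == [] and res.n_empty_dropped == 1

    @pytest.mark.parametrize(
        "length,window,kept",
        [(23, (23, 29), True), (29, (23, 29), True), (30, (23, 29), False),
         (22, (23, 29), False), (18, (18, 29), True)],
    )
    def test_size_window_is_inclusive(self, length, window, kept):
        reads = _reads("A" * length)
        out, n_removed = size_select(reads, *window)
        assert (len(out) == 1) is kept
        assert n_removed == (0 if kept else 1)


class TestMatchReads:
    def test_eighty_percent_similarity_boundary(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        ref = "".join(bases[rng.integers(0, 4, 200)])
        window = list(ref[50:75])  # 25 nt
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for k in range(5):
            window[2 + 4 * k] = flip[window[2 + 4 * k]]
        read5 = "".join(window)  # 5 mismatches: 20/25 = 0.80
        hits = match_reads([Read("r", read5)], {"ref": ref}, 0.8)["r"]
        assert any(h.pos == 50 and h.mismatches == 5 for h in hits)

        window[2 + 4 * 5 - 2] = flip[window[20]]  # 6th mismatch
        read6 = "".join(window)
        hits = match_reads([Read("r", read6)], {"ref": ref}, 0.8)["r"]
        assert not any(h.pos == 50 for h in hits)

    def test_reverse_complement_read_yields_minus_strand_hit(self):
        ref = "AAAACCCCGGGGTTTTACGTACGTACGTAAAA"
        read = revcomp(ref[4:28])
        hits = match_reads([Read("r", read)], {"ref": ref}, 1.0, "both")["r"]
        assert [(h.pos, h.strand) for h in hits] == [(4, "-")]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            match_reads(_reads("ACGTACGT"), {}, 1.0)

    def test_exact_matcher_agrees_with_sliding_window_oracle(self):
        """With tolerance 1.0 the k-mer path equals naive O(n*m) scanning."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        refs = {f"c{j}": "".join(bases[rng.integers(0, 4, 3000)])
                for j in range(3)}
        idx = ReferenceIndex(refs)
        for _ in range(50):
            name = f"c{rng.integers(0, 3)}"
            L = int(rng.integers(18, 30))
            s = int(rng.integers(0, 3000 - L))
            seq = refs[name][s:s + L]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            got = {(h.ref, h.pos, h.strand) for h in idx.exact(seq, "both")}
            expect = set()
            for rname, ref in refs.items():
                for strand, probe in (("+", seq), ("-", revcomp(seq))):
                    j = ref.find(probe)
                    while j >= 0:
                        expect.add((rname, j, strand))
                        j = ref.find(probe, j + 1)
            assert got == expect


def _assign_map(assignments):
    return {a.read_id: a for a in assignments}


class TestHierarchy:
    def test_ncrna_beats_gene_overlap(self, micro_assets):
        # sequence present both at the rRNA locus and inside geneN's exon
        read = Read("r", micro_assets.sequences["chr1"][110:135])
        (a,) = classify_hierarchical([read], micro_assets)
        assert a.cls == "non_piRNA" and a.locus == "rrna1"

    def test_cluster_beats_te(self, micro_assets):
        # sequence present in cluster1 (TE remnant) and in TE1 consensus
        read = Read("r", micro_assets.sequences["chr1"][1210:1235])
        (a,) = classify_hierarchical([read], micro_assets)
        assert a.cls == "cluster" and a.locus == "cluster1"

    def test_te_only_read_goes_to_te_tier(self, micro_assets):
        read = Read("r", micro_assets.te_consensus["TE1"][500:525])
        (a,) = classify_hierarchical([read], micro_assets)
        assert a.cls == "TE" and a.locus == "TE1"

    def test_two_gene_read_is_discarded(self, micro_assets):
        # duplicated segment shared by geneA and geneB exons
        read = Read("r", micro_assets.sequences["chr1"][4210:4235])
        (a,) = classify_hierarchical([read], micro_assets)
        assert a.cls == "unassigned" and a.locus == "multi_gene"

    def test_unique_genic_read_is_assigned(self, micro_assets):
        read = Read("r", micro_assets.sequences["chr1"][3160:3185])
        (a,) = classify_hierarchical([read], micro_assets)
        assert a.cls == "genic" and a.locus == "geneA"
        assert (a.chrom, a.pos, a.strand) == ("chr1", 3160, "+")

    def test_within_gene_multimapper_gets_seeded_random_position(self):
        """A repeat inside one gene keeps the read, position drawn with seed."""
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        seq = list("".join(bases[rng.integers(0, 4, 2000)]))
        seq[300:400] = seq[100:200]  # internal tandem-like repeat
        seq[600:700] = seq[100:200]
        from cdspirna.core_io import GeneModel, GenomeAssets

        gene = GeneModel("rep", "chr1", "+", exons=[(50, 1000)],
                         utr5_span=[(50, 100)], cds_span=[(100, 900)],
                         utr3_span=[(900, 1000)])
        assets = GenomeAssets(sequences={"chr1": "".join(seq)}, genes=[gene])
        read = Read("r", "".join(seq[110:135]))
        positions = set()
        for seed in range(8):
            (a,) = classify_hierarchical(
                [read], assets, rng=np.random.default_rng(seed))
            assert a.cls == "genic" and a.locus == "rep"
            positions.add(a.pos)
        assert positions <= {110, 310, 610}
        assert len(positions) > 1  # random among the three placements
        # same seed → same position
        (a1,) = classify_hierarchical([read], assets,
                                      rng=np.random.default_rng(0))
        (a2,) = classify_hierarchical([read], assets,
                                      rng=np.random.default_rng(0))
        assert a1.pos == a2.pos

    def test_independent_mode_maps_te_read_despite_cluster_tier(self, micro_assets):
        read = Read("r", micro_assets.te_consensus["TE1"][500:525])
        (a,) = classify_hierarchical(
            [read], micro_assets, ClassifyPolicy(tier_mode="independent"))
        assert a.cls == "TE"

    def test_classification_is_a_partition(self, micro_assets):
        chrom = micro_assets.sequences["chr1"]
        reads = [Read(f"r{i}", chrom[p:p + 25])
                 for i, p in enumerate(range(0, 5900, 37))]
        assignments = classify_hierarchical(reads, micro_assets)
        assert len(assignments) == len(reads)
        assert {a.read_id for a in assignments} == {r.read_id for r in reads}
        valid = {"non_piRNA", "cluster", "TE", "genic", "unassigned"}
        assert {a.cls for a in assignments} <= valid


class TestQuantify:
    def test_tpm_from_rpk_proportions(self, micro_assets):
        # geneA exon length 500 nt, geneB 600 nt; equal RPK needs 5:6 counts
        chrom = micro_assets.sequences["chr1"]
        reads = (
            [Read(f"a{i}", chrom[3160 + i:3185 + i]) for i in range(4)]
            + [Read(f"b{i}", chrom[4300 + i:4325 + i]) for i in range(12)]
        )
        asg = classify_hierarchical(reads, micro_assets)
        prof = quantify(asg, micro_assets)
        rpk = prof.genes["rpk"]
        tpm = prof.genes["tpm"]
        expected = rpk * 1e6 / rpk.sum()
        assert np.allclose(tpm, expected)
        assert abs(tpm.sum() - 1e6) < 1e-6

    def test_rpm_uses_after_nonpirna_denominator(self, micro_assets):
        chrom = micro_assets.sequences["chr1"]
        reads = (
            [Read(f"n{i}", chrom[110 + i:135 + i]) for i in range(5)]  # rRNA
            + [Read(f"a{i}", chrom[3160:3185]) for i in range(5)]       # genic
        )
        prof = quantify(classify_hierarchical(reads, micro_assets), micro_assets)
        assert prof.total_after_nonpirna == 5
        assert prof.genes.loc["geneA", "rpm"] == pytest.approx(5 * 1e6 / 5)

    def test_counts_conserved_across_classes(self, micro_assets):
        chrom = micro_assets.sequences["chr1"]
        reads = [Read(f"r{i}", chrom[p:p + 24])
                 for i, p in enumerate(range(80, 5700, 53))]
        prof = quantify(classify_hierarchical(reads, micro_assets), micro_assets)
        assert prof.conservation_ok()
        assert sum(prof.class_counts.values()) == len(reads)


class TestCoverage:
    def test_single_read_depth_span(self, micro_assets):
        chrom = micro_assets.sequences["chr1"]
        read = Read("r", chrom[3160:3185])
        asg = classify_hierarchical([read], micro_assets)
        track = coverage_from_assignments(asg, micro_assets,
                                          total_after_nonpirna=1_000_000)
        vals = track.values["chr1"]
        assert (vals[3160:3185] == 1).all()
        assert vals.sum() == 25
        assert track.scaling_factor == 1.0

    def test_scaling_factor_halves_at_double_depth(self, micro_assets):
        asg = classify_hierarchical(
            [Read("r", micro_assets.sequences["chr1"][3160:3185])], micro_assets)
        track = coverage_from_assignments(asg, micro_assets,
                                          total_after_nonpirna=2_000_000)
        assert track.scaling_factor == 0.5
        assert track.scaled("chr1")[3160] == 0.5
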