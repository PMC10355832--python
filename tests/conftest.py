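"""Shared fixtures: handcrafted micro-references and simulated experiments."""

from __future__ import annotations

import numpy as np
import pytest

from cdspirna import synthetic_data as syn
from cdspirna.core_io import GeneModel, GenomeAssets, Locus
from cdspirna.pipeline import ScreenExperiment, run_screen_experiment


@pytest.fixture(scope="session")
def screen_exp() -> ScreenExperiment:
    """The standard simulated screen (20 hosts, 200 decoys, two total + two
    Aub-IP libraries); shared across tests because it is the expensive run."""
    return run_screen_experiment()


@pytest.fixture(scope="session")
def small_exp() -> ScreenExperiment:
    """A down-scaled screen run for cheap structural checks."""
    return run_screen_experiment(spec=syn.SimulationSpec.small())


@pytest.fixture()
def micro_assets() -> GenomeAssets:
    """A handcrafted reference where tier membership is fully controlled.

    chr1 layout (all coordinates half-open):
      [100, 400)   rRNA locus, also overlapping geneN's exon below
      [1000, 2000) piRNA cluster; [1200, 1500) duplicates TE1[0:300)
      [3000, 3600) geneA (+): exons [3000,3300)+[3400,3600), CDS mid
      [4000, 4600) geneB (+): single exon; [4200,4250) duplicates
                   geneA [3100,3150) → a read there hits two genes
      [5000, 5400) geneN (+): single exon overlapping nothing, but its
                   first 100 bases duplicate the rRNA locus start
    """
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=6000)]

    te1 = "".join(bases[rng.integers(0, 4, size=800)])
    seq[1200:1500] = list(te1[:300])          # cluster ∩ TE sequence
    seq[4200:4250] = seq[3100:3150]           # two-gene duplication
    seq[5000:5100] = seq[100:200]             # gene ∩ rRNA sequence

    genes = [
        GeneModel("geneA", "chr1", "+",
                  exons=[(3000, 3300), (3400, 3600)],
                  utr5_span=[(3000, 3100)],
                  cds_span=[(3100, 3300), (3400, 3500)],
                  utr3_span=[(3500, 3600)]),
        GeneModel("geneB", "chr1", "+",
                  exons=[(4000, 4600)],
                  utr5_span=[(4000, 4100)],
                  cds_span=[(4100, 4500)],
                  utr3_span=[(4500, 4600)]),
        GeneModel("geneN", "chr1", "+",
                  exons=[(5000, 5400)],
                  utr5_span=[(5000, 5100)],
                  cds_span=[(5100, 5300)],
                  utr3_span=[(5300, 5400)]),
    ]
    assets = GenomeAssets(
        sequences={"chr1": "".join(seq)},
        genes=genes,
        clusters=[Locus("chr1", 1000, 2000, "cluster1", "+", "cluster")],
        te_consensus={"TE1": te1},
        non_pirna=[Locus("chr1", 100, 400, "rrna1", "+", "rRNA")],
    )
    assets.validate()
    return assets
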