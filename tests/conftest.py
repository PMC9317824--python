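import numpy as np
import pytest

from geneburden.qualify import Consequence, QualificationParams, TranscriptModel, Variant
from geneburden.simulate import GeneSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def qual_params():
    return QualificationParams(delscore_min=0.1)


@pytest.fixture(scope="session")
def toy_transcript():
    # two exons, 150 coding bases, + strand
    return TranscriptModel(
        transcript_id="TX1", gene_id="G1", strand="+",
        cds_intervals=((101, 200), (301, 350)),
    )


def make_variant(consequence, pos=150, maf=5e-4, delscore=None, gene="G1",
                 cds_fraction=None, alt="T"):
    return Variant(
        chrom="1", pos=pos, ref="C", alt=alt, gene_id=gene,
        consequence=consequence, delscore=delscore, maf=maf,
        cds_fraction=cds_fraction, af_ext=maf,
    )


@pytest.fixture(scope="session")
def crafted_variants(toy_transcript):
    """Ten crafted variants: seven qualify, three are excluded (tail
    stop-gain, common missense, unscored missense)."""
    mid = 150  # cds_fraction 0.33 on TX1
    tail = 350  # last coding base, cds_fraction 1.0
    passing = [
        make_variant(Consequence.STOP_GAINED, pos=mid),
        make_variant(Consequence.FRAMESHIFT, pos=120, alt="TA"),
        make_variant(Consequence.SPLICE_SITE, pos=201),
        make_variant(Consequence.START_LOST, pos=101),
        make_variant(Consequence.MISSENSE, pos=130, delscore=0.4),
        make_variant(Consequence.MISSENSE, pos=310, delscore=0.2),
        make_variant(Consequence.STOP_GAINED, pos=305),
    ]
    failing = [
        make_variant(Consequence.STOP_GAINED, pos=tail),       # CDS tail
        make_variant(Consequence.MISSENSE, pos=140, delscore=0.4, maf=0.02),  # common
        make_variant(Consequence.MISSENSE, pos=145),           # unscored
    ]
    return passing, failing


@pytest.fixture(scope="session")
def small_cohort():
    """Modest two-gene cohort (one predisposing, one null) reused across
    association and pipeline tests."""
    cfg = SimConfig(
        gene_specs=[
            GeneSpec(gene_id="GENE_RISK", or_lof=3.0, or_mis=1.5,
                     carrier_freq_lof=5e-3, carrier_freq_mis=8e-3,
                     recurrent_share=0.9),
            GeneSpec(gene_id="GENE_NULL", or_lof=1.0, or_mis=1.0,
                     carrier_freq_lof=3e-3, carrier_freq_mis=5e-3),
        ],
        n_cases=3000, n_controls=3000, seed=11, decoys_per_gene=3,
    )
    return simulate_cohort(cfg)
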