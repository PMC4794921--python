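import pandas as pd
import pytest

from nfkbmap import synthetic_data as sd
from nfkbmap.cistrome_combinatorics import build_occupancy_matrix
from nfkbmap.formats_io import Gene, GeneAnnotation
from nfkbmap.region_gene_assignment import assign_regions


@pytest.fixture(scope="session")
def tiny_annotation() -> GeneAnnotation:
    """Three genes on one chromosome, mixed strands, with clusters/exons."""
    return GeneAnnotation(
        [
            Gene("gA", "chr1", "+", 10_000, start=10_000, end=15_000,
                 exons=((10_000, 10_300), (14_700, 15_000)),
                 clusters=("gA.tc1", "gA.tc2")),
            Gene("gB", "chr1", "-", 59_999, start=55_000, end=60_000,
                 exons=((55_000, 55_300), (59_700, 60_000)),
                 clusters=("gB.tc1",)),
            Gene("gC", "chr1", "+", 120_000, start=120_000, end=124_000,
                 exons=((120_000, 120_300), (123_700, 124_000)),
                 clusters=("gC.tc1",)),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small planted dataset shared by assignment/target/logit tests."""
    ann = sd.simulate_genome(150, 3_000_000, seed=11)
    peaks, profiles, truth = sd.simulate_cistrome(
        ann, n_regions=200, seed=12
    )
    m = build_occupancy_matrix(peaks)
    links = assign_regions(m, ann, dhs=truth.dhs, loops=truth.loops)
    return {"ann": ann, "peaks": peaks, "profiles": profiles,
            "truth": truth, "m": m, "links": links}


@pytest.fixture()
def regulation_frame():
    """Hand-written per-gene regulation table for design-matrix tests."""
    return pd.DataFrame(
        {
            "canonical_regulated": [True, False, False, True],
            "canonical_direction": ["activated", "none", "none", "repressed"],
            "noncanonical_regulated": [False, True, False, True],
            "noncanonical_direction": ["none", "activated", "none", "repressed"],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
    )
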