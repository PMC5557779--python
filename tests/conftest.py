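import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsamap.model import BaseDepths, GenotypeMatrix, SnpSite

settings.register_profile(
    "suite", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_site(
    chrom="1H",
    pos=1000,
    ref="A",
    alts=("T",),
    p1="A",
    p2="T",
    dom=(30, 0, 0, 15),
    rec=(0, 0, 0, 40),
    **kwargs,
):
    """Compact SnpSite factory; dom/rec are (A, C, G, T) depth tuples."""
    return SnpSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=alts,
        parent1_allele=p1,
        parent2_allele=p2,
        bulk_dom=BaseDepths(*dom),
        bulk_rec=BaseDepths(*rec),
        **kwargs,
    )


# Published fine-mapping genotype matrix: 15 informative plants out of a
# recessive class of 172; markers listed in physical order.
TABLE3_PLANTS = [
    "Y225", "Y314", "Y333", "Y372", "Y401", "Y406",
    "Y316", "Y415", "Y328", "Y330", "Y331", "Y332", "Y379", "Y422", "Y444",
]
TABLE3_CALLS = {
    "HZSNP63": ["0/1"] * 6 + ["0/0"] * 9,
    "HZSNP34": ["0/0"] * 15,
    "HZSNP36": ["0/0"] * 15,
    "HZSNP32": ["0/0"] * 15,
    "HZSNP59": ["0/0"] * 6 + ["0/1", "0/1"] + ["0/0"] * 7,
    "HZSNP61": ["0/0"] * 6 + ["0/1"] * 9,
}
TABLE3_ORDER = ["HZSNP63", "HZSNP34", "HZSNP36", "HZSNP32", "HZSNP59", "HZSNP61"]


def table3_matrix(n_population=172):
    return GenotypeMatrix(
        marker_ids=list(TABLE3_ORDER),
        plant_ids=list(TABLE3_PLANTS),
        calls=[list(TABLE3_CALLS[m]) for m in TABLE3_ORDER],
        n_population=n_population,
    )


@pytest.fixture
def fine_mapping_matrix():
    return table3_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20170814)
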