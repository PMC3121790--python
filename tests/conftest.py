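import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _cds_feature(start, end, strand, locus):
    return SeqFeature(
        SimpleLocation(start, end, strand), type="CDS",
        qualifiers={"locus_tag": [locus]},
    )


@pytest.fixture(scope="session")
def toy_genome():
    """A 900-nt genome with five CDSs exercising the extraction rules.

    geneA [100,250)+ : free 100-nt UTR (clipped at the origin).
    geneB [310,400)+ : UTR clipped to 60 nt by geneA's 3' end.
    geneC [500,620)- : reverse strand; UTR clipped to 80 nt by geneD.
    geneD [700,760)+ : downstream region contains an N -> excluded.
    geneE [800,850)+ : CDS length 50, not divisible by 3 -> skipped.
    """
    rng = np.random.default_rng(2024)
    seq = list("".join(rng.choice(list("ACGT"), 900)))
    seq[100:103] = "ATG"  # geneA start
    seq[310:313] = "ATG"  # geneB start
    seq[617:620] = "CAT"  # geneC start (reverse strand ATG)
    seq[700:703] = "ATG"  # geneD start
    seq[800:803] = "ATG"  # geneE start
    seq[770] = "N"  # inside geneD's downstream region
    rec = SeqRecord(Seq("".join(seq)), id="toygenome")
    rec.features = [
        _cds_feature(100, 250, 1, "geneA"),
        _cds_feature(310, 400, 1, "geneB"),
        _cds_feature(500, 620, -1, "geneC"),
        _cds_feature(700, 760, 1, "geneD"),
        _cds_feature(800, 850, 1, "geneE"),
    ]
    return rec


@pytest.fixture(scope="session")
def contrast_set():
    """2 x 200 genes: SD-/unstructured vs SD+/structured (seed fixed)."""
    from sdscan.simulate import generate_contrast_set

    return generate_contrast_set(n_per_class=200, seed=11)


@pytest.fixture(scope="session")
def contrast_calls(contrast_set):
    from sdscan.hybridization import call_genes

    return call_genes(contrast_set.regions, scheme="strict")


@pytest.fixture(scope="session")
def panel_minus():
    from sdscan.simulate import generate_construct_panel

    return generate_construct_panel(n_constructs=12, sd_status=False, seed=0)


@pytest.fixture(scope="session")
def panel_plus():
    from sdscan.simulate import generate_construct_panel

    return generate_construct_panel(n_constructs=12, sd_status=True, seed=0)
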