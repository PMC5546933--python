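import pytest

from becall.locus import GuideRNA, TargetLocus
from becall.simulate import demo_locus


@pytest.fixture(scope="session")
def locus() -> TargetLocus:
    """The packaged synthetic demo locus (full-length 20-nt guide)."""
    return demo_locus()


@pytest.fixture(scope="session")
def locus_minus() -> TargetLocus:
    """Same physical locus built on the reverse-complemented amplicon."""
    return demo_locus(strand="-")


def make_toy_locus(spacer: str = "ACGTTGCAGATTCACG", up: str = "TTAGATTACA", down: str = "ATTAGACCTAT"):
    """A small locus (~40 bp amplicon) for exhaustive alignment checks."""
    guide = GuideRNA(name="toy", spacer=spacer)
    amplicon = up + spacer + "AGG" + down
    return TargetLocus(
        name="toy",
        amplicon=amplicon,
        protospacer_start=len(up),
        strand="+",
        guide=guide,
    )


@pytest.fixture()
def toy_locus() -> TargetLocus:
    return make_toy_locus()
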