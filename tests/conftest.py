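import pytest

from mosaicsv.genome import build_reference


@pytest.fixture()
def small_ref():
    """Fresh 2x30 kb genome (implanting mutates it, so never session-scoped)."""
    return build_reference(7, n_contigs=2, contig_length=30_000,
                           snp_density=0.0005)


@pytest.fixture(scope="session")
def plain_ref():
    """Read-only genome for alignment tests (no implants)."""
    return build_reference(11, n_contigs=2, contig_length=30_000,
                           snp_density=0.0)
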