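import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from splshuffle.library_model import BlockPartition, ParentSet
from splshuffle.synthetic_data import _CODONS_BY_AA, default_study


def parents_from_aa(aa_seqs, labels=None):
    """Deterministic ParentSet from amino-acid strings (first codon per residue)."""
    if labels is None:
        labels = tuple("PQRSTUVW"[: len(aa_seqs)])
    nt = tuple("".join(_CODONS_BY_AA[a][0] for a in s) for s in aa_seqs)
    return ParentSet(tuple(labels), tuple(aa_seqs), nt)


@pytest.fixture(scope="session")
def study():
    """Default six-parent / six-block study system (fixed seed)."""
    return default_study(seed=0)


@pytest.fixture()
def toy_parents():
    """Two 2-residue parents: KE / RD."""
    return parents_from_aa(["KE", "RD"], labels=("P1", "P2"))


@pytest.fixture()
def toy_partition():
    return BlockPartition(L_aa=2, crossovers=(1,))
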