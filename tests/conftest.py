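import numpy as np
import pytest

from crossmeta.io_ace import ContigMembership, ContigRecord, build_inventory
from crossmeta.profile import CrossProfile, build_profile


@pytest.fixture
def tiny_inventory():
    """Two samples, three reads, with sequences."""
    return build_inventory(
        [
            ("s1", {"a", "b"}, {"a": "ACGTACGT", "b": "TTTTACGT"}),
            ("s2", {"c"}, {"c": "ACGTTTTT"}),
        ]
    )


@pytest.fixture
def tiny_membership():
    return ContigMembership(
        contigs=[
            ContigRecord("c1", ("a", "c")),
            ContigRecord("c2", ("b",)),
        ]
    )


@pytest.fixture
def tiny_profile(tiny_inventory, tiny_membership):
    return build_profile(tiny_inventory, tiny_membership)


@pytest.fixture
def random_profile():
    """A 50-contig, 4-sample profile with a fixed seed."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 5, size=(50, 4))
    counts[counts.sum(axis=1) == 0, 0] = 1  # every contig needs >=1 read
    return CrossProfile(
        samples=("w", "x", "y", "z"),
        contig_ids=tuple(f"c{k}" for k in range(50)),
        counts=counts,
        singletons={s: [] for s in ("w", "x", "y", "z")},
    )


def make_profile(counts, samples=None):
    counts = np.asarray(counts)
    samples = tuple(samples or (f"s{i+1}" for i in range(counts.shape[1])))
    return CrossProfile(
        samples=samples,
        contig_ids=tuple(f"c{k+1}" for k in range(counts.shape[0])),
        counts=counts,
        singletons={s: [] for s in samples},
    )
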