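"""Cross-assembly accounting: contig x sample read counts and derived quantities.

Notation follows the cross-assembly literature: with contigs indexed
k = 1..n, ``r_ki`` is the number of reads in contig k that came from
metagenome i, ``r_i`` the total number of assembled reads of sample i,
``c_i`` the number of contigs containing at least one read from i, ``c_ij``
the number of cross-contigs (contigs with reads from both i and j), and
``p_ki = r_ki / r_i`` the fraction of i's assembled reads lying in contig k.
Singleton reads (assembled into no contig) are listed in the output table but
never enter any distance computation or denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crossmeta.io_ace import (
    ContigMembership,
    InputError,
    ReadInventory,
    match_membership_to_inventory,
)

__all__ = [
    "CrossProfile",
    "PairwiseCounts",
    "build_profile",
    "pairwise_counts",
    "abundance_vectors",
]


@dataclass(frozen=True)
class CrossProfile:
    """Contig x sample read-count matrix with singleton bookkeeping."""

    samples: tuple[str, ...]
    contig_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_contigs, n_samples), integer r_ki
    singletons: dict[str, list[str]]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.contig_ids), len(self.samples)):
            raise InputError("counts matrix shape does not match labels")
        if (counts < 0).any():
            raise InputError("read counts must be non-negative")
        if len(self.contig_ids) and (counts.sum(axis=1) < 1).any():
            raise InputError("every contig must contain at least one read")

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)

    def sample_index(self, label: str) -> int:
        try:
            return self.samples.index(label)
        except ValueError:
            raise InputError(f"unknown sample {label!r}") from None

    def assembled_totals(self) -> np.ndarray:
        """r_i for every sample (total reads incorporated into contigs)."""
        return np.asarray(self.counts).sum(axis=0)


@dataclass(frozen=True)
class PairwiseCounts:
    """The contig/read tallies a pairwise distance formula consumes."""

    sample_i: str
    sample_j: str
    c_i: int
    c_j: int
    c_ij: int
    r_i: int
    r_j: int
    r_ij: int
    r_ji: int

    def __post_init__(self) -> None:
        if not (0 <= self.c_ij <= min(self.c_i, self.c_j)):
            raise InputError("c_ij must satisfy 0 <= c_ij <= min(c_i, c_j)")
        if not (0 <= self.r_ij <= self.r_i and 0 <= self.r_ji <= self.r_j):
            raise InputError("r_ij must satisfy 0 <= r_ij <= r_i")


def build_profile(
    inventory: ReadInventory, membership: ContigMembership
) -> CrossProfile:
    """Count, for every contig, the reads contributed by each sample.

    ACE identifiers are canonicalized against the inventory first (exact
    match, then a single trailing ``.<digits>`` strip); an identifier that
    resolves to no sample is a hard error.  Inventory reads absent from every
    contig become singletons.
    """
    membership = match_membership_to_inventory(membership, inventory)
    sample_of = inventory.sample_of()
    index = {label: i for i, label in enumerate(inventory.samples)}

    counts = np.zeros((membership.n_contigs, len(inventory.samples)), dtype=np.int64)
    assembled: set[str] = set()
    for k, contig in enumerate(membership.contigs):
        for rid in contig.read_ids:
            counts[k, index[sample_of[rid]]] += 1
            assembled.add(rid)

    singletons = {
        label: sorted(inventory.reads_by_sample[label] - assembled)
        for label in inventory.samples
    }
    return CrossProfile(
        samples=tuple(inventory.samples),
        contig_ids=tuple(c.contig_id for c in membership.contigs),
        counts=counts,
        singletons=singletons,
    )


def pairwise_counts(profile: CrossProfile, i: str, j: str) -> PairwiseCounts:
    """Contig and read tallies for one unordered sample pair."""
    if i == j:
        raise InputError("pairwise counts need two distinct samples")
    ii, jj = profile.sample_index(i), profile.sample_index(j)
    col_i = np.asarray(profile.counts)[:, ii]
    col_j = np.asarray(profile.counts)[:, jj]
    r_i, r_j = int(col_i.sum()), int(col_j.sum())
    if r_i == 0:
        raise InputError(f"sample {i!r} has no assembled reads")
    if r_j == 0:
        raise InputError(f"sample {j!r} has no assembled reads")
    in_i, in_j = col_i > 0, col_j > 0
    shared = in_i & in_j
    return PairwiseCounts(
        sample_i=i,
        sample_j=j,
        c_i=int(in_i.sum()),
        c_j=int(in_j.sum()),
        c_ij=int(shared.sum()),
        r_i=r_i,
        r_j=r_j,
        r_ij=int(col_i[shared].sum()),
        r_ji=int(col_j[shared].sum()),
    )


def abundance_vectors(profile: CrossProfile) -> np.ndarray:
    """Per-sample probability vectors over contigs, ``p_ki = r_ki / r_i``.

    Columns sum to one; singletons never enter the denominator, so ``p``
    really is a probability distribution over the observed contigs.
    """
    counts = np.asarray(profile.counts, dtype=float)
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [profile.samples[z] for z in zero]
        raise InputError(f"sample(s) with no assembled reads: {bad}")
    return counts / totals
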