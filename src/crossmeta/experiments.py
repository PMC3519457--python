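"""End-to-end analyses of the synthetic experiments.

Each function generates a fixture with :mod:`crossmeta.synthetic`, pushes it
through the real pipeline (toy cross-assembly -> ACE-style membership ->
profile -> distances -> BioNJ), and returns the summary quantities the
experiment is about: distance-vs-overlap series, sister-pair recovery under
permuted abundances, and the shrinking internal branch under contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crossmeta.bionj import PhyloTree, bionj, internal_branch_length
from crossmeta.distances import (
    CROSS_ASSEMBLY_FORMULAS,
    DistanceMatrix,
    distance_matrix,
)
from crossmeta.io_ace import build_inventory
from crossmeta.kmer_profile import dinuc_profile, dist_dinuc
from crossmeta.profile import CrossProfile, build_profile
from crossmeta.synthetic import (
    SimulatedReadSet,
    experiment_abundance,
    experiment_noise,
    experiment_overlap,
    toy_cross_assemble,
)

__all__ = [
    "profile_from_readsets",
    "run_overlap_analysis",
    "run_abundance_analysis",
    "run_noise_analysis",
    "AbundanceResult",
]


def profile_from_readsets(
    readsets: list[SimulatedReadSet], k: int = 21, min_shared: int = 2
) -> CrossProfile:
    """Toy-assemble read sets and account the result like any ACE input."""
    asm = toy_cross_assemble(readsets, k=k, min_shared=min_shared)
    inventory = build_inventory(
        [(rs.sample, rs.read_ids(), rs.sequences()) for rs in readsets]
    )
    return build_profile(inventory, asm.membership)


def run_overlap_analysis(
    seed=None,
    *,
    n_steps: int = 12,
    species_per_sample: int = 10,
    n_reads: int = 2000,
    genome_length: int = 20_000,
    k: int = 21,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Distance to the reference sample as species overlap decreases.

    Every step is cross-assembled pairwise with the reference and all four
    cross-assembly distances plus the dinucleotide odds-ratio distance are
    computed.  Returns one row per step with columns ``overlap``, ``shot``,
    ``minimum``, ``wootters``, ``reads`` and ``dinuc``.
    """
    fixture = experiment_overlap(
        n_steps,
        species_per_sample,
        seed,
        n_reads=n_reads,
        genome_length=genome_length,
    )
    ref = fixture.reference
    ref_dinuc = dinuc_profile([r.sequence for r in ref.reads], ref.sample)
    rows = []
    for overlap, rs in fixture.steps:
        profile = profile_from_readsets([ref, rs], k=k, min_shared=min_shared)
        row = {"step": rs.sample, "overlap": overlap}
        for formula in CROSS_ASSEMBLY_FORMULAS:
            row[formula] = distance_matrix(profile, formula)[ref.sample, rs.sample]
        step_dinuc = dinuc_profile([r.sequence for r in rs.reads], rs.sample)
        row["dinuc"] = dist_dinuc(ref_dinuc, step_dinuc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AbundanceResult:
    profile: CrossProfile
    matrices: dict[str, DistanceMatrix]
    trees: dict[str, PhyloTree]
    pairs: list[tuple[str, str]]
    sisters_recovered: dict[str, dict[tuple[str, str], bool]]

    def all_pairs_recovered(self, formula: str) -> bool:
        return all(self.sisters_recovered[formula].values())


def run_abundance_analysis(
    seed=None,
    *,
    n_pairs: int = 4,
    species: int = 10,
    n_reads: int = 1500,
    genome_length: int = 300_000,
    k: int = 21,
    min_shared: int = 2,
) -> AbundanceResult:
    """Joint cross-assembly of permuted-abundance pairs, with sister checks.

    A pair counts as recovered by a formula when the BioNJ tree for that
    formula contains an edge separating exactly that pair from all other
    samples.
    """
    fixture = experiment_abundance(
        n_pairs, species, seed, n_reads=n_reads, genome_length=genome_length
    )
    profile = profile_from_readsets(fixture.readsets, k=k, min_shared=min_shared)
    all_labels = set(profile.samples)
    matrices: dict[str, DistanceMatrix] = {}
    trees: dict[str, PhyloTree] = {}
    recovered: dict[str, dict[tuple[str, str], bool]] = {}
    for formula in CROSS_ASSEMBLY_FORMULAS:
        dm = distance_matrix(profile, formula)
        tree = bionj(dm)
        matrices[formula] = dm
        trees[formula] = tree
        status: dict[tuple[str, str], bool] = {}
        for pair in fixture.pairs:
            side = set(pair)
            length = internal_branch_length(tree, (side, all_labels - side))
            status[pair] = length is not None
        recovered[formula] = status
    return AbundanceResult(
        profile=profile,
        matrices=matrices,
        trees=trees,
        pairs=fixture.pairs,
        sisters_recovered=recovered,
    )


def run_noise_analysis(
    seed=None,
    *,
    noise_levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_pool_a: int = 3,
    n_pool_b: int = 6,
    species_per_sample: int = 5,
    n_reads: int = 500,
    genome_length: int = 150_000,
    divergence: float = 0.03,
    k: int = 21,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Length of the pool-separating internal branch across noise levels.

    For every noise level the nine samples are jointly cross-assembled and,
    per distance formula, the BioNJ tree is checked for the bipartition that
    separates the pool-A samples from the pool-B samples.  Returns one row
    per level with, per formula, the branch length of that bipartition (0.0
    when absent) and whether it was present.
    """
    fixture = experiment_noise(
        noise_levels,
        seed,
        n_pool_a=n_pool_a,
        n_pool_b=n_pool_b,
        species_per_sample=species_per_sample,
        n_reads=n_reads,
        genome_length=genome_length,
        divergence=divergence,
    )
    rows = []
    for level in fixture.levels:
        readsets = fixture.readsets_by_level[level]
        profile = profile_from_readsets(readsets, k=k, min_shared=min_shared)
        labels = list(profile.samples)
        side_a = {l for l in labels if l.startswith("A")}
        side_b = set(labels) - side_a
        row: dict = {"noise": level}
        for formula in CROSS_ASSEMBLY_FORMULAS:
            tree = bionj(distance_matrix(profile, formula))
            length = internal_branch_length(tree, (side_a, side_b))
            row[formula] = float(length) if length is not None else 0.0
            row[f"{formula}_present"] = length is not None
        rows.append(row)
    return pd.DataFrame(rows)
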