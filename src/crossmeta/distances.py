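"""Pairwise distance formulas between cross-assembled metagenomes.

Four formulas, all mapping to [0, 1] with 0 for complete sharing:

``shot``
    Gene-content-style distance correcting shared-contig counts for sample
    size: the similarity is ``c_ij * sqrt((c_i^2 + c_j^2) / (2 c_i^2 c_j^2))``
    -- equivalently the root mean square of the separately normalized
    fractions ``c_ij/c_i`` and ``c_ij/c_j`` (the square of the geometric mean
    of c_i and c_j divided by their root mean square, as a denominator).
``minimum``
    Normalizes the shared-contig count by the smaller sample:
    ``1 - c_ij / min(c_i, c_j)``.
``wootters``
    A statistical distance between the per-sample probability vectors over
    contigs: ``(2/pi) * arccos(sum_k sqrt(p_ki * p_kj))``, i.e. the angle
    subtended by the two distributions on the probability simplex
    (Bhattacharyya angle), interpretable as the minimum number of statistical
    "jumps" needed to morph one distribution into the other.
``reads``
    Mirrors ``shot`` but on read fractions instead of contig fractions:
    ``1 - rms(r_ij/r_i, r_ji/r_j)``.  Less sensitive to long contigs
    attracting stray reads.

Because the RMS of two fractions is at most their maximum,
``dist_shot >= dist_minimum`` always, strictly whenever ``c_i != c_j`` and
``c_ij > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from crossmeta.io_ace import InputError
from crossmeta.profile import CrossProfile, PairwiseCounts, abundance_vectors, pairwise_counts

__all__ = [
    "DistanceMatrix",
    "dist_shot",
    "dist_minimum",
    "dist_wootters",
    "dist_reads",
    "distance_matrix",
    "CROSS_ASSEMBLY_FORMULAS",
]

CROSS_ASSEMBLY_FORMULAS = ("shot", "minimum", "wootters", "reads")


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    formula_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise InputError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append(lab + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        return path

    def write_phylip(self, path: str | Path) -> Path:
        """Relaxed PHYLIP square distance format (name, whitespace, values)."""
        path = Path(path)
        lines = [f"{len(self.labels)}"]
        width = max(10, max(len(l) for l in self.labels) + 2)
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.values[i])
            lines.append(lab.ljust(width) + row)
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        return path


# ---------------------------------------------------------------------------
# single-pair formulas


def dist_shot(pc: PairwiseCounts) -> float:
    """Size-corrected shared-contig distance (presence/absence based)."""
    if pc.c_i <= 0 or pc.c_j <= 0:
        raise InputError("shot distance needs c_i > 0 and c_j > 0")
    ci, cj = float(pc.c_i), float(pc.c_j)
    sim = pc.c_ij * math.sqrt((ci * ci + cj * cj) / (2.0 * ci * ci * cj * cj))
    return 1.0 - min(sim, 1.0)


def dist_minimum(pc: PairwiseCounts) -> float:
    """Shared contigs normalized by the smaller sample's contig count."""
    if pc.c_i <= 0 or pc.c_j <= 0:
        raise InputError("minimum distance needs c_i > 0 and c_j > 0")
    return 1.0 - pc.c_ij / min(pc.c_i, pc.c_j)


def dist_wootters(p_i, p_j, scaled: bool = True) -> float:
    """Statistical distance between two probability vectors over contigs.

    ``arccos`` of the Bhattacharyya coefficient; with ``scaled`` (default) the
    result is multiplied by 2/pi so that disjoint support gives exactly 1,
    commensurate with the other formulas.  ``scaled=False`` returns raw
    radians in [0, pi/2].
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if p_i.shape != p_j.shape or p_i.ndim != 1:
        raise InputError("probability vectors must be 1-D and of equal length")
    if (p_i < 0).any() or (p_j < 0).any():
        raise InputError("probability vectors must be non-negative")
    for name, p in (("p_i", p_i), ("p_j", p_j)):
        if abs(p.sum() - 1.0) > 1e-9:
            raise InputError(f"{name} does not sum to 1 (sum={p.sum()!r})")
    # accumulate in sorted order for run-to-run reproducibility
    terms = np.sort(np.sqrt(p_i * p_j))
    bha = min(max(float(terms.sum()), 0.0), 1.0)
    angle = math.acos(bha)
    return angle * (2.0 / math.pi) if scaled else angle


def dist_reads(pc: PairwiseCounts) -> float:
    """Size-corrected shared-read distance (abundance based)."""
    if pc.r_i <= 0 or pc.r_j <= 0:
        raise InputError("reads distance needs r_i > 0 and r_j > 0")
    fi = pc.r_ij / pc.r_i
    fj = pc.r_ji / pc.r_j
    return 1.0 - min(math.sqrt((fi * fi + fj * fj) / 2.0), 1.0)


# ---------------------------------------------------------------------------
# full matrices


def distance_matrix(profile: CrossProfile, formula: str) -> DistanceMatrix:
    """Apply one of the four cross-assembly formulas to every sample pair."""
    if formula not in CROSS_ASSEMBLY_FORMULAS:
        raise InputError(
            f"unknown formula {formula!r}; expected one of {CROSS_ASSEMBLY_FORMULAS}"
        )
    labels = profile.samples
    n = len(labels)
    if n < 2:
        raise InputError("need >=2 samples for a distance matrix")
    D = np.zeros((n, n), dtype=float)
    p = abundance_vectors(profile) if formula == "wootters" else None
    for a in range(n):
        for b in range(a + 1, n):
            if formula == "wootters":
                d = dist_wootters(p[:, a], p[:, b])
            else:
                pc = pairwise_counts(profile, labels[a], labels[b])
                d = {"shot": dist_shot, "minimum": dist_minimum, "reads": dist_reads}[
                    formula
                ](pc)
            D[a, b] = D[b, a] = d
    return DistanceMatrix(labels=tuple(labels), values=D, formula_name=formula)
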