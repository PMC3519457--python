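"""Dinucleotide odds-ratio signatures and the derived inter-sample distance.

The dinucleotide odds ratio rho*_XY = f*_XY / (f*_X f*_Y) compares the
observed frequency of the dinucleotide XY with the expectation under
independence of its two bases, computed strand-symmetrically: every read is
counted together with its reverse complement (separately -- no junction
windows are formed across reads or between a read and its own reverse
complement).  The 16-component vector of odds ratios is a compositional
signature that separates taxa of different base composition, and serves as a
reference- and assembly-independent baseline for comparing metagenomes; a
word length of two is the classic choice for such signatures.

The distance between two samples is the average absolute difference of their
odds ratios, delta* = (1/16) sum_XY |rho*a_XY - rho*b_XY| (Karlin's
convention), an exact pseudometric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from crossmeta.io_ace import InputError
from crossmeta.distances import DistanceMatrix

__all__ = [
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
    "DinucProfile",
    "dinuc_profile",
    "dist_dinuc",
    "dinuc_distance_matrix",
    "write_profile_table",
]

NUCLEOTIDES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; anything not ACGT (case-insensitive) maps to -1 and
# breaks both mononucleotide and dinucleotide windows
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DinucProfile:
    """Strand-symmetric dinucleotide odds-ratio signature of one sample."""

    sample: str
    rho: dict[str, float]
    mono: dict[str, float]
    total_nt: int

    def __post_init__(self) -> None:
        if set(self.rho) != set(DINUCLEOTIDES):
            raise InputError("rho must contain all 16 dinucleotides")
        if abs(sum(self.mono.values()) - 1.0) > 1e-9:
            raise InputError("mononucleotide frequencies must sum to 1")
        if any(v < 0 for v in self.rho.values()):
            raise InputError("odds ratios must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.rho[d] for d in DINUCLEOTIDES], dtype=float)


def _concatenate_codes(parts: Iterable[str]) -> np.ndarray:
    # join with a sentinel 'N' so no window spans two parts
    joined = "N".join(parts)
    raw = np.frombuffer(joined.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


def dinuc_profile(sequences: Iterable[str], sample: str = "") -> DinucProfile:
    """Compute the dinucleotide odds-ratio signature of a read collection.

    Each read contributes its forward sequence and its reverse complement
    (counted separately, so the profile is exactly invariant under
    reverse-complementing any read).  Ambiguous bases break windows:
    dinucleotides containing them are skipped and they do not enter
    mononucleotide counts.
    """
    seqs = [s for s in sequences if s]
    if not seqs:
        raise InputError("no sequences provided")
    both = seqs + [revcomp(s) for s in seqs]
    codes = _concatenate_codes(both)

    valid = codes >= 0
    mono_counts = np.bincount(codes[valid], minlength=4).astype(float)
    total_mono = mono_counts.sum()

    a, b = codes[:-1], codes[1:]
    pair_ok = (a >= 0) & (b >= 0)
    if not pair_ok.any():
        raise InputError("no usable dinucleotide windows in input")
    pair_codes = 4 * a[pair_ok].astype(np.int64) + b[pair_ok]
    di_counts = np.bincount(pair_codes, minlength=16).astype(float)
    total_di = di_counts.sum()

    f_mono = mono_counts / total_mono
    f_di = di_counts / total_di
    rho = {}
    for idx, xy in enumerate(DINUCLEOTIDES):
        denom = f_mono[NUCLEOTIDES.index(xy[0])] * f_mono[NUCLEOTIDES.index(xy[1])]
        rho[xy] = float(f_di[idx] / denom) if denom > 0 else 0.0
    mono = {nt: float(f_mono[i]) for i, nt in enumerate(NUCLEOTIDES)}
    # forward and reverse strands contribute equally, so halving recovers the
    # number of unambiguous nucleotides actually read
    return DinucProfile(sample=sample, rho=rho, mono=mono,
                        total_nt=int(total_mono) // 2)


def dist_dinuc(a: DinucProfile, b: DinucProfile) -> float:
    """Average absolute odds-ratio difference, delta* (a pseudometric)."""
    return float(np.abs(a.as_vector() - b.as_vector()).sum() / 16.0)


def dinuc_distance_matrix(profiles: Sequence[DinucProfile]) -> DistanceMatrix:
    """All-pairs delta* distances between sample signatures."""
    if len(profiles) < 2:
        raise InputError("need >=2 profiles for a distance matrix")
    labels = tuple(p.sample for p in profiles)
    if len(set(labels)) != len(labels):
        raise InputError("profile sample labels must be unique")
    n = len(profiles)
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist_dinuc(profiles[i], profiles[j])
    return DistanceMatrix(labels=labels, values=D, formula_name="dinuc")


def write_profile_table(profiles: Sequence[DinucProfile], path: str | Path) -> Path:
    """Write one row per sample with the 16 odds ratios, tab-separated."""
    path = Path(path)
    lines = ["sample\t" + "\t".join(DINUCLEOTIDES)]
    for p in profiles:
        lines.append(p.sample + "\t" + "\t".join(f"{p.rho[d]:.6f}" for d in DINUCLEOTIDES))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path
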