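"""Synthetic communities, pyrosequencing-like reads and a toy cross-assembly.

Everything here exists so that the whole pipeline — ACE parsing, contig
accounting, distance formulas, trees — can be exercised end-to-end with exact
ground truth and no external data.  The generator emulates, at desk scale,
the simulation design used to validate cross-assembly distances:

* genome pools playing the role of bacterial phyla, distinguishable by
  disjoint GC ranges (a low-GC pool standing in for *Firmicutes*, a high-GC
  one for *Actinobacteria*, a mid-GC contaminant pool for *Proteobacteria*);
* communities with uniform or logarithmic (rank-decay) species abundances and
  an optional contamination ("noise") fraction drawn from the contaminant
  pool;
* pyrosequencing-like reads: length 450 +/- 100 nt (truncated), 2 % errors
  split 85 % substitutions / 15 % indels, with error probability inflated
  inside homopolymer runs >= 3 nt (a simplified homopolymer error model);
* a toy cross-assembler that single-linkage-clusters reads sharing at least
  ``min_shared`` exact canonical k-mers and emits a valid ACE file, together
  with the true genome-of-origin composition of every contig.

Genome scale is reduced from megabases to tens of kilobases and community
size from ~30 to ~10 species so every experiment runs in minutes; the
statistical structure (overlap series, log abundances, noise gradient) is
preserved.  All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from crossmeta.io_ace import ContigMembership, ContigRecord, InputError
from crossmeta.kmer_profile import revcomp

__all__ = [
    "Genome",
    "CommunitySpec",
    "SimRead",
    "SimulatedReadSet",
    "ToyAssembly",
    "make_genome_pool",
    "random_dinuc_bias",
    "logarithmic_abundances",
    "uniform_abundances",
    "sample_reads",
    "toy_cross_assemble",
    "experiment_overlap",
    "experiment_abundance",
    "experiment_noise",
    "OverlapFixture",
    "AbundanceFixture",
    "NoiseFixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class Genome:
    id: str
    sequence: str
    gc: float  # target GC used at generation time
    pool: str

    def __len__(self) -> int:
        return len(self.sequence)


def _draw_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def random_dinuc_bias(rng, sigma: float = 0.25) -> np.ndarray:
    """Random log-normal 4x4 dinucleotide bias matrix.

    Real genomes over- and under-represent specific dinucleotides (CpG or TpA
    depletion, for instance) in a lineage-specific way; that signature — not
    base composition, which odds ratios divide out — is what dinucleotide
    signatures distinguish taxa by.  A pool generated with one of these
    matrices carries a coherent signature distinct from other pools'.
    """
    rng = _rng(rng)
    return np.exp(rng.normal(0.0, sigma, size=(4, 4)))


def _markov_bases(
    rng: np.random.Generator, length: int, gc: float, bias: np.ndarray
) -> np.ndarray:
    """First-order Markov sequence with target composition and dinuc bias.

    Transition rows are proportional to ``pi_adj[Y] * bias[X, Y]``; ``pi_adj``
    is fixed-point adjusted so the chain's stationary composition matches the
    GC target despite the bias.
    """
    at = (1.0 - gc) / 2.0
    target = np.array([at, gc / 2.0, gc / 2.0, at])
    pi_adj = target.copy()
    for _ in range(25):
        P = pi_adj[None, :] * bias
        P /= P.sum(axis=1, keepdims=True)
        w = target.copy()
        for _ in range(60):
            w = w @ P
        pi_adj *= target / np.maximum(w, 1e-12)
        pi_adj /= pi_adj.sum()
    P = pi_adj[None, :] * bias
    P /= P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    cum_list = cum.tolist()
    u = rng.random(length).tolist()
    out = np.empty(length, dtype=np.int8)
    state = int(rng.choice(4, p=target))
    for i in range(length):
        row = cum_list[state]
        x = u[i]
        state = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = state
    return out


def make_genome_pool(
    n_genomes: int,
    length_range: tuple[int, int] = (20_000, 100_000),
    gc_range: tuple[float, float] = (0.3, 0.7),
    seed=None,
    *,
    pool: str = "pool",
    divergence: float | None = None,
    dinuc_bias: np.ndarray | None = None,
) -> list[Genome]:
    """Generate a pool of random genomes with controlled GC content.

    With ``divergence=None`` every genome is an independent random sequence:
    genomes share no long k-mers, so reads from different genomes never
    cross-assemble.  With a ``divergence`` fraction (e.g. 0.03) all genomes
    in the pool descend from one random ancestor and differ from it by that
    fraction of substituted sites — species in the pool are then homologous
    ("similar but not the same"), and reads from different species share long
    identical stretches, as congeneric bacteria do.

    ``dinuc_bias`` (a 4x4 matrix, see :func:`random_dinuc_bias`) generates the
    sequences from a first-order Markov chain instead of iid draws, giving
    the whole pool a coherent dinucleotide signature on top of its GC
    content; without it the pool's dinucleotide odds ratios are ~1, which no
    real taxon's are.
    """
    if n_genomes < 1:
        raise InputError("need at least one genome")
    lo, hi = length_range
    if not (1_000 <= lo <= hi):
        raise InputError("genome lengths must be >=1 kb and lo <= hi")
    g_lo, g_hi = gc_range
    if not (0.0 < g_lo <= g_hi < 1.0):
        raise InputError("GC range must satisfy 0 < lo <= hi < 1")
    if divergence is not None and not (0.0 <= divergence <= 0.5):
        raise InputError("divergence must lie in [0, 0.5]")
    rng = _rng(seed)

    lengths = rng.integers(lo, hi + 1, size=n_genomes)
    gcs = rng.uniform(g_lo, g_hi, size=n_genomes)
    def fresh(length: int, gc: float) -> np.ndarray:
        if dinuc_bias is not None:
            return _markov_bases(rng, length, gc, np.asarray(dinuc_bias, float))
        return _draw_bases(rng, length, gc)

    genomes: list[Genome] = []
    if divergence is None:
        for t in range(n_genomes):
            codes = fresh(int(lengths[t]), float(gcs[t]))
            seq = _BASES[codes].tobytes().decode("ascii")
            genomes.append(Genome(f"{pool}_g{t:03d}", seq, float(gcs[t]), pool))
    else:
        ancestor = fresh(hi, (g_lo + g_hi) / 2.0)
        for t in range(n_genomes):
            codes = ancestor[: int(lengths[t])].copy()
            mut = rng.random(codes.size) < divergence
            codes[mut] = _draw_bases(rng, int(mut.sum()), float(gcs[t]))
            seq = _BASES[codes.astype(np.int8)].tobytes().decode("ascii")
            genomes.append(Genome(f"{pool}_g{t:03d}", seq, float(gcs[t]), pool))
    return genomes


# ---------------------------------------------------------------------------
# communities


def logarithmic_abundances(n: int, decay: float = 0.5) -> np.ndarray:
    """Rank-decay abundances a_r proportional to decay**rank, normalized.

    ``decay=0.5`` (rank-halving) is the default logarithmic profile.
    """
    if n < 1:
        raise InputError("need at least one species")
    if not (0.0 < decay <= 1.0):
        raise InputError("decay must lie in (0, 1]")
    a = decay ** np.arange(n, dtype=float)
    return a / a.sum()


def uniform_abundances(n: int) -> np.ndarray:
    if n < 1:
        raise InputError("need at least one species")
    return np.full(n, 1.0 / n)


@dataclass(frozen=True)
class CommunitySpec:
    """One sample: its member species, abundances and contamination level."""

    label: str
    members: tuple[tuple[str, float], ...]
    n_reads: int
    noise_fraction: float = 0.0
    contaminants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        abunds = np.array([a for _, a in self.members], dtype=float)
        if (abunds <= 0).any():
            raise InputError("abundances must be positive")
        if abs(abunds.sum() - 1.0) > 1e-9:
            raise InputError("abundances must sum to 1")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise InputError("noise fraction must lie in [0, 1]")
        if self.noise_fraction > 0 and not self.contaminants:
            raise InputError("noise fraction > 0 needs a contaminant pool")
        if self.n_reads <= 0:
            raise InputError("n_reads must be positive")


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sample: str
    genome_id: str
    start: int
    strand: str  # "+" or "-"
    sequence: str


@dataclass
class SimulatedReadSet:
    sample: str
    reads: list[SimRead]

    def read_ids(self) -> set[str]:
        return {r.read_id for r in self.reads}

    def sequences(self) -> dict[str, str]:
        return {r.read_id: r.sequence for r in self.reads}

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="\n") as fh:
            for r in self.reads:
                fh.write(f">{r.read_id}\n{r.sequence}\n")
        return path

    def write_fastq(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="\n") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
        return path

    def write_provenance(self, path: str | Path) -> Path:
        """Ground-truth table: read id, sample, source genome, start, strand."""
        path = Path(path)
        lines = ["read_id\tsample\tgenome_id\tstart\tstrand"]
        for r in self.reads:
            lines.append(f"{r.read_id}\t{r.sample}\t{r.genome_id}\t{r.start}\t{r.strand}")
        path.write_text("\n".join(lines) + "\n", newline="\n")
        return path


def _homopolymer_mask(codes: np.ndarray, min_run: int) -> np.ndarray:
    """Boolean mask of positions lying inside homopolymer runs >= min_run."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = codes[1:] != codes[:-1]
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def _apply_errors(
    codes: np.ndarray,
    hp_mask: np.ndarray,
    rng: np.random.Generator,
    error_rate: float,
    sub_fraction: float,
    hp_factor: float,
) -> np.ndarray:
    """Apply substitution and indel errors to a read (2-bit codes)."""
    if error_rate <= 0:
        return codes
    p = np.full(codes.size, error_rate)
    p[hp_mask] = np.minimum(error_rate * hp_factor, 1.0)
    hit = np.flatnonzero(rng.random(codes.size) < p)
    if hit.size == 0:
        return codes
    out = codes.copy()
    kinds = rng.random(hit.size)
    subs = hit[kinds < sub_fraction]
    if subs.size:
        out[subs] = (out[subs] + rng.integers(1, 4, size=subs.size)) % 4
    indels = hit[kinds >= sub_fraction]
    if indels.size:
        ins_mask = rng.random(indels.size) < 0.5
        ins_pos = indels[ins_mask]
        del_pos = indels[~ins_mask]
        if del_pos.size:
            out = np.delete(out, del_pos)
            # shift insertion positions left past any deletions before them
            ins_pos = ins_pos - np.searchsorted(np.sort(del_pos), ins_pos)
        if ins_pos.size:
            out = np.insert(out, np.clip(ins_pos, 0, out.size),
                            rng.integers(0, 4, size=ins_pos.size))
    return out


def sample_reads(
    spec: CommunitySpec,
    pool: Mapping[str, Genome] | Sequence[Genome],
    seed=None,
    *,
    read_length_mean: float = 450.0,
    read_length_sd: float = 100.0,
    read_length_min: int = 50,
    error_rate: float = 0.02,
    sub_fraction: float = 0.85,
    homopolymer_factor: float = 3.0,
    homopolymer_min_run: int = 3,
) -> SimulatedReadSet:
    """Draw pyrosequencing-like reads from a community.

    Each read picks a source genome (a contaminant with probability
    ``spec.noise_fraction``, else a member weighted by abundance), a length
    from a normal(450, 100) truncated to [50, genome length], a uniform start
    and strand, and then suffers per-base errors at ``error_rate`` (85 %
    substitutions, 15 % indels split evenly between insertions and
    deletions), with the error probability multiplied by
    ``homopolymer_factor`` inside homopolymer runs of >= 3 nt.  Ground-truth
    provenance (genome, start, strand) is recorded per read.
    """
    if isinstance(pool, Mapping):
        genomes = dict(pool)
    else:
        genomes = {g.id: g for g in pool}
    for gid, _ in spec.members:
        if gid not in genomes:
            raise InputError(f"community member {gid!r} not in genome pool")
    for gid in spec.contaminants:
        if gid not in genomes:
            raise InputError(f"contaminant {gid!r} not in genome pool")
    rng = _rng(seed)

    member_ids = [gid for gid, _ in spec.members]
    member_p = np.array([a for _, a in spec.members])
    codes_cache: dict[str, np.ndarray] = {}
    hp_cache: dict[str, np.ndarray] = {}

    def codes_of(gid: str) -> tuple[np.ndarray, np.ndarray]:
        if gid not in codes_cache:
            raw = np.frombuffer(genomes[gid].sequence.encode("ascii"), dtype=np.uint8)
            c = _CODE[raw].astype(np.int8)
            codes_cache[gid] = c
            hp_cache[gid] = _homopolymer_mask(c, homopolymer_min_run)
        return codes_cache[gid], hp_cache[gid]

    reads: list[SimRead] = []
    is_noise = rng.random(spec.n_reads) < spec.noise_fraction
    lengths = np.rint(rng.normal(read_length_mean, read_length_sd, spec.n_reads))
    for idx in range(spec.n_reads):
        if is_noise[idx]:
            gid = spec.contaminants[rng.integers(len(spec.contaminants))]
        else:
            gid = member_ids[rng.choice(len(member_ids), p=member_p)]
        codes, hp = codes_of(gid)
        glen = codes.size
        length = int(min(max(lengths[idx], read_length_min), glen))
        start = int(rng.integers(0, glen - length + 1))
        frag = codes[start : start + length]
        frag_hp = hp[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = (3 - frag)[::-1]
            frag_hp = frag_hp[::-1]
        frag = _apply_errors(frag, frag_hp, rng, error_rate, sub_fraction,
                             homopolymer_factor)
        seq = _BASES[frag.astype(np.int8)].tobytes().decode("ascii")
        reads.append(
            SimRead(
                read_id=f"{spec.label}_r{idx:05d}",
                sample=spec.label,
                genome_id=gid,
                start=start,
                strand=strand,
                sequence=seq,
            )
        )
    return SimulatedReadSet(sample=spec.label, reads=reads)


# ---------------------------------------------------------------------------
# toy cross-assembler


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _read_kmers(seq: str, k: int) -> np.ndarray:
    """Distinct canonical k-mers of one read as int64 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw].astype(np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ok = codes >= 0
    fwd = np.zeros(n, dtype=np.int64)
    window_ok = np.ones(n, dtype=bool)
    rc_codes = (3 - codes)[::-1]
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | codes[j : j + n]
        rev = (rev << 2) | rc_codes[j : j + n]
        window_ok &= ok[j : j + n]
    # window i on the forward strand corresponds to window n-1-i on the
    # reverse complement
    canon = np.minimum(fwd, rev[::-1])
    return np.unique(canon[window_ok])


@dataclass
class ToyAssembly:
    """A toy cross-assembly plus the exact ground truth behind it."""

    membership: ContigMembership
    singletons: dict[str, list[str]]
    genome_composition: dict[str, Counter]  # contig id -> genome -> n reads
    sample_composition: dict[str, Counter]  # contig id -> sample -> n reads
    samples: tuple[str, ...]

    def write_ace(self, path: str | Path) -> Path:
        """Emit a minimal consed-dialect ACE file (CO + AF records)."""
        path = Path(path)
        n_reads = sum(len(c.read_ids) for c in self.membership.contigs)
        lines = [f"AS {self.membership.n_contigs} {n_reads}", ""]
        for contig in self.membership.contigs:
            lines.append(
                f"CO {contig.contig_id} {100 * len(contig.read_ids)} "
                f"{len(contig.read_ids)} 1 U"
            )
            for off, rid in enumerate(contig.read_ids, start=1):
                lines.append(f"AF {rid} U {off}")
            lines.append("")
        path.write_text("\n".join(lines) + "\n", newline="\n")
        return path


def toy_cross_assemble(
    readsets: Sequence[SimulatedReadSet],
    k: int = 21,
    min_shared: int = 2,
) -> ToyAssembly:
    """Single-linkage cluster reads sharing >= ``min_shared`` canonical k-mers.

    Deliberately conservative (exact k-mer matches only, two witnesses by
    default) to avoid chimeric clusters.  Multi-read clusters become contigs,
    ordered by their smallest read index for determinism; remaining reads are
    singletons.  Returns the membership together with the true genome/sample
    composition of every contig.
    """
    if not (15 <= k <= 31):
        raise InputError("k must lie in [15, 31]")
    if min_shared < 1:
        raise InputError("min_shared must be >= 1")
    all_reads: list[SimRead] = []
    for rs in readsets:
        all_reads.extend(rs.reads)
    if not all_reads:
        raise InputError("no reads to assemble")

    # (kmer, read index) pairs over all reads, deduplicated within each read
    kmer_arrays = []
    idx_arrays = []
    for ridx, read in enumerate(all_reads):
        km = _read_kmers(read.sequence, k)
        if km.size:
            kmer_arrays.append(km)
            idx_arrays.append(np.full(km.size, ridx, dtype=np.int64))
    kmers = np.concatenate(kmer_arrays) if kmer_arrays else np.empty(0, np.int64)
    ridx = np.concatenate(idx_arrays) if idx_arrays else np.empty(0, np.int64)
    order = np.lexsort((ridx, kmers))
    kmers, ridx = kmers[order], ridx[order]

    # all within-group read pairs, generated per offset so groups of any size
    # are handled without a Python loop over groups
    pair_keys = []
    n_total = len(all_reads)
    t = 1
    while True:
        if t >= kmers.size:
            break
        same = kmers[:-t] == kmers[t:]
        if not same.any():
            break
        a = ridx[:-t][same]
        b = ridx[t:][same]
        pair_keys.append(a * n_total + b)  # a < b within a sorted group
        t += 1

    uf = _UnionFind(n_total)
    if pair_keys:
        keys = np.concatenate(pair_keys)
        uniq, counts = np.unique(keys, return_counts=True)
        good = uniq[counts >= min_shared]
        for key in good.tolist():
            uf.union(key // n_total, key % n_total)

    clusters: dict[int, list[int]] = {}
    for i in range(n_total):
        clusters.setdefault(uf.find(i), []).append(i)

    multi = sorted((v for v in clusters.values() if len(v) > 1), key=lambda v: v[0])
    contigs: list[ContigRecord] = []
    genome_comp: dict[str, Counter] = {}
    sample_comp: dict[str, Counter] = {}
    for c, members in enumerate(multi):
        cid = f"ctg{c:05d}"
        contigs.append(ContigRecord(cid, tuple(all_reads[i].read_id for i in members)))
        genome_comp[cid] = Counter(all_reads[i].genome_id for i in members)
        sample_comp[cid] = Counter(all_reads[i].sample for i in members)

    in_contig = {i for v in multi for i in v}
    singles: dict[str, list[str]] = {rs.sample: [] for rs in readsets}
    for i, read in enumerate(all_reads):
        if i not in in_contig:
            singles[read.sample].append(read.read_id)

    membership = ContigMembership(
        contigs=contigs,
        declared_counts={c.contig_id: len(c.read_ids) for c in contigs},
    )
    return ToyAssembly(
        membership=membership,
        singletons=singles,
        genome_composition=genome_comp,
        sample_composition=sample_comp,
        samples=tuple(rs.sample for rs in readsets),
    )


# ---------------------------------------------------------------------------
# the three simulation experiments (desk-scale replicas)


@dataclass
class OverlapFixture:
    """Reference sample plus a series of samples with decreasing overlap."""

    reference: SimulatedReadSet
    steps: list[tuple[float, SimulatedReadSet]]  # (true overlap fraction, reads)
    pools: dict[str, list[Genome]]


@dataclass
class AbundanceFixture:
    """Pairs of samples sharing a permuted logarithmic abundance profile."""

    readsets: list[SimulatedReadSet]
    pairs: list[tuple[str, str]]
    abundances: dict[str, np.ndarray]
    pool: list[Genome]


@dataclass
class NoiseFixture:
    """Two signal pools of samples plus a shared contaminant gradient."""

    levels: list[float]
    readsets_by_level: dict[float, list[SimulatedReadSet]]
    pool_a_samples: list[str]
    pool_b_samples: list[str]
    pools: dict[str, list[Genome]]


def experiment_overlap(
    n_steps: int = 12,
    species_per_sample: int = 10,
    seed=None,
    *,
    n_reads: int = 2000,
    genome_length: int = 20_000,
) -> OverlapFixture:
    """Series of communities with species overlap decreasing from 1 to 0.

    Sample 0 is the reference (all species from the low-GC pool); sample 1
    contains the same species; each subsequent sample replaces one more
    species with a genome from the mid-GC replacement pool, until the final
    sample shares no species with the reference.  With the defaults that is
    12 samples over 10 species.  Each step is meant to be cross-assembled
    pairwise with the reference.
    """
    if n_steps < 3:
        raise InputError("need at least 3 steps")
    if n_steps > species_per_sample + 2:
        raise InputError(
            "cannot replace more species than the sample contains "
            f"({n_steps} steps need {n_steps - 2} replacements but the sample "
            f"has {species_per_sample} species)"
        )
    rng = _rng(seed)
    lr = (genome_length, genome_length)
    pool_f = make_genome_pool(species_per_sample, lr, (0.32, 0.42), rng,
                              pool="lowgc", dinuc_bias=random_dinuc_bias(rng))
    pool_p = make_genome_pool(n_steps - 2, lr, (0.48, 0.58), rng,
                              pool="midgc", dinuc_bias=random_dinuc_bias(rng))
    genomes = {g.id: g for g in pool_f + pool_p}

    def community(label: str, member_genomes: list[Genome]) -> CommunitySpec:
        n = len(member_genomes)
        return CommunitySpec(
            label=label,
            members=tuple((g.id, 1.0 / n) for g in member_genomes),
            n_reads=n_reads,
        )

    reference = sample_reads(community("ov00", pool_f), genomes, rng)
    steps: list[tuple[float, SimulatedReadSet]] = []
    for t in range(1, n_steps):
        replaced = t - 1
        members = pool_f[replaced:] + pool_p[:replaced]
        overlap = 1.0 - replaced / species_per_sample
        rs = sample_reads(community(f"ov{t:02d}", members), genomes, rng)
        steps.append((overlap, rs))
    return OverlapFixture(reference=reference, steps=steps,
                          pools={"lowgc": pool_f, "midgc": pool_p})


def experiment_abundance(
    n_pairs: int = 4,
    species: int = 10,
    seed=None,
    *,
    n_reads: int = 1500,
    genome_length: int = 300_000,
    decay: float = 0.5,
) -> AbundanceFixture:
    """Sample pairs sharing a species set but with permuted log abundances.

    All samples contain the same species; within a pair the abundance vector
    is identical, across pairs it is a different random permutation of the
    same logarithmic (rank-decay) profile.  The whole set is meant to be
    cross-assembled jointly; a correct analysis recovers the pairs as sisters
    in the cladogram.
    """
    if n_pairs < 2:
        raise InputError("need at least 2 pairs")
    rng = _rng(seed)
    lr = (genome_length, genome_length)
    pool = make_genome_pool(species, lr, (0.32, 0.42), rng, pool="lowgc")
    base = logarithmic_abundances(species, decay)

    readsets: list[SimulatedReadSet] = []
    pairs: list[tuple[str, str]] = []
    abundances: dict[str, np.ndarray] = {}
    genomes = {g.id: g for g in pool}
    seen: set[tuple[int, ...]] = set()
    for m in range(n_pairs):
        while True:
            perm = tuple(int(x) for x in rng.permutation(species))
            if perm not in seen:
                seen.add(perm)
                break
        abund = base[list(perm)]
        labels = (f"ab{2 * m + 1:02d}", f"ab{2 * m + 2:02d}")
        pairs.append(labels)
        for label in labels:
            spec = CommunitySpec(
                label=label,
                members=tuple((pool[s].id, float(abund[s])) for s in range(species)),
                n_reads=n_reads,
            )
            abundances[label] = abund.copy()
            readsets.append(sample_reads(spec, genomes, rng))
    return AbundanceFixture(readsets=readsets, pairs=pairs,
                            abundances=abundances, pool=pool)


def experiment_noise(
    noise_levels: Iterable[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    seed=None,
    *,
    n_pool_a: int = 3,
    n_pool_b: int = 6,
    species_per_sample: int = 5,
    n_reads: int = 500,
    genome_length: int = 150_000,
    divergence: float = 0.03,
    n_contaminants: int = 40,
    contaminant_length: int = 50_000,
) -> NoiseFixture:
    """Two phylum-like signal pools contaminated by a shared noise gradient.

    Three samples draw their (distinct) species from a high-GC pool and six
    from a low-GC pool; within each pool the species are homologous
    (``divergence`` from a common ancestor), so same-pool samples share
    sequence even though they share no species.  Every sample is additionally
    contaminated with a ``noise`` fraction of reads drawn uniformly from a
    shared mid-GC contaminant pool; one fixture per noise level.

    The contaminant pool's total sequence space (``n_contaminants *
    contaminant_length``) is deliberately large relative to the contaminant
    read mass, mirroring the original design (hundreds of megabase genomes
    sampled uniformly): noise reads then mostly remain singletons, so
    contamination acts by diluting the within-pool signal rather than by
    creating spuriously shared contigs.
    """
    levels = [float(x) for x in noise_levels]
    if any(not (0.0 <= x <= 1.0) for x in levels):
        raise InputError("noise levels must lie in [0, 1]")
    rng = _rng(seed)
    lr = (genome_length, genome_length)
    pool_a = make_genome_pool(n_pool_a * species_per_sample, lr, (0.58, 0.68),
                              rng, pool="highgc", divergence=divergence)
    pool_b = make_genome_pool(n_pool_b * species_per_sample, lr, (0.30, 0.40),
                              rng, pool="lowgc", divergence=divergence)
    pool_c = make_genome_pool(n_contaminants,
                              (contaminant_length, contaminant_length),
                              (0.44, 0.54), rng, pool="contam")
    genomes = {g.id: g for g in pool_a + pool_b + pool_c}
    contaminant_ids = tuple(g.id for g in pool_c)

    a_labels = [f"A{i + 1}" for i in range(n_pool_a)]
    b_labels = [f"B{i + 1}" for i in range(n_pool_b)]
    assignments: dict[str, list[Genome]] = {}
    for i, label in enumerate(a_labels):
        assignments[label] = pool_a[i * species_per_sample:(i + 1) * species_per_sample]
    for i, label in enumerate(b_labels):
        assignments[label] = pool_b[i * species_per_sample:(i + 1) * species_per_sample]

    readsets_by_level: dict[float, list[SimulatedReadSet]] = {}
    for level in levels:
        readsets: list[SimulatedReadSet] = []
        for label in a_labels + b_labels:
            members = assignments[label]
            spec = CommunitySpec(
                label=f"{label}n{int(round(100 * level)):03d}",
                members=tuple((g.id, 1.0 / len(members)) for g in members),
                n_reads=n_reads,
                noise_fraction=level,
                contaminants=contaminant_ids,
            )
            readsets.append(sample_reads(spec, genomes, rng))
        readsets_by_level[level] = readsets
    return NoiseFixture(
        levels=levels,
        readsets_by_level=readsets_by_level,
        pool_a_samples=a_labels,
        pool_b_samples=b_labels,
        pools={"highgc": pool_a, "lowgc": pool_b, "contam": pool_c},
    )
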