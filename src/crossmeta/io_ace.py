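"""Input/output for cross-assembly analyses.

Reads per-sample FASTA/FASTQ files (only the read identifiers are required,
so sequence-stripped files are legal), parses the ACE file describing the
cross-assembly, and writes the per-contig read-count table
(``output.contigs2reads.txt``).

The ACE dialect accepted here is the consed/454 one: an optional
``AS <ncontigs> <nreads>`` header, contigs introduced by
``CO <id> <len> <nreads> <nsegs> <orient>``, and member reads listed on
``AF <read_id> <C|U> <offset>`` lines and/or ``RD <read_id> ...`` blocks.
AF lines are authoritative for membership; RD blocks are used only when a
contig has no AF lines.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "InputError",
    "DuplicateReadIdError",
    "AceFormatError",
    "UnmatchedReadError",
    "ReadInventory",
    "ContigRecord",
    "ContigMembership",
    "read_sample_reads",
    "build_inventory",
    "parse_ace",
    "match_membership_to_inventory",
    "write_contigs2reads",
    "read_contigs2reads",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class DuplicateReadIdError(InputError):
    """A read identifier occurred more than once."""


class AceFormatError(InputError):
    """The ACE file violates the expected structure."""


class UnmatchedReadError(InputError):
    """ACE read identifiers that cannot be resolved to any sample."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ReadInventory:
    """Per-sample sets of read identifiers (and optionally sequences).

    Every read identifier must occur in exactly one sample: cross-assembly
    accounting attributes each assembled read to its sample of origin purely
    by identifier, so a collision between samples would corrupt every count.
    """

    samples: tuple[str, ...]
    reads_by_sample: Mapping[str, frozenset[str]]
    sequences_by_sample: Mapping[str, Mapping[str, str]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise InputError("sample labels must be unique")
        if any(not s for s in self.samples):
            raise InputError("sample labels must be non-empty")
        if self.sequences_by_sample is not None:
            for label, seqs in self.sequences_by_sample.items():
                if set(seqs) != set(self.reads_by_sample[label]):
                    raise InputError(
                        f"sequence identifiers for sample {label!r} do not "
                        "match its read identifiers"
                    )

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.reads_by_sample.values())

    def sample_of(self) -> dict[str, str]:
        """Map every read identifier to its sample label."""
        out: dict[str, str] = {}
        for label in self.samples:
            for rid in self.reads_by_sample[label]:
                out[rid] = label
        return out


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    read_ids: tuple[str, ...]


@dataclass
class ContigMembership:
    """For each contig, the member read identifiers parsed from the ACE file."""

    contigs: list[ContigRecord]
    declared_counts: dict[str, int] | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate contig identifiers: {dup[:5]}")
        for c in self.contigs:
            if not c.read_ids:
                raise InputError(f"contig {c.contig_id!r} has no member reads")

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    def member_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.contigs:
            out.update(c.read_ids)
        return out


# ---------------------------------------------------------------------------
# read files


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sample_reads(
    path: str | Path,
    sample_label: str,
    format_hint: str = "auto",
) -> tuple[str, set[str], dict[str, str] | None]:
    """Read one sample's read file and return its identifiers.

    Parameters
    ----------
    path:
        FASTA or FASTQ file, optionally gzip-compressed (by ``.gz`` suffix).
    sample_label:
        Label attached to this sample.
    format_hint:
        ``"fasta"``, ``"fastq"`` or ``"auto"`` (detect from the first
        non-blank character: ``>`` vs ``@``).

    Returns
    -------
    ``(sample_label, identifiers, sequences)`` where *identifiers* is the set
    of record identifiers (header token up to the first whitespace) and
    *sequences* maps identifier to sequence, or is ``None`` for
    sequence-stripped files (any record with an empty sequence marks the whole
    file as stripped).
    """
    if format_hint not in ("fasta", "fastq", "auto"):
        raise InputError(f"unknown format hint {format_hint!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"read file not found: {path}")

    with _open_text(path) as handle:
        if format_hint == "auto":
            pos = handle.tell()
            first = ""
            for line in handle:
                if line.strip():
                    first = line.strip()[0]
                    break
            handle.seek(pos)
            if first == ">":
                format_hint = "fasta"
            elif first == "@":
                format_hint = "fastq"
            else:
                raise InputError(
                    f"{path}: cannot detect format (first character {first!r}, "
                    "expected '>' or '@')"
                )
        try:
            if format_hint == "fasta":
                records = [(t, s) for t, s in SimpleFastaParser(handle)]
            else:
                records = [(t, s) for t, s, _q in FastqGeneralIterator(handle)]
        except ValueError as exc:
            raise InputError(f"{path}: unparseable record structure: {exc}") from exc

    ids: set[str] = set()
    seqs: dict[str, str] = {}
    stripped = False
    for title, seq in records:
        rid = title.split()[0] if title.split() else ""
        if not rid:
            raise InputError(f"{path}: record with empty identifier")
        if rid in ids:
            raise DuplicateReadIdError(
                f"{path}: duplicate read identifier {rid!r} within one file"
            )
        ids.add(rid)
        seq = seq.strip()
        if seq:
            seqs[rid] = seq
        else:
            stripped = True
    return sample_label, ids, (None if stripped or not seqs else seqs)


def build_inventory(
    per_sample_reads: Sequence[tuple[str, Iterable[str], Mapping[str, str] | None]],
) -> ReadInventory:
    """Combine per-sample read sets into a validated :class:`ReadInventory`.

    Raises on fewer than two samples (a comparison needs pairs) and on any
    read identifier shared between two samples.
    """
    if len(per_sample_reads) < 2:
        raise InputError("need >=2 metagenomes to compare")
    labels = [label for label, _, _ in per_sample_reads]
    seen: dict[str, str] = {}
    reads_by_sample: dict[str, frozenset[str]] = {}
    seqs_by_sample: dict[str, dict[str, str]] = {}
    for label, ids, seqs in per_sample_reads:
        idset = frozenset(ids)
        for rid in idset:
            if rid in seen:
                raise DuplicateReadIdError(
                    f"read identifier {rid!r} occurs in both sample "
                    f"{seen[rid]!r} and sample {label!r}; identifiers must be "
                    "unique across all datasets"
                )
            seen[rid] = label
        reads_by_sample[label] = idset
        if seqs is not None:
            seqs_by_sample[label] = dict(seqs)
    return ReadInventory(
        samples=tuple(labels),
        reads_by_sample=reads_by_sample,
        sequences_by_sample=seqs_by_sample or None,
    )


# ---------------------------------------------------------------------------
# ACE parsing


def parse_ace(path: str | Path) -> ContigMembership:
    """Parse a consed-dialect ACE file into contig membership.

    AF lines are authoritative for membership; RD blocks are a fallback when a
    contig has no AF lines.  A read listed more than once within one contig is
    kept once (re-aligned duplicates are assembler artifacts).  A disagreement
    between the CO line's declared read count and the member lines found is
    recorded as a warning, and membership is taken from the actual lines.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"ACE file not found: {path}")

    contigs: list[ContigRecord] = []
    declared: dict[str, int] = {}
    warns: list[str] = []

    cur_id: str | None = None
    cur_af: list[str] = []
    cur_rd: list[str] = []

    def _close_contig(offset: int) -> None:
        nonlocal cur_id, cur_af, cur_rd
        if cur_id is None:
            return
        members = cur_af if cur_af else cur_rd
        # count each read once per contig, preserving first-seen order
        uniq = list(dict.fromkeys(members))
        if not uniq:
            raise AceFormatError(
                f"{path}: contig {cur_id!r} declares no member reads "
                f"(contig block ends near byte offset {offset})"
            )
        if cur_id in declared and declared[cur_id] != len(uniq):
            msg = (
                f"contig {cur_id!r}: CO line declares {declared[cur_id]} reads "
                f"but {len(uniq)} member lines found; using member lines"
            )
            warns.append(msg)
            warnings.warn(msg, stacklevel=3)
        contigs.append(ContigRecord(cur_id, tuple(uniq)))
        cur_id, cur_af, cur_rd = None, [], []

    offset = 0
    with open(path, "rb") as fh:
        for raw in fh:
            line_offset = offset
            offset += len(raw)
            line = raw.decode("utf-8", errors="replace").rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split()
            tag = fields[0]
            if tag == "AS":
                continue
            if tag == "CO":
                _close_contig(line_offset)
                if len(fields) < 5:
                    raise AceFormatError(
                        f"{path}: truncated CO line at byte offset {line_offset}: "
                        f"{line!r}"
                    )
                cur_id = fields[1]
                try:
                    declared[cur_id] = int(fields[3])
                except ValueError as exc:
                    raise AceFormatError(
                        f"{path}: non-numeric read count on CO line at byte "
                        f"offset {line_offset}: {line!r}"
                    ) from exc
            elif tag == "AF":
                if cur_id is None:
                    raise AceFormatError(
                        f"{path}: AF line before any CO line at byte offset "
                        f"{line_offset}"
                    )
                if len(fields) < 2:
                    raise AceFormatError(
                        f"{path}: truncated AF line at byte offset {line_offset}"
                    )
                cur_af.append(fields[1])
            elif tag == "RD":
                if cur_id is None:
                    # RD outside a contig block: ignore (some writers append
                    # orphan blocks); membership comes from CO blocks only.
                    continue
                if len(fields) < 2:
                    raise AceFormatError(
                        f"{path}: truncated RD line at byte offset {line_offset}"
                    )
                cur_rd.append(fields[1])
            # all other tags (BQ, BS, QA, DS, WA, CT, sequence data) are
            # irrelevant to membership and skipped
    _close_contig(offset)

    if not contigs:
        raise AceFormatError(f"{path}: no contigs found")
    return ContigMembership(contigs=contigs, declared_counts=declared or None,
                            warnings=warns)


_SUFFIX_RE = re.compile(r"\.\d+$")


def match_membership_to_inventory(
    membership: ContigMembership, inventory: ReadInventory
) -> ContigMembership:
    """Canonicalize ACE read identifiers against the inventory.

    Exact string match first; if that fails, retry after stripping a single
    trailing ``.<digits>`` suffix (454/consed dialects append fragment
    suffixes).  Identifiers that still match nothing are a hard error listing
    up to 20 offenders: a silent mismatch would corrupt every downstream count.
    """
    known: set[str] = set()
    for label in inventory.samples:
        known.update(inventory.reads_by_sample[label])

    unmatched: list[str] = []
    new_contigs: list[ContigRecord] = []
    for contig in membership.contigs:
        resolved: list[str] = []
        for rid in contig.read_ids:
            if rid in known:
                resolved.append(rid)
                continue
            stripped = _SUFFIX_RE.sub("", rid)
            if stripped != rid and stripped in known:
                resolved.append(stripped)
            else:
                unmatched.append(rid)
        new_contigs.append(
            ContigRecord(contig.contig_id, tuple(dict.fromkeys(resolved)))
        )
    if unmatched:
        shown = unmatched[:20]
        raise UnmatchedReadError(
            f"{len(unmatched)} ACE read identifier(s) match no sample; "
            f"first offenders: {shown}"
        )
    return ContigMembership(
        contigs=new_contigs,
        declared_counts=membership.declared_counts,
        warnings=list(membership.warnings),
    )


# ---------------------------------------------------------------------------
# contigs2reads table

_SINGLETON_HEADER = "# singletons"


def write_contigs2reads(profile, path: str | Path) -> Path:
    """Write the per-contig read-count table plus singleton identifiers.

    Layout: a header row (``contig`` then one column per sample), one
    tab-separated row per contig with the read counts from each sample, then a
    ``# singletons`` section with one row per sample listing its unassembled
    read identifiers (space-separated).
    """
    path = Path(path)
    lines = ["contig\t" + "\t".join(profile.samples)]
    for k, cid in enumerate(profile.contig_ids):
        row = profile.counts[k]
        lines.append(cid + "\t" + "\t".join(str(int(x)) for x in row))
    lines.append(_SINGLETON_HEADER)
    for label in profile.samples:
        ids = profile.singletons.get(label, [])
        lines.append(label + "\t" + " ".join(ids))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_contigs2reads(
    path: str | Path,
) -> tuple[list[str], dict[str, list[int]], dict[str, list[str]]]:
    """Parse a contigs2reads table back into counts and singleton lists."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    if header[0] != "contig":
        raise InputError(f"{path}: not a contigs2reads table")
    samples = header[1:]
    counts: dict[str, list[int]] = {}
    singletons: dict[str, list[str]] = {}
    in_singletons = False
    for line in lines[1:]:
        if line == _SINGLETON_HEADER:
            in_singletons = True
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if in_singletons:
            singletons[fields[0]] = fields[1].split() if len(fields) > 1 else []
        else:
            counts[fields[0]] = [int(x) for x in fields[1:]]
    return samples, counts, singletons
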