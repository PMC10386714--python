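"""Small-RNA read preprocessing, placement on tRNA coordinates, counting.

Preprocessing follows the small-RNA convention of the NEXTFLEX-style
libraries: 3' adapter removal, a minimum-length filter, then trimming a fixed
number of bases off both ends (the kit's randomized adapter bases).

Alignment is an exhaustive best-stratum Hamming scan against the compact
mature-tRNA reference: for each distinct read sequence, all loci at the lowest
mismatch count (up to ``max_mismatches``) are reported, emulating a
``bowtie -v 2 --best --strata``-style mapping with a ``-m``-style multi-hit
cap.  Fragment identity is the trimmed read sequence; multi-mapped loci travel
alongside as annotation, so a read is never counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .reference import RNA_ALPHABET, TRNAReference

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

__all__ = [
    "DEFAULT_ADAPTER",
    "Locus",
    "AlignedFragment",
    "FragmentCountTable",
    "PreprocessResult",
    "preprocess_reads",
    "read_fastq",
    "write_fastq",
    "align_fragments",
    "write_sam",
    "ingest_alignments",
    "count_fragments",
]

Locus = tuple[str, int, int]  # (species id, start, end) 0-based half-open


@dataclass
class AlignedFragment:
    """One distinct fragment sequence with its reference loci.

    ``n_reads`` carries the number of reads with this sequence in the sample
    the fragment came from (1 for externally ingested single reads).
    """

    fragment_seq: str
    loci: tuple[Locus, ...]
    n_reads: int = 1

    @property
    def n_hits(self) -> int:
        return len(self.loci)


@dataclass
class FragmentCountTable:
    """Unique-fragment raw counts (rows: sequences, columns: samples) + loci."""

    counts: pd.DataFrame
    loci: dict[str, tuple[Locus, ...]]

    def __post_init__(self) -> None:
        for seq in self.counts.index:
            if not self.loci.get(seq):
                raise ValueError(f"fragment {seq!r} has no locus annotation")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Counts plus a semicolon-separated locus column, for TSV export."""
        out = self.counts.copy()
        out.insert(
            0,
            "loci",
            [
                ";".join(f"{s}:{a}-{b}" for s, a, b in self.loci[seq])
                for seq in out.index
            ],
        )
        return out


@dataclass
class PreprocessResult:
    """Trimmed reads plus per-rule tallies."""

    reads: list[str]
    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_too_short: int = 0
    n_bad_chars: int = 0


def _find_adapter(seq: str, adapter: str) -> Optional[int]:
    """Leftmost 3'-adapter start.  Exact match for overlaps < 10 nt, one
    mismatch allowed for overlaps >= 10 nt."""
    n, m = len(seq), len(adapter)
    for i in range(n):
        overlap = min(m, n - i)
        budget = 1 if overlap >= 10 else 0
        mism = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            return i
    return None


def preprocess_reads(
    reads: Iterable[str],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 23,
    end_trim: int = 4,
) -> PreprocessResult:
    """Adapter-trim, length-filter and end-trim raw small-RNA reads.

    The 3' adapter is removed at its first occurrence; reads shorter than
    ``min_len`` after adapter removal are dropped; survivors then lose
    ``end_trim`` nt from each end.  Reads with non-nucleotide characters are
    skipped and tallied.  Output reads are RNA (U) strings; no output read is
    shorter than ``min_len - 2 * end_trim``.
    """
    adapter = adapter.upper().replace("U", "T")
    result = PreprocessResult(reads=[])
    for raw in reads:
        result.n_input += 1
        seq = raw.upper().replace("U", "T")
        if set(seq) - set("ACGT"):
            result.n_bad_chars += 1
            continue
        hit = _find_adapter(seq, adapter)
        if hit is not None:
            seq = seq[:hit]
            result.n_adapter_trimmed += 1
        if len(seq) < min_len:
            result.n_too_short += 1
            continue
        trimmed = seq[end_trim : len(seq) - end_trim] if end_trim else seq
        if not trimmed:
            result.n_too_short += 1
            continue
        result.reads.append(trimmed.replace("T", "U"))
    if result.n_bad_chars:
        warnings.warn(f"skipped {result.n_bad_chars} reads with non-nucleotide characters")
    return result


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from FASTQ (as DNA/RNA strings)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    """Write sequences as FASTQ with dummy maximum qualities."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_fragments(
    reads: Iterable[str],
    ref: TRNAReference,
    max_mismatches: int = 2,
    max_hits: int = 500,
) -> list[AlignedFragment]:
    """Best-stratum exhaustive Hamming alignment of reads to the reference.

    For each distinct read sequence, every locus achieving the minimum
    mismatch count (when that minimum is <= ``max_mismatches``) is reported.
    Reads with more than ``max_hits`` best-stratum loci are discarded, as are
    unaligned reads; both are tallied in a warning.  Sense strand only; no
    indels (Hamming distance).
    """
    if len(ref) == 0:
        raise ValueError("empty reference")
    encoded = {sp.id: _encode(sp.sequence) for sp in ref}
    seq_counts: dict[str, int] = {}
    for r in reads:
        seq_counts[r] = seq_counts.get(r, 0) + 1

    out: list[AlignedFragment] = []
    n_unaligned = 0
    n_overmapped = 0
    for seq, n in seq_counts.items():
        q = _encode(seq)
        L = len(q)
        best = max_mismatches + 1
        loci: list[tuple[int, Locus]] = []
        for sp in ref:
            s = encoded[sp.id]
            if L > len(s):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(s, L)
            mism = (windows != q).sum(axis=1)
            for start in np.flatnonzero(mism <= max_mismatches):
                loci.append((int(mism[start]), (sp.id, int(start), int(start) + L)))
        if loci:
            best = min(m for m, _ in loci)
        if best > max_mismatches:
            n_unaligned += n
            continue
        best_loci = tuple(loc for m, loc in loci if m == best)
        if len(best_loci) > max_hits:
            n_overmapped += n
            continue
        out.append(AlignedFragment(fragment_seq=seq, loci=best_loci, n_reads=n))
    if n_unaligned or n_overmapped:
        warnings.warn(
            f"dropped {n_unaligned} unaligned reads and {n_overmapped} reads "
            f"with > {max_hits} loci"
        )
    return out


def write_sam(
    fragments: Sequence[AlignedFragment], ref: TRNAReference, path: str | Path
) -> None:
    """Write alignments as SAM: one primary plus secondary records per read.

    Each read of a fragment is emitted once per locus (first locus primary,
    flag 0; others secondary, flag 256) so external tools see the same
    multi-mapping structure ``align_fragments`` produced.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": sp.id, "LN": sp.length} for sp in ref],
        }
    )
    tid = {sp.id: i for i, sp in enumerate(ref)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        read_no = 0
        for frag in fragments:
            for _ in range(frag.n_reads):
                name = f"frag{read_no}"
                read_no += 1
                for j, (sid, start, end) in enumerate(frag.loci):
                    a = pysam.AlignedSegment(header)
                    a.query_name = name
                    a.flag = 0 if j == 0 else 256
                    a.reference_id = tid[sid]
                    a.reference_start = start
                    a.mapping_quality = 255
                    a.cigarstring = f"{end - start}M"
                    if j == 0:
                        a.query_sequence = frag.fragment_seq.replace("U", "T")
                    fh.write(a)


def _ingest_sam(path: str | Path, ref: TRNAReference) -> list[AlignedFragment]:
    by_read: dict[str, dict] = {}
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            sid = rec.reference_name
            if sid not in ref:
                unknown.add(sid)
                continue
            entry = by_read.setdefault(rec.query_name, {"seq": None, "loci": []})
            entry["loci"].append((sid, rec.reference_start, rec.reference_end))
            if rec.query_sequence and not rec.is_secondary:
                entry["seq"] = rec.query_sequence.upper().replace("T", "U")
    if unknown:
        raise ValueError(f"unknown reference names: {sorted(unknown)}")
    fragments: dict[str, AlignedFragment] = {}
    for name, entry in by_read.items():
        seq = entry["seq"]
        if seq is None:  # reconstruct from the first locus
            sid, start, end = entry["loci"][0]
            seq = ref[sid].sequence[start:end]
        loci = tuple(sorted(set(entry["loci"])))
        if seq in fragments:
            prev = fragments[seq]
            fragments[seq] = AlignedFragment(
                fragment_seq=seq,
                loci=tuple(sorted(set(prev.loci) | set(loci))),
                n_reads=prev.n_reads + 1,
            )
        else:
            fragments[seq] = AlignedFragment(fragment_seq=seq, loci=loci, n_reads=1)
    return list(fragments.values())


def _ingest_bed(path: str | Path, ref: TRNAReference) -> list[AlignedFragment]:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
    )
    unknown = sorted(set(bed["chrom"]) - set(ref.ids))
    if unknown:
        raise ValueError(f"unknown reference names: {unknown}")
    fragments: dict[str, AlignedFragment] = {}
    for name, grp in bed.groupby("name", sort=False):
        loci = tuple(
            sorted(
                {
                    (row.chrom, int(row.start), int(row.end))
                    for row in grp.itertuples()
                }
            )
        )
        sid, start, end = loci[0]
        seq = ref[sid].sequence[start:end]
        if seq in fragments:
            prev = fragments[seq]
            fragments[seq] = AlignedFragment(
                fragment_seq=seq,
                loci=tuple(sorted(set(prev.loci) | set(loci))),
                n_reads=prev.n_reads + 1,
            )
        else:
            fragments[seq] = AlignedFragment(fragment_seq=seq, loci=loci, n_reads=1)
    return list(fragments.values())


def ingest_alignments(path: str | Path, ref: TRNAReference) -> list[AlignedFragment]:
    """Ingest external aligner output (SAM/BAM or 6-column BED) on the reference.

    Secondary alignments of one read merge into a single fragment's locus set;
    coordinates become 0-based half-open.  Unknown reference names are a hard
    error listing the offenders.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _ingest_bed(path, ref)
    return _ingest_sam(path, ref)


def count_fragments(
    alignments: Mapping[str, Sequence[AlignedFragment]],
) -> FragmentCountTable:
    """Unique-fragment count table over samples.

    One row per distinct fragment sequence; each read contributes 1 to its
    sequence's count in its sample regardless of how many loci it has.  Rows
    record the union of loci seen across samples.
    """
    samples = list(alignments)
    counts: dict[str, dict[str, int]] = {}
    loci: dict[str, set[Locus]] = {}
    for sample, frags in alignments.items():
        for frag in frags:
            row = counts.setdefault(frag.fragment_seq, {})
            row[sample] = row.get(sample, 0) + frag.n_reads
            loci.setdefault(frag.fragment_seq, set()).update(frag.loci)
    index = sorted(counts)
    table = pd.DataFrame(
        [[counts[seq].get(s, 0) for s in samples] for seq in index],
        index=index,
        columns=samples,
        dtype=np.int64,
    )
    return FragmentCountTable(
        counts=table, loci={seq: tuple(sorted(loci[seq])) for seq in index}
    )
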