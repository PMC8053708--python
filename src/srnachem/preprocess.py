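"""Read preprocessing: 3'-adapter trimming, quality/length gates, UMI
extraction, PCR deduplication and collapsing to unique insert sequences.

The library layout puts the 3' adapter (and both UMIs) inside the read:
``UMI5 + insert + UMI3 + adapter3``.  Only the 3' adapter is searched for;
reads are sequenced from the 5'-adapter side so the 5' adapter never appears
in-read at small-RNA insert lengths.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

REJECT_LOW_QUALITY = "low_quality"
REJECT_TOO_SHORT = "too_short"
REJECT_TOO_LONG = "too_long"


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct insert sequence with its molecule and read counts.

    ``unique_count`` counts distinct (insert, UMI-pair) molecules;
    ``raw_count`` counts all accepted reads with this insert.
    """

    sequence: str
    unique_count: int
    raw_count: int


@dataclass
class PreprocessConfig:
    adapter3: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACA"
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    q_min: float = 30.0
    len_min: int = 15
    len_max: int = 40
    umi5_len: int = 6
    umi3_len: int = 6

    def __post_init__(self) -> None:
        if not self.adapter3:
            raise ValueError("adapter3 must be nonempty")
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length strings, early exit > limit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def find_adapter(
    seq: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> Optional[int]:
    """Locate the leftmost 3'-adapter occurrence; return the trim index.

    An occurrence is the full adapter, or an adapter prefix of length
    >= ``min_overlap`` reaching the read end, with at most
    ``max_mismatch_rate`` mismatches over the overlap.  Candidate positions
    are seeded by exact matches of the adapter's first two 8-mers
    (pigeonhole: any occurrence with <= 1 mismatch in its first 16 nt is
    found); short suffix overlaps are checked directly.
    """
    n, m = len(seq), len(adapter)
    candidates: set[int] = set()
    seed_len = 8
    if m >= 2 * seed_len:
        seeds = [(adapter[:seed_len], 0), (adapter[seed_len : 2 * seed_len], seed_len)]
    else:
        seeds = [(adapter[: min(m, seed_len)], 0)]
    for needle, off in seeds:
        i = seq.find(needle)
        while i >= 0:
            if i - off >= 0:
                candidates.add(i - off)
            i = seq.find(needle, i + 1)
    # Short suffix overlaps (adapter prefix running off the read end) whose
    # seed would not fit.
    for k in range(min_overlap, min(m, 2 * seed_len)):
        p = n - k
        if p >= 0:
            candidates.add(p)
    for p in sorted(candidates):
        overlap = min(m, n - p)
        if overlap < min_overlap or (overlap < m and p + overlap < n):
            continue
        limit = int(max_mismatch_rate * overlap)
        if _mismatches(seq[p : p + overlap], adapter[:overlap], limit) <= limit:
            return p
    return None


def mean_phred(quality: str) -> float:
    if not quality:
        return 0.0
    return sum(ord(c) - 33 for c in quality) / len(quality)


def trim_and_filter(
    read: RawRead, cfg: PreprocessConfig
) -> tuple[Optional[str], Optional[str]]:
    """Trim the 3' adapter and apply quality and length gates.

    Returns (trimmed sequence, None) on success or (None, reason).  Reads
    with no adapter hit are kept untrimmed and left to the length gate, so a
    short genuine insert whose adapter carries errors can still be salvaged
    by the mismatch-tolerant search.  The length gate bounds are on the
    trimmed sequence handed to UMI extraction (the caller widens them by the
    UMI lengths when gating inserts).
    """
    pos = find_adapter(read.sequence, cfg.adapter3, cfg.min_overlap, cfg.max_mismatch_rate)
    if pos is None:
        trimmed, qual = read.sequence, read.quality
    else:
        trimmed, qual = read.sequence[:pos], read.quality[:pos]
    if not trimmed or mean_phred(qual) < cfg.q_min:
        return None, REJECT_LOW_QUALITY if trimmed else REJECT_TOO_SHORT
    if len(trimmed) < cfg.len_min:
        return None, REJECT_TOO_SHORT
    if len(trimmed) > cfg.len_max:
        return None, REJECT_TOO_LONG
    return trimmed, None


def extract_umi(sequence: str, umi5_len: int, umi3_len: int) -> tuple[str, str]:
    """Split a trimmed sequence into (umi_pair, insert).

    The UMI pair is the concatenation of the first ``umi5_len`` and last
    ``umi3_len`` bases; the insert is the interior.
    """
    if len(sequence) <= umi5_len + umi3_len:
        raise ValueError("sequence too short for the configured UMI lengths")
    umi = sequence[:umi5_len] + (sequence[-umi3_len:] if umi3_len else "")
    insert = sequence[umi5_len : len(sequence) - umi3_len]
    return umi, insert


def dedup_and_collapse(pairs: Iterable[tuple[str, str]]) -> list[CollapsedRead]:
    """Collapse (insert, umi) pairs into unique reads.

    ``unique_count`` is the number of distinct (insert, UMI) molecules and
    ``raw_count`` the total read occurrences of the insert.  Output is sorted
    by unique_count descending, ties by sequence.
    """
    raw: Counter[str] = Counter()
    uniq: set[tuple[str, str]] = set()
    for insert, umi in pairs:
        raw[insert] += 1
        uniq.add((insert, umi))
    uniq_counts: Counter[str] = Counter(insert for insert, _ in uniq)
    out = [
        CollapsedRead(seq, uniq_counts[seq], raw[seq]) for seq in raw
    ]
    out.sort(key=lambda r: (-r.unique_count, r.sequence))
    return out


@dataclass
class PreprocessResult:
    collapsed: list[CollapsedRead]
    n_input: int
    n_accepted: int
    rejections: dict[str, int]


def preprocess_reads(
    reads: Iterable[tuple[str, str, str]], cfg: PreprocessConfig
) -> PreprocessResult:
    """Full preprocessing of (id, sequence, quality) tuples.

    The trim-stage length gate is widened by the UMI lengths so that the gate
    effectively applies to the insert.
    """
    umi_total = cfg.umi5_len + cfg.umi3_len
    trim_cfg = PreprocessConfig(
        adapter3=cfg.adapter3,
        min_overlap=cfg.min_overlap,
        max_mismatch_rate=cfg.max_mismatch_rate,
        q_min=cfg.q_min,
        len_min=cfg.len_min + umi_total,
        len_max=cfg.len_max + umi_total,
        umi5_len=cfg.umi5_len,
        umi3_len=cfg.umi3_len,
    )
    rejections: Counter[str] = Counter()
    pairs = []
    n_input = 0
    for rid, seq, qual in reads:
        n_input += 1
        trimmed, reason = trim_and_filter(RawRead(rid, seq, qual), trim_cfg)
        if trimmed is None:
            rejections[reason] += 1
            continue
        umi, insert = extract_umi(trimmed, cfg.umi5_len, cfg.umi3_len)
        pairs.append((insert, umi))
    collapsed = dedup_and_collapse(pairs)
    return PreprocessResult(
        collapsed=collapsed,
        n_input=n_input,
        n_accepted=len(pairs),
        rejections=dict(rejections),
    )


def read_fastq(path) -> Iterable[tuple[str, str, str]]:
    """Stream (id, sequence, quality) tuples from a FASTQ(.gz) file."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual
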