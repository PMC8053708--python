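"""Reference construction and the ordered small-RNA annotation cascade.

Each collapsed read is assigned to a single sRNA class by trying reference
stages in a fixed priority order (miRNA first, genome last).  Alignment is
sense-strand only, ungapped, and allows at most one mismatch; miRNA and
piRNA stages additionally gate on read length.  tRNA-derived fragments are
sub-typed by where they fall relative to the anticodon loop of the mature
tRNA (or the flanks of the precursor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Reference classes, in default cascade priority order.  The "ncRNA" stage of
# the original protocol is subdivided into its constituent types.
CLASS_MIRNA = "miRNA"
CLASS_RRNA = "rRNA"
CLASS_CYTO_TRNA = "cyto_tRNA"
CLASS_PRE_TRNA = "pre_tRNA"
CLASS_PIRNA = "piRNA_cluster"
CLASS_MITO_TRNA = "mito_tRNA"
CLASS_LNCRNA = "lncRNA"
CLASS_SNRNA = "snRNA"
CLASS_SNORNA = "snoRNA"
CLASS_MRNA = "mRNA"
CLASS_OTHER_NCRNA = "other_ncRNA"
CLASS_GENOME = "genome"

DEFAULT_CASCADE_ORDER = (
    CLASS_MIRNA,
    CLASS_RRNA,
    CLASS_CYTO_TRNA,
    CLASS_PRE_TRNA,
    CLASS_PIRNA,
    CLASS_MITO_TRNA,
    CLASS_LNCRNA,
    CLASS_SNRNA,
    CLASS_SNORNA,
    CLASS_MRNA,
    CLASS_OTHER_NCRNA,
    CLASS_GENOME,
)

TRNA_CLASSES = (CLASS_CYTO_TRNA, CLASS_MITO_TRNA)

# tRF types
TSRNA_TRF5 = "tRF5"
TSRNA_HALF5 = "half5"
TSRNA_HALF3 = "half3"
TSRNA_TRF3 = "tRF3"
TSRNA_INTERNAL = "internal"
TSRNA_LEADER5 = "leader5"
TSRNA_TRAILER3 = "trailer3"

# Stage gates: length window and mismatch allowance.
MIRNA_LEN_RANGE = (16, 28)
PIRNA_LEN_RANGE = (24, 32)


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence with class label and tRNA metadata.

    ``anticodon_span`` is 1-based inclusive on ``sequence`` and must be set
    exactly for tRNA classes.  ``mature_span`` (0-based half-open) records the
    mature interval on precursor references.
    """

    ref_id: str
    ref_class: str
    sequence: str
    anticodon_span: Optional[tuple[int, int]] = None
    is_histidine: bool = False
    isodecoder: Optional[str] = None
    mature_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.ref_class in TRNA_CLASSES:
            if self.anticodon_span is None:
                raise ValueError(f"{self.ref_id}: tRNA reference lacks anticodon_span")
            lo, hi = self.anticodon_span
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(f"{self.ref_id}: anticodon_span outside sequence")


@dataclass(frozen=True)
class AnnotationHit:
    """A read-to-reference assignment from the cascade.

    ``start`` is 0-based on the reference; mismatch position (reference
    coordinate, 0-based) and the substituted read base are recorded for
    single-mismatch hits so that pileups can be built downstream.
    """

    sequence: str
    ref_class: str
    ref_id: str
    start: int
    mismatches: int
    mismatch_pos: Optional[int] = None
    mismatch_base: Optional[str] = None
    tsrna_type: Optional[str] = None


def build_mature_trna_refs(raw: Iterable[ReferenceRecord]) -> list[ReferenceRecord]:
    """Append the post-transcriptional CCA to every tRNA and the extra G to
    histidine tRNAs (shifting the anticodon span by one).

    CCA is appended unconditionally, even if the input already ends in CCA:
    genomic tRNA references conventionally lack the CCA tail, and the rare
    genomic CCA ending simply yields a slightly longer reference.
    """
    out = []
    for rec in raw:
        seq = rec.sequence + "CCA"
        span = rec.anticodon_span
        if rec.is_histidine:
            seq = "G" + seq
            if span is not None:
                span = (span[0] + 1, span[1] + 1)
        out.append(replace(rec, sequence=seq, anticodon_span=span))
    return out


def build_precursor_refs(
    contigs: dict[str, str],
    loci: Sequence[tuple[str, str, int, int]],
    flank: int = 100,
) -> list[ReferenceRecord]:
    """Extract precursor references around tRNA loci.

    ``loci`` holds (ref_id, contig, start, end) with 0-based half-open genomic
    coordinates of the mature tRNA.  Each precursor spans ``flank`` nt of
    genomic context on both sides, clipped at contig edges; the mature
    interval within the precursor is recorded in ``mature_span``.
    """
    out = []
    for ref_id, contig, start, end in loci:
        if contig not in contigs:
            raise KeyError(f"locus {ref_id}: contig {contig!r} not provided")
        seq = contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"locus {ref_id}: coordinates outside contig")
        lo = max(0, start - flank)
        hi = min(len(seq), end + flank)
        out.append(
            ReferenceRecord(
                ref_id=ref_id,
                ref_class=CLASS_PRE_TRNA,
                sequence=seq[lo:hi],
                mature_span=(start - lo, end - lo),
            )
        )
    return out


def _hamming_le1(a: str, b: str) -> Optional[int]:
    """Return the single mismatch offset if a and b differ at exactly <=1
    position (None-as-offset -1 means identical); None if >1 mismatches."""
    mm = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if mm >= 0:
                return None
            mm = i
    return mm


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i >= 0:
        yield i
        i = haystack.find(needle, i + 1)


def align_read(
    seq: str,
    references: Sequence[ReferenceRecord],
    max_mismatches: int = 1,
) -> Optional[AnnotationHit]:
    """Align a read against references, sense strand only, ungapped.

    Exact hits are preferred over single-mismatch hits; ties are broken by
    reference input order, then leftmost start on the reference.  Exact
    matching uses the host substring search; single-mismatch candidates are
    found by the pigeonhole split (one half of the read must match exactly).
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    # Pass 1: exact.
    for ref in references:
        pos = ref.sequence.find(seq)
        if pos >= 0:
            return AnnotationHit(seq, ref.ref_class, ref.ref_id, pos, 0)
    if max_mismatches == 0:
        return None
    # Pass 2: one mismatch via pigeonhole halves.
    half = len(seq) // 2
    left, right = seq[:half], seq[half:]
    for ref in references:
        best: Optional[tuple[int, int]] = None  # (start, mismatch offset)
        candidates = set()
        if left:
            for p in _find_all(ref.sequence, left):
                candidates.add(p)
        for p in _find_all(ref.sequence, right):
            if p - half >= 0:
                candidates.add(p - half)
        for start in sorted(candidates):
            if start + len(seq) > len(ref.sequence):
                continue
            window = ref.sequence[start : start + len(seq)]
            mm = _hamming_le1(seq, window)
            if mm is not None and mm >= 0:
                best = (start, mm)
                break
        if best is not None:
            start, mm = best
            return AnnotationHit(
                seq,
                ref.ref_class,
                ref.ref_id,
                start,
                1,
                mismatch_pos=start + mm,
                mismatch_base=seq[mm],
            )
    return None


@dataclass
class TsrnaTypingConfig:
    """Boundary rules for tRNA-fragment typing on the mature reference.

    The anticodon loop is the anticodon triplet widened by ``loop_pad`` nt on
    each side; a fragment 3' end within the last ``cca_tol`` nt counts as
    reaching the reference end (the CCA tail); a fragment start within the
    first ``start_tol`` + 1 positions counts as the 5' end (tolerating the
    histidine G).
    """

    loop_pad: int = 2
    cca_tol: int = 3
    start_tol: int = 1


def classify_tsrna(
    hit: AnnotationHit,
    ref: ReferenceRecord,
    config: TsrnaTypingConfig | None = None,
) -> str:
    """Type a tRNA-derived fragment.

    On mature references: fragments anchored at the 5' end are halves if they
    terminate inside the anticodon loop and tRF5s if they stop short of it;
    fragments anchored at the CCA end are halves if they begin inside the
    loop and tRF3s if they begin after it; everything else is internal.  On
    precursor references, fragments overlapping the upstream flank are 5'
    leaders and those overlapping the downstream flank are 3' trailers.
    """
    cfg = config or TsrnaTypingConfig()
    s = hit.start + 1  # 1-based
    e = hit.start + len(hit.sequence)
    if ref.ref_class == CLASS_PRE_TRNA:
        if ref.mature_span is None:
            raise ValueError(f"{ref.ref_id}: precursor lacks mature_span")
        m_lo, m_hi = ref.mature_span  # 0-based half-open
        if hit.start < m_lo:
            return TSRNA_LEADER5
        if e > m_hi:
            return TSRNA_TRAILER3
        return TSRNA_INTERNAL
    if ref.anticodon_span is None:
        raise ValueError(f"{ref.ref_id}: missing anticodon_span")
    loop_lo = ref.anticodon_span[0] - cfg.loop_pad
    loop_hi = ref.anticodon_span[1] + cfg.loop_pad
    at_5p = s <= 1 + cfg.start_tol
    at_3p = e >= len(ref.sequence) - cfg.cca_tol + 1
    if at_5p:
        if loop_lo <= e <= loop_hi:
            return TSRNA_HALF5
        if e < loop_lo:
            return TSRNA_TRF5
    if at_3p:
        if loop_lo <= s <= loop_hi:
            return TSRNA_HALF3
        if s > loop_hi:
            return TSRNA_TRF3
    return TSRNA_INTERNAL


@dataclass
class CascadeConfig:
    order: tuple[str, ...] = DEFAULT_CASCADE_ORDER
    mirna_len_range: tuple[int, int] = MIRNA_LEN_RANGE
    pirna_len_range: tuple[int, int] = PIRNA_LEN_RANGE
    typing: TsrnaTypingConfig = field(default_factory=TsrnaTypingConfig)


class ReferenceDB:
    """References grouped into cascade stages."""

    def __init__(self, records: Sequence[ReferenceRecord], config: CascadeConfig | None = None):
        self.config = config or CascadeConfig()
        known = set(self.config.order)
        for rec in records:
            if rec.ref_class not in known:
                raise ValueError(f"unknown reference class {rec.ref_class!r}")
        self.records = list(records)
        self._by_class: dict[str, list[ReferenceRecord]] = {c: [] for c in self.config.order}
        for rec in records:
            self._by_class[rec.ref_class].append(rec)
        self._by_id = {rec.ref_id: rec for rec in records}

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    def stage(self, ref_class: str) -> list[ReferenceRecord]:
        return self._by_class[ref_class]

    def stages(self) -> Iterable[tuple[str, list[ReferenceRecord]]]:
        for c in self.config.order:
            if self._by_class[c]:
                yield c, self._by_class[c]


def annotate_read(seq: str, db: ReferenceDB) -> Optional[AnnotationHit]:
    """Run one read through the cascade; first stage with a hit wins."""
    cfg = db.config
    for ref_class, refs in db.stages():
        if ref_class == CLASS_MIRNA:
            lo, hi = cfg.mirna_len_range
            if not (lo <= len(seq) <= hi):
                continue
            hit = align_read(seq, refs, max_mismatches=0)
        elif ref_class == CLASS_PIRNA:
            lo, hi = cfg.pirna_len_range
            if not (lo <= len(seq) <= hi):
                continue
            hit = align_read(seq, refs, max_mismatches=1)
        else:
            hit = align_read(seq, refs, max_mismatches=1)
        if hit is not None:
            if ref_class in TRNA_CLASSES or ref_class == CLASS_PRE_TRNA:
                hit = replace(hit, tsrna_type=classify_tsrna(hit, db[hit.ref_id], cfg.typing))
            return hit
    return None


def annotate_cascade(
    sequences: Iterable[str],
    db: ReferenceDB,
) -> tuple[list[AnnotationHit], list[str]]:
    """Annotate collapsed read sequences; returns (hits, unannotated).

    Every input sequence lands in exactly one of the two outputs.
    """
    hits: list[AnnotationHit] = []
    unannotated: list[str] = []
    for seq in sequences:
        hit = annotate_read(seq, db)
        if hit is None:
            unannotated.append(seq)
        else:
            hits.append(hit)
    return hits, unannotated


# ---------------------------------------------------------------------------
# Reference I/O: FASTA plus a TSV metadata sidecar.

METADATA_COLUMNS = (
    "ref_id",
    "class",
    "anticodon_start",
    "anticodon_end",
    "is_histidine",
    "isodecoder",
    "mature_start",
    "mature_end",
)


def write_references(records: Sequence[ReferenceRecord], fasta_path, meta_path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.ref_id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(meta_path, "w") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for r in records:
            ac = r.anticodon_span or ("", "")
            ms = r.mature_span or ("", "")
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.ref_id,
                        r.ref_class,
                        ac[0],
                        ac[1],
                        int(r.is_histidine),
                        r.isodecoder or "",
                        ms[0],
                        ms[1],
                    )
                )
                + "\n"
            )


def read_references(fasta_path, meta_path) -> list[ReferenceRecord]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records = []
    with open(meta_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ref_id = f[idx["ref_id"]]
            ac_lo, ac_hi = f[idx["anticodon_start"]], f[idx["anticodon_end"]]
            m_lo, m_hi = f[idx["mature_start"]], f[idx["mature_end"]]
            records.append(
                ReferenceRecord(
                    ref_id=ref_id,
                    ref_class=f[idx["class"]],
                    sequence=seqs[ref_id],
                    anticodon_span=(int(ac_lo), int(ac_hi)) if ac_lo else None,
                    is_histidine=bool(int(f[idx["is_histidine"]] or 0)),
                    isodecoder=f[idx["isodecoder"]] or None,
                    mature_span=(int(m_lo), int(m_hi)) if m_lo else None,
                )
            )
    return records


def hits_to_rows(hits: Sequence[AnnotationHit]) -> list[dict]:
    """Serialize hits with 1-based start for tabular output."""
    return [
        {
            "sequence": h.sequence,
            "class": h.ref_class,
            "ref_id": h.ref_id,
            "start": h.start + 1,
            "mismatches": h.mismatches,
            "tsrna_type": h.tsrna_type or "",
        }
        for h in hits
    ]
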