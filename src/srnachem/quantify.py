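"""Expression tables, normalizations, coverage profiles and parental
sequence grouping.

Counts are UMI-deduplicated molecule counts ("unique reads").  Two derived
layers are provided: RPM (reads per million mapped reads, where "mapped"
means cascade-annotated, genome stage included by default) and a
miRNA-anchored normalization in which each library is rescaled so its total
miRNA RPM equals one million.  The miRNA anchor makes libraries prepared
with different enzyme treatments comparable, on the premise that miRNAs
carry ligatable termini and no relevant methylation in every treatment
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import CLASS_GENOME, CLASS_MIRNA, AnnotationHit
from .preprocess import CollapsedRead

META_COLUMNS = ("class", "ref_id", "start", "tsrna_type")


@dataclass
class ExpressionTable:
    """Annotated unique sequences x libraries, with derived layers.

    ``counts`` is indexed by insert sequence with one column per library;
    ``meta`` carries the cascade annotation per sequence.  ``rpm`` and
    ``mirna_norm`` are computed lazily and cached.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    include_genome_in_denominator: bool = True
    _rpm: Optional[pd.DataFrame] = field(default=None, repr=False)
    _mirna_norm: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def rpm(self) -> pd.DataFrame:
        if self._rpm is None:
            self._rpm = compute_rpm(
                self.counts,
                self.meta,
                include_genome=self.include_genome_in_denominator,
            )
        return self._rpm

    @property
    def mirna_norm(self) -> pd.DataFrame:
        if self._mirna_norm is None:
            self._mirna_norm = normalize_to_mirna(self.rpm, self.meta)
        return self._mirna_norm


def build_expression_table(
    per_library: Mapping[str, tuple[Sequence[AnnotationHit], Sequence[CollapsedRead]]],
    include_genome_in_denominator: bool = True,
) -> ExpressionTable:
    """Assemble a table from per-library (hits, collapsed reads).

    Rows are the union of annotated sequences over libraries; cells are
    unique (molecule) counts, zero where a sequence was not seen.
    """
    count_cols = {}
    meta_rows: dict[str, dict] = {}
    for lib, (hits, collapsed) in per_library.items():
        uniq = {c.sequence: c.unique_count for c in collapsed}
        col = {}
        for h in hits:
            col[h.sequence] = uniq.get(h.sequence, 0)
            if h.sequence not in meta_rows:
                meta_rows[h.sequence] = {
                    "class": h.ref_class,
                    "ref_id": h.ref_id,
                    "start": h.start,
                    "tsrna_type": h.tsrna_type or "",
                }
        count_cols[lib] = col
    counts = pd.DataFrame(count_cols).fillna(0).astype(int)
    counts = counts.sort_index()
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(counts.index)
    return ExpressionTable(
        counts=counts,
        meta=meta,
        include_genome_in_denominator=include_genome_in_denominator,
    )


def compute_rpm(
    counts: pd.DataFrame,
    meta: Optional[pd.DataFrame] = None,
    include_genome: bool = True,
) -> pd.DataFrame:
    """Reads per million mapped reads, per library.

    The denominator is the per-library sum over all annotated rows; the
    genome stage can be excluded from it (rows keep their values, scaled by
    the smaller denominator).
    """
    if include_genome or meta is None:
        denom = counts.sum(axis=0)
    else:
        denom = counts.loc[meta["class"] != CLASS_GENOME].sum(axis=0)
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])
        raise ValueError(f"zero mapped reads in libraries: {bad}")
    return counts / denom * 1e6


def normalize_to_mirna(rpm: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Rescale each library so its total miRNA RPM is one million.

    Values remain on an RPM-like scale ("miRNA-million"); a library with no
    detected miRNA cannot be anchored and raises.
    """
    mirna_total = rpm.loc[meta["class"] == CLASS_MIRNA].sum(axis=0)
    if (mirna_total <= 0).any():
        bad = list(mirna_total.index[mirna_total <= 0])
        raise ValueError(f"no miRNA detected in libraries: {bad}")
    return rpm * (1e6 / mirna_total)


@dataclass
class CoverageProfile:
    """Per-position abundance and end-count histograms on one reference."""

    ref_id: str
    coverage: np.ndarray
    five_prime_ends: np.ndarray
    three_prime_ends: np.ndarray


def coverage_profile(
    hits: Sequence[AnnotationHit],
    abundances: Mapping[str, float],
    ref_length: int,
    ref_id: str,
    min_display: float = 0.0,
) -> CoverageProfile:
    """Sum read abundances position-wise along one reference.

    ``abundances`` maps read sequence to its weight (unique count or a
    normalized value); reads below ``min_display`` are dropped (display
    filter for structural maps, conventionally 300 RPM).
    """
    cov = np.zeros(ref_length)
    five = np.zeros(ref_length)
    three = np.zeros(ref_length)
    for h in hits:
        if h.ref_id != ref_id:
            raise ValueError(f"hit on {h.ref_id}, expected {ref_id}")
        w = abundances.get(h.sequence, 0.0)
        if w < min_display:
            continue
        end = h.start + len(h.sequence)
        cov[h.start : end] += w
        five[h.start] += w
        three[end - 1] += w
    return CoverageProfile(ref_id, cov, five, three)


def class_composition(
    table: ExpressionTable, library: str, exclude_genome: bool = True
) -> pd.Series:
    """Fraction of annotated abundance per sRNA class in one library.

    Genome-only reads are excluded from the composition denominator by
    default (they are not an sRNA class).  Fractions sum to 1.
    """
    if library not in table.counts.columns:
        raise KeyError(library)
    counts = table.counts[library]
    cls = table.meta["class"]
    if exclude_genome:
        mask = cls != CLASS_GENOME
        counts, cls = counts[mask], cls[mask]
    totals = counts.groupby(cls).sum()
    totals = totals[totals > 0]
    return totals / totals.sum()


def greedy_parent_grouping(
    counts: Mapping[str, float] | Sequence[CollapsedRead],
) -> list[tuple[str, list[str]]]:
    """Group sequences under iteratively chosen parental representatives.

    Repeatedly picks the highest-count unassigned sequence as the next
    parental sequence and assigns to it every unassigned sequence related by
    substring containment (member contained in parent or vice versa).  Ties
    on count break lexicographically.  Returns (representative, members)
    pairs; every input sequence appears in exactly one group.
    """
    if not isinstance(counts, Mapping):
        counts = {c.sequence: c.unique_count for c in counts}
    remaining = sorted(counts, key=lambda s: (-counts[s], s))
    unassigned = set(remaining)
    groups: list[tuple[str, list[str]]] = []
    for rep in remaining:
        if rep not in unassigned:
            continue
        unassigned.discard(rep)
        members = [
            s for s in remaining
            if s in unassigned and (s in rep or rep in s)
        ]
        unassigned.difference_update(members)
        groups.append((rep, members))
    return groups
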