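"""Misincorporation-based methylome calling.

A processive reverse transcriptase reads through m1A, m3C and m1G but
misincorporates at them, so those sites show elevated mismatch frequencies
in alignments.  Comparing mismatch pileups between a demethylated library
(AlkB-treated) and its untreated counterpart separates methylation signal
from sequence error: a genuine site has a high mismatch frequency without
AlkB that collapses with AlkB.  The frequency difference is reported as a
stoichiometry estimate; it is a lower bound confounded by the RT's
misincorporation rate (expected frequency at stop rate 0 is
stoichiometry x misinc_rate), which the simulator documents exactly so
tests can correct for it.

RT stops are molecule loss in this model (a truncated cDNA cannot amplify),
so stop signals appear only as coverage drop-off across a site, via
``quantify.coverage_profile``, not as a separate caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationHit, ReferenceRecord
from .simchem import METHYL_BASE, MethylKind

BASE_TO_KIND = {b: k for k, b in METHYL_BASE.items()}


@dataclass
class SitePileup:
    """Per-position depth and mismatch counts on one reference.

    ``mismatch[b]`` holds per-position counts of reads carrying substituted
    base ``b``; depth counts all covering reads.  Counts are weighted by
    unique (molecule) counts.
    """

    ref_id: str
    ref_seq: str
    depth: np.ndarray
    mismatch: dict[str, np.ndarray] = field(default_factory=dict)

    def mismatch_total(self) -> np.ndarray:
        total = np.zeros(len(self.ref_seq))
        for arr in self.mismatch.values():
            total += arr
        return total

    def frequency(self) -> np.ndarray:
        """Mismatch frequency per position (0 where depth is 0)."""
        total = self.mismatch_total()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.depth > 0, total / np.maximum(self.depth, 1), 0.0)
        return f


def build_pileup(
    hits: Sequence[AnnotationHit],
    weights: Mapping[str, float],
    references: Mapping[str, ReferenceRecord] | Sequence[ReferenceRecord],
) -> dict[str, SitePileup]:
    """Accumulate depth and mismatch pileups from <=1-mismatch alignments.

    ``weights`` maps read sequence to its molecule count.  Only alignments
    the cascade produced feed the pileup, so a methylated read carrying an
    additional sequencing error is lost (a small, documented downward bias).
    """
    if not isinstance(references, Mapping):
        references = {r.ref_id: r for r in references}
    pileups: dict[str, SitePileup] = {}
    for h in hits:
        ref = references[h.ref_id]
        if h.start + len(h.sequence) > len(ref.sequence):
            raise ValueError(f"hit on {h.ref_id} overruns the reference")
        p = pileups.get(h.ref_id)
        if p is None:
            p = SitePileup(
                ref_id=h.ref_id,
                ref_seq=ref.sequence,
                depth=np.zeros(len(ref.sequence)),
            )
            pileups[h.ref_id] = p
        w = float(weights.get(h.sequence, 0.0))
        if w == 0.0:
            continue
        p.depth[h.start : h.start + len(h.sequence)] += w
        if h.mismatches and h.mismatch_pos is not None:
            arr = p.mismatch.get(h.mismatch_base)
            if arr is None:
                arr = np.zeros(len(ref.sequence))
                p.mismatch[h.mismatch_base] = arr
            arr[h.mismatch_pos] += w
    return pileups


@dataclass(frozen=True)
class MethylCall:
    ref_id: str
    position: int  # 1-based on the reference
    kind: MethylKind
    f_no_alkb: float
    f_with_alkb: float
    depth_no_alkb: float
    depth_with_alkb: float

    @property
    def delta(self) -> float:
        return self.f_no_alkb - self.f_with_alkb

    @property
    def stoichiometry_estimate(self) -> float:
        return estimate_stoichiometry(self)


def estimate_stoichiometry(call: MethylCall) -> float:
    """Frequency-difference stoichiometry estimate (misincorporation-rate
    confounded lower bound; expected value is stoichiometry x misinc rate at
    stop rate 0)."""
    return call.f_no_alkb - call.f_with_alkb


def call_methylation_sites(
    pileup_no_alkb: Mapping[str, SitePileup],
    pileup_with_alkb: Mapping[str, SitePileup],
    f_min: float = 0.10,
    depth_min: float = 50.0,
    reduction_min: float = 3.0,
) -> list[MethylCall]:
    """Call m1A/m3C/m1G sites from paired pileups.

    A site is called iff the reference base is A, C or G, depth reaches
    ``depth_min`` in both groups, the no-AlkB mismatch frequency reaches
    ``f_min`` and AlkB reduces it at least ``reduction_min``-fold.  The
    methylation kind follows the reference base.
    """
    calls = []
    for ref_id in sorted(pileup_no_alkb):
        if ref_id not in pileup_with_alkb:
            continue
        p_no = pileup_no_alkb[ref_id]
        p_with = pileup_with_alkb[ref_id]
        f_no = p_no.frequency()
        f_with = p_with.frequency()
        for pos in range(len(p_no.ref_seq)):
            base = p_no.ref_seq[pos]
            if base not in BASE_TO_KIND:
                continue
            if p_no.depth[pos] < depth_min or p_with.depth[pos] < depth_min:
                continue
            if f_no[pos] < f_min:
                continue
            if f_no[pos] < reduction_min * max(f_with[pos], 1e-12):
                continue
            calls.append(
                MethylCall(
                    ref_id=ref_id,
                    position=pos + 1,
                    kind=BASE_TO_KIND[base],
                    f_no_alkb=float(f_no[pos]),
                    f_with_alkb=float(f_with[pos]),
                    depth_no_alkb=float(p_no.depth[pos]),
                    depth_with_alkb=float(p_with.depth[pos]),
                )
            )
    return calls


def calls_to_frame(calls: Sequence[MethylCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_id": c.ref_id,
                "position": c.position,
                "kind": c.kind.value,
                "f_no_alkb": c.f_no_alkb,
                "f_with_alkb": c.f_with_alkb,
                "delta": c.delta,
                "stoichiometry_estimate": c.stoichiometry_estimate,
                "depth_no_alkb": c.depth_no_alkb,
                "depth_with_alkb": c.depth_with_alkb,
            }
            for c in calls
        ]
    )
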