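"""Treatment-responsive species calling.

The core inference: a sequence abundant in the fully treated library but
depleted more than ``fc_threshold``-fold in a library lacking one enzyme
carries the chemistry that enzyme resolves.  Omitting T4 PNK implicates
5'-OH or 3'-P/3'-cP termini (the assay cannot distinguish these); omitting
Cap-Clip implicates a 5' cap or 5'-ppp; omitting the AlkB mix implicates
m1A/m3C/m1G methylation.  Values are compared on the miRNA-anchored
normalized layer so that library-scale differences between treatment groups
cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

CHEM_PNK = "pnk_responsive"          # 5'-OH or 3'-P / 3'-cP
CHEM_CAPCLIP = "capclip_responsive"  # 5'-cap or 5'-ppp
CHEM_ALKB = "alkb_responsive"        # m1A / m3C / m1G

OMITTED_TO_CHEMISTRY = {
    "pnk": CHEM_PNK,
    "cap_clip": CHEM_CAPCLIP,
    "alkb": CHEM_ALKB,
}

# Reduced-plan label -> enzyme the plan omits (relative to the full C+P+A).
REDUCED_LABEL_TO_OMITTED = {"CA": "pnk", "PA": "cap_clip", "CP": "alkb"}


@dataclass(frozen=True)
class ResponsiveCall:
    sequence: str
    ref_class: str
    full_value: float
    reduced_value: float
    fold_change: float
    inferred_chemistry: str


def call_responsive(
    full_values: pd.Series,
    reduced_values: pd.Series,
    omitted_enzyme: str,
    classes: Optional[Mapping[str, str] | pd.Series] = None,
    fc_threshold: float = 30.0,
    min_full: float = 10.0,
    pseudocount: float = 0.5,
) -> list[ResponsiveCall]:
    """Call treatment-responsive sequences between two libraries.

    Both inputs must be on the same (miRNA-normalized) layer, indexed by
    sequence; missing sequences count as zero.  A sequence is responsive iff
    ``full >= min_full`` and ``(full + eps) / (reduced + eps) > fc_threshold``.
    The chemistry label is a pure function of the omitted enzyme.
    """
    if omitted_enzyme not in OMITTED_TO_CHEMISTRY:
        raise ValueError(f"unknown omitted enzyme {omitted_enzyme!r}")
    chemistry = OMITTED_TO_CHEMISTRY[omitted_enzyme]
    idx = full_values.index.union(reduced_values.index)
    full = full_values.reindex(idx).fillna(0.0)
    reduced = reduced_values.reindex(idx).fillna(0.0)
    fc = (full + pseudocount) / (reduced + pseudocount)
    mask = (full >= min_full) & (fc > fc_threshold)
    if classes is None:
        classes = {}
    calls = []
    for seq in idx[mask]:
        cls = classes.get(seq, "") if isinstance(classes, Mapping) else classes.get(seq, "")
        calls.append(
            ResponsiveCall(
                sequence=seq,
                ref_class=cls or "",
                full_value=float(full[seq]),
                reduced_value=float(reduced[seq]),
                fold_change=float(fc[seq]),
                inferred_chemistry=chemistry,
            )
        )
    calls.sort(key=lambda c: (-c.full_value, c.sequence))
    return calls


def responsive_composition(calls: Sequence[ResponsiveCall]) -> pd.Series:
    """Fraction of responsive abundance (full-library values) per class."""
    if not calls:
        return pd.Series(dtype=float)
    df = pd.DataFrame(
        {"class": [c.ref_class for c in calls], "value": [c.full_value for c in calls]}
    )
    totals = df.groupby("class")["value"].sum()
    return totals / totals.sum()


def calls_to_frame(calls: Sequence[ResponsiveCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence": c.sequence,
                "class": c.ref_class,
                "full_value": c.full_value,
                "reduced_value": c.reduced_value,
                "fold_change": c.fold_change,
                "inferred_chemistry": c.inferred_chemistry,
            }
            for c in calls
        ]
    )
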