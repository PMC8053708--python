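from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np
import pytest

import srnachem as s
from srnachem.annotate import ReferenceRecord


def brute_force_align(
    seq: str, refs: Sequence[ReferenceRecord], max_mismatches: int = 1
) -> Optional[tuple[int, int, int]]:
    """Independent oracle: full Hamming scan over every offset of every
    reference.  Returns (mismatches, ref_index, start) for the best hit under
    the tie-break (fewest mismatches, then reference order, then leftmost),
    or None."""
    best = None
    for ri, ref in enumerate(refs):
        for start in range(len(ref.sequence) - len(seq) + 1):
            mm = 0
            for a, b in zip(seq, ref.sequence[start : start + len(seq)]):
                if a != b:
                    mm += 1
                    if mm > max_mismatches:
                        break
            if mm <= max_mismatches:
                cand = (mm, ri, start)
                if best is None or cand < best:
                    best = cand
    return best


@pytest.fixture(scope="session")
def scenario():
    return s.default_scenario(7)


@pytest.fixture(scope="session")
def small_study(scenario):
    """Four treatment libraries at modest depth, shared across module tests."""
    cfg = s.SimConfig(seed=7, n_reads=20_000)
    return s.run_simulated_study(scenario, ["CPA", "CA", "PA", "CP"], cfg)


def all_states():
    return s.TerminusState.all_states()


def all_plans():
    plans = []
    for dea, cc, pnk, alkb in itertools.product([False, True], repeat=4):
        plans.append(
            s.TreatmentPlan(deacylate=dea, cap_clip=cc, pnk=pnk, alkb=alkb, label="custom")
        )
    return plans
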