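"""Generative model of terminus-chemistry small-RNA library preparation.

The bench protocol being emulated: small RNAs carry one of five 5' states
(monophosphate, hydroxyl, m7G cap, m3G cap, triphosphate) and one of four 3'
states (hydroxyl, phosphate, 2',3'-cyclic phosphate, aminoacyl).  Adapter
ligation requires 5'-P and 3'-OH, so untreated libraries only see a slice of
the population.  Sequential enzymatic treatments widen that slice:

* deacylation buffer:      3'-aa  -> 3'-OH
* Cap-Clip pyrophosphatase: 5' m7G/m3G caps and 5'-ppp -> 5'-P
* T4 PNK:                  5'-OH -> 5'-P;  3'-P and 3'-cP -> 3'-OH
* AlkB demethylase mix:    removes m1A / m3C / m1G marks

Reverse transcription by a processive group-II-intron RT reads through
residual methylated nucleosides but misincorporates (or aborts) at them,
leaving a mismatch signature used downstream to call methylation sites and
estimate their stoichiometry.

Molecules are simulated with per-molecule realized methylation (a site of
stoichiometry s is marked on a given molecule with probability s), treated,
filtered on ligatability, reverse transcribed, UMI-tagged, PCR-duplicated
and emitted as FASTQ together with a ground-truth table.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate as ann
from .annotate import ReferenceRecord

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


class FivePrime(str, Enum):
    P = "P"
    OH = "OH"
    CAP_M7G = "cap_m7G"
    CAP_M3G = "cap_m3G"
    PPP = "ppp"


class ThreePrime(str, Enum):
    OH = "OH"
    P = "P"
    CP = "cP"
    AA = "aa"


class MethylKind(str, Enum):
    M1A = "m1A"
    M3C = "m3C"
    M1G = "m1G"


METHYL_BASE = {MethylKind.M1A: "A", MethylKind.M3C: "C", MethylKind.M1G: "G"}

CAPPED_FIVE = (FivePrime.CAP_M7G, FivePrime.CAP_M3G, FivePrime.PPP)
PNK_THREE = (ThreePrime.P, ThreePrime.CP)


@dataclass(frozen=True)
class TerminusState:
    five_prime: FivePrime
    three_prime: ThreePrime

    @staticmethod
    def all_states() -> list["TerminusState"]:
        return [TerminusState(f, t) for f in FivePrime for t in ThreePrime]


@dataclass(frozen=True)
class MethylSite:
    """A methylated nucleoside within a species sequence (0-based offset)."""

    offset: int
    kind: MethylKind
    stoichiometry: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.stoichiometry <= 1.0):
            raise ValueError("stoichiometry must lie in [0, 1]")


@dataclass
class SRNASpecies:
    """One distinct small-RNA molecule species with its chemical ground truth.

    ``abundance`` holds one nonnegative weight per condition (tissue);
    ``parent_span`` is 0-based half-open on the parent reference sequence.
    """

    id: str
    sequence: str
    parent_class: str
    parent_id: Optional[str] = None
    parent_span: Optional[tuple[int, int]] = None
    terminus: TerminusState = TerminusState(FivePrime.P, ThreePrime.OH)
    methyl_sites: list[MethylSite] = field(default_factory=list)
    abundance: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        for site in self.methyl_sites:
            if self.sequence[site.offset] != METHYL_BASE[site.kind]:
                raise ValueError(
                    f"{self.id}: base at offset {site.offset} is "
                    f"{self.sequence[site.offset]}, not {METHYL_BASE[site.kind]}"
                )
        if any(a < 0 for a in self.abundance):
            raise ValueError(f"{self.id}: negative abundance")


PLAN_FLAG_LETTERS = {"C": "cap_clip", "P": "pnk", "A": "alkb"}


@dataclass(frozen=True)
class TreatmentPlan:
    """Which enzymes a library preparation applies.

    Named groups follow the C/P/A letter code (Cap-Clip, PNK, AlkB);
    deacylation is applied in every named group.  Whether the "untreated"
    control includes deacylation is protocol-dependent and exposed as a flag.
    """

    deacylate: bool = True
    cap_clip: bool = False
    pnk: bool = False
    alkb: bool = False
    label: str = ""

    @classmethod
    def from_label(cls, label: str, deacylate: bool = True) -> "TreatmentPlan":
        if label == "untreated":
            return cls(deacylate=deacylate, label=label)
        flags = {"cap_clip": False, "pnk": False, "alkb": False}
        for ch in label:
            if ch not in PLAN_FLAG_LETTERS:
                raise ValueError(f"unknown treatment letter {ch!r} in {label!r}")
            flags[PLAN_FLAG_LETTERS[ch]] = True
        return cls(deacylate=True, label=label, **flags)


FULL_PLAN = TreatmentPlan.from_label("CPA")


@dataclass
class SimConfig:
    """Simulation parameters.

    All probabilities are per-event and lie in [0, 1].  ``seed`` is mandatory:
    every random draw in the generator flows from it.
    """

    seed: int
    n_reads: int = 200_000
    umi5_len: int = 6
    umi3_len: int = 6
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    adapter3: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACA"
    seq_error_rate: float = 0.001
    misinc_rate: float = 0.6
    stop_rate: float = 0.1
    alkb_efficiency: float = 1.0
    enzyme_efficiencies: dict = field(
        default_factory=lambda: {"deacylate": 1.0, "cap_clip": 1.0, "pnk": 1.0}
    )
    pcr_dup_mean: float = 1.5
    read_length: int = 75
    quality_char: str = "F"  # Phred+33 Q37
    low_quality_fraction: float = 0.0
    low_quality_char: str = "5"  # Q20, rejected by the default mean-Q30 gate

    def __post_init__(self) -> None:
        probs = [
            self.seq_error_rate,
            self.misinc_rate,
            self.stop_rate,
            self.alkb_efficiency,
            self.low_quality_fraction,
            *self.enzyme_efficiencies.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.pcr_dup_mean < 1.0:
            raise ValueError("pcr_dup_mean must be >= 1")


def is_ligatable(state: TerminusState) -> bool:
    """Adapter ligation requires a 5'-monophosphate and a 3'-hydroxyl."""
    return state.five_prime is FivePrime.P and state.three_prime is ThreePrime.OH


def apply_treatments(
    state: TerminusState,
    sites: Sequence[MethylSite],
    plan: TreatmentPlan,
    rng: Optional[np.random.Generator] = None,
    cfg: Optional[SimConfig] = None,
) -> tuple[TerminusState, list[MethylSite]]:
    """Apply the enzymatic treatment plan to one molecule.

    Order is fixed (deacylate, Cap-Clip, PNK, AlkB).  With the default
    efficiencies of 1.0 every conversion is deterministic and the operation is
    idempotent; lower efficiencies make each conversion an independent
    Bernoulli event drawn from ``rng``.
    """
    eff = cfg.enzyme_efficiencies if cfg is not None else {}
    alkb_eff = cfg.alkb_efficiency if cfg is not None else 1.0

    def acts(enzyme: str) -> bool:
        p = eff.get(enzyme, 1.0)
        if p >= 1.0:
            return True
        if rng is None:
            raise ValueError("rng required for sub-unit enzyme efficiencies")
        return bool(rng.random() < p)

    five, three = state.five_prime, state.three_prime
    if plan.deacylate and three is ThreePrime.AA and acts("deacylate"):
        three = ThreePrime.OH
    if plan.cap_clip and five in CAPPED_FIVE and acts("cap_clip"):
        five = FivePrime.P
    if plan.pnk:
        if five is FivePrime.OH and acts("pnk"):
            five = FivePrime.P
        if three in PNK_THREE and acts("pnk"):
            three = ThreePrime.OH
    residual = list(sites)
    if plan.alkb and residual:
        if alkb_eff >= 1.0:
            residual = []
        else:
            if rng is None:
                raise ValueError("rng required for sub-unit AlkB efficiency")
            residual = [s for s in residual if rng.random() >= alkb_eff]
    return TerminusState(five, three), residual


DROPPED = None  # sentinel: RT aborted, molecule lost (cannot be amplified)


def reverse_transcribe(
    seq: str,
    residual_sites: Sequence[MethylSite],
    rng: np.random.Generator,
    cfg: SimConfig,
) -> Optional[str]:
    """Reverse transcription with misincorporation/abort at methylated sites.

    At each residual methylated site, independently: with ``stop_rate`` the RT
    aborts and the molecule is dropped (a truncated cDNA lacks the second
    adapter complement and cannot amplify); otherwise with ``misinc_rate`` the
    base at the site is replaced by a uniformly chosen different base.
    Per-base sequencing error is applied afterwards at ``seq_error_rate``.
    """
    out = seq
    for site in residual_sites:
        if cfg.stop_rate > 0 and rng.random() < cfg.stop_rate:
            return DROPPED
        if cfg.misinc_rate > 0 and rng.random() < cfg.misinc_rate:
            old = out[site.offset]
            new = BASES[(BASES.index(old) + 1 + rng.integers(3)) % 4]
            out = out[: site.offset] + new + out[site.offset + 1 :]
    if cfg.seq_error_rate > 0:
        n_err = rng.binomial(len(out), cfg.seq_error_rate)
        for pos in rng.choice(len(out), size=n_err, replace=False) if n_err else ():
            old = out[pos]
            new = BASES[(BASES.index(old) + 1 + rng.integers(3)) % 4]
            out = out[:pos] + new + out[pos + 1 :]
    return out


def _random_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if length == 0:
        return [""] * n
    arr = _BASE_ARR[rng.integers(0, 4, size=(n, length))]
    return [row.tobytes().decode() for row in arr]


TRUTH_COLUMNS = (
    "species_id",
    "parent_class",
    "sequence",
    "five_final",
    "three_final",
    "n_drawn",
    "n_ligatable",
    "n_molecules",
    "n_reads",
)


def simulate_library(
    species: Sequence[SRNASpecies],
    condition: int,
    plan: TreatmentPlan,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one sequencing library under a treatment plan.

    Draws ``cfg.n_reads`` molecules proportional to abundance in the given
    condition, applies treatments, discards non-ligatable molecules (no
    redraw: library depth reflects ligatability), reverse transcribes
    survivors, attaches UMIs and the in-read 3' adapter, PCR-duplicates each
    molecule (geometric, mean ``pcr_dup_mean``) and emits FASTQ records as
    (id, sequence, quality) tuples plus a per-species truth table.

    Reads are sequenced from the 5'-adapter side, so the emitted read is
    UMI5 + insert + UMI3 + 3'-adapter, truncated to ``read_length``.
    """
    if not species:
        raise ValueError("species list is empty")
    if cfg.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    weights = np.array([sp.abundance[condition] for sp in species], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no species has positive abundance in this condition")
    counts = rng.multinomial(cfg.n_reads, weights / weights.sum())

    records: list[tuple[str, str, str]] = []
    truth_rows = []
    deterministic_enzymes = all(v >= 1.0 for v in cfg.enzyme_efficiencies.values())
    read_no = 0
    for sp, m in zip(species, counts):
        # Deterministic-path final state, for the truth table label.
        label_state, _ = apply_treatments(sp.terminus, [], plan)
        n_lig = 0
        n_mol = 0
        n_reads_emitted = 0
        if m > 0:
            k = len(sp.methyl_sites)
            stoich = np.array([s.stoichiometry for s in sp.methyl_sites])
            marked = (
                rng.random((m, k)) < stoich if k else np.zeros((m, 0), dtype=bool)
            )
            # Terminus conversion / ligatability per molecule.
            if deterministic_enzymes:
                lig = np.full(m, is_ligatable(label_state))
            else:
                lig = np.empty(m, dtype=bool)
                for j in range(m):
                    st, _ = apply_treatments(sp.terminus, [], plan, rng, cfg)
                    lig[j] = is_ligatable(st)
            # AlkB demethylation of realized marks.
            residual = marked
            if plan.alkb and k:
                residual = marked & ~(rng.random((m, k)) < cfg.alkb_efficiency)
            # RT stops at residual marks.
            if k and cfg.stop_rate > 0:
                stopped = (residual & (rng.random((m, k)) < cfg.stop_rate)).any(axis=1)
            else:
                stopped = np.zeros(m, dtype=bool)
            # RT misincorporation at residual, non-stopped marks.
            if k and cfg.misinc_rate > 0:
                misinc = residual & (rng.random((m, k)) < cfg.misinc_rate)
            else:
                misinc = np.zeros((m, k), dtype=bool)
            keep = lig & ~stopped
            n_lig = int(lig.sum())
            idx = np.flatnonzero(keep)
            n_mol = len(idx)
            if n_mol:
                umi5 = _random_umis(rng, n_mol, cfg.umi5_len)
                umi3 = _random_umis(rng, n_mol, cfg.umi3_len)
                dup = (
                    rng.geometric(1.0 / cfg.pcr_dup_mean, size=n_mol)
                    if cfg.pcr_dup_mean > 1.0
                    else np.ones(n_mol, dtype=int)
                )
                n_err = (
                    rng.binomial(len(sp.sequence), cfg.seq_error_rate, size=n_mol)
                    if cfg.seq_error_rate > 0
                    else np.zeros(n_mol, dtype=int)
                )
                lowq = (
                    rng.random(n_mol) < cfg.low_quality_fraction
                    if cfg.low_quality_fraction > 0
                    else np.zeros(n_mol, dtype=bool)
                )
                # Insert variants: substitution pattern -> sequence, cached.
                variant_cache: dict[tuple[int, ...], str] = {}
                for row, j in enumerate(idx):
                    mis_offsets = tuple(
                        sp.methyl_sites[q].offset for q in np.flatnonzero(misinc[j])
                    )
                    insert = variant_cache.get(mis_offsets)
                    if insert is None:
                        insert = sp.sequence
                        for off in mis_offsets:
                            old = insert[off]
                            new = BASES[(BASES.index(old) + 1 + rng.integers(3)) % 4]
                            insert = insert[:off] + new + insert[off + 1 :]
                        variant_cache[mis_offsets] = insert
                    if n_err[row]:
                        chars = list(insert)
                        for pos in rng.choice(len(chars), size=n_err[row], replace=False):
                            old = chars[pos]
                            chars[pos] = BASES[(BASES.index(old) + 1 + rng.integers(3)) % 4]
                        insert = "".join(chars)
                    read = (umi5[row] + insert + umi3[row] + cfg.adapter3)[: cfg.read_length]
                    qc = cfg.low_quality_char if lowq[row] else cfg.quality_char
                    qual = qc * len(read)
                    for _ in range(int(dup[row])):
                        read_no += 1
                        records.append((f"{sp.id}:{read_no}", read, qual))
                        n_reads_emitted += 1
        truth_rows.append(
            (
                sp.id,
                sp.parent_class,
                sp.sequence,
                label_state.five_prime.value,
                label_state.three_prime.value,
                int(m),
                n_lig,
                n_mol,
                n_reads_emitted,
            )
        )
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return records, truth


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (id, sequence, quality) tuples as 4-line FASTQ (gzip if *.gz)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Default synthetic scenario

# Parent class labels carried by species (sources of the small RNAs).
P_MIRNA = "miRNA"
P_RSRNA = "rsRNA"
P_TSRNA = "tsRNA"
P_PRE_TSRNA = "pre_tsRNA"
P_PIRNA = "piRNA"
P_SNSRNA = "snsRNA"
P_SNOSRNA = "snosRNA"
P_LNCSRNA = "lncsRNA"
P_MT_TSRNA = "mt_tsRNA"
P_MRNA_SRNA = "mRNA_sRNA"
P_OTHER = "other"

PARENT_CLASSES = (
    P_MIRNA,
    P_RSRNA,
    P_TSRNA,
    P_PRE_TSRNA,
    P_PIRNA,
    P_SNSRNA,
    P_SNOSRNA,
    P_LNCSRNA,
    P_MT_TSRNA,
    P_MRNA_SRNA,
    P_OTHER,
)

# Expected cascade assignment for each parent class (used by truth-based
# evaluation of the annotation cascade).
PARENT_TO_REF_CLASS = {
    P_MIRNA: ann.CLASS_MIRNA,
    P_RSRNA: ann.CLASS_RRNA,
    P_TSRNA: ann.CLASS_CYTO_TRNA,
    P_PRE_TSRNA: ann.CLASS_PRE_TRNA,
    P_PIRNA: ann.CLASS_PIRNA,
    P_SNSRNA: ann.CLASS_SNRNA,
    P_SNOSRNA: ann.CLASS_SNORNA,
    P_LNCSRNA: ann.CLASS_LNCRNA,
    P_MT_TSRNA: ann.CLASS_MITO_TRNA,
    P_MRNA_SRNA: ann.CLASS_MRNA,
    P_OTHER: ann.CLASS_GENOME,
}


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_ARR[rng.integers(0, 4, size=n)].tobytes().decode()


@dataclass
class Scenario:
    """A complete simulated study: species truth, references, tissue names."""

    species: list[SRNASpecies]
    references: list[ReferenceRecord]
    tissues: tuple[str, ...]

    def species_table(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            rows.append(
                {
                    "species_id": sp.id,
                    "parent_class": sp.parent_class,
                    "parent_id": sp.parent_id or "",
                    "span_start": sp.parent_span[0] if sp.parent_span else "",
                    "span_end": sp.parent_span[1] if sp.parent_span else "",
                    "five_prime": sp.terminus.five_prime.value,
                    "three_prime": sp.terminus.three_prime.value,
                    "methyl_sites": ";".join(
                        f"{s.offset}:{s.kind.value}:{s.stoichiometry}"
                        for s in sp.methyl_sites
                    ),
                    "sequence": sp.sequence,
                    **{
                        f"abundance_{t}": sp.abundance[i]
                        for i, t in enumerate(self.tissues)
                    },
                }
            )
        return pd.DataFrame(rows)


def default_scenario(seed: int, n_tissues: int = 3) -> Scenario:
    """Build the default synthetic study.

    Emits >= 120 species spread over all parent classes (>= 8 each), covering
    every one of the 20 terminus-state pairs and all three methylation kinds
    at stoichiometries 0.25, 0.5 and 1.0, across ``n_tissues`` conditions
    including strictly single-tissue species.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    tissues = tuple(f"tissue{i+1}" for i in range(n_tissues))
    refs: list[ReferenceRecord] = []
    used_seqs: set[str] = set()

    def fresh_seq(n: int) -> str:
        while True:
            s = _rand_seq(rng, n)
            if s not in used_seqs:
                used_seqs.add(s)
                return s

    # --- references -------------------------------------------------------
    mirna_refs = [
        ReferenceRecord(f"mir-{i+1}", ann.CLASS_MIRNA, fresh_seq(int(rng.integers(20, 25))))
        for i in range(12)
    ]
    rrna_lens = {"rRNA-5S": 120, "rRNA-18S": 600, "rRNA-28S": 800}
    rrna_refs = [ReferenceRecord(k, ann.CLASS_RRNA, fresh_seq(n)) for k, n in rrna_lens.items()]

    # Cytosolic tRNAs live on a toy genome contig so precursors can be cut out.
    amino = ["Ala", "Gly", "Glu", "Lys", "His", "Val", "Leu", "Ser", "His", "Arg"]
    gap = 400
    contig_parts = [_rand_seq(rng, 300)]
    pos = 300
    trna_loci = []  # (ref_id, contig, start, end)
    raw_trnas = []
    for i, aa in enumerate(amino):
        body = _rand_seq(rng, 72)
        rid = f"tRNA-{aa}-{i+1}"
        raw_trnas.append(
            ReferenceRecord(
                rid,
                ann.CLASS_CYTO_TRNA,
                body,
                anticodon_span=(34, 36),
                is_histidine=(aa == "His"),
                isodecoder=f"{aa}-{i+1}",
            )
        )
        trna_loci.append((rid, "chr_toy", pos, pos + 72))
        contig_parts.append(body)
        pos += 72
        g = _rand_seq(rng, gap)
        while g.startswith("CCA"):  # keep mature CCA junction unambiguous
            g = _rand_seq(rng, gap)
        contig_parts.append(g)
        pos += gap
    contig = "".join(contig_parts)
    mature_trnas = ann.build_mature_trna_refs(raw_trnas)
    pre_trnas = ann.build_precursor_refs(
        {"chr_toy": contig},
        [(f"pre_{rid}", c, s, e) for rid, c, s, e in trna_loci],
    )

    pirna_refs = [
        ReferenceRecord(f"piR-cluster-{i+1}", ann.CLASS_PIRNA, fresh_seq(800)) for i in range(2)
    ]
    mito_raw = [
        ReferenceRecord(
            f"mt-tRNA-{i+1}",
            ann.CLASS_MITO_TRNA,
            fresh_seq(70),
            anticodon_span=(33, 35),
            isodecoder=f"mt-{i+1}",
        )
        for i in range(8)
    ]
    mito_trnas = ann.build_mature_trna_refs(mito_raw)
    lnc_refs = [ReferenceRecord(f"lncRNA-{i+1}", ann.CLASS_LNCRNA, fresh_seq(400)) for i in range(3)]
    sn_refs = [ReferenceRecord(f"snRNA-U{i+1}", ann.CLASS_SNRNA, fresh_seq(160)) for i in range(4)]
    sno_refs = [ReferenceRecord(f"snoRNA-{i+1}", ann.CLASS_SNORNA, fresh_seq(130)) for i in range(4)]
    mrna_refs = [ReferenceRecord(f"mRNA-{i+1}", ann.CLASS_MRNA, fresh_seq(400)) for i in range(3)]
    genome_ref = ReferenceRecord("chr_toy", ann.CLASS_GENOME, contig)

    refs = (
        mirna_refs
        + rrna_refs
        + mature_trnas
        + pre_trnas
        + pirna_refs
        + mito_trnas
        + lnc_refs
        + sn_refs
        + sno_refs
        + mrna_refs
        + [genome_ref]
    )

    # --- methylation truth: sites live on reference positions --------------
    # (ref_id -> list of (ref position 0-based, kind, stoichiometry)).
    ref_sites: dict[str, list[tuple[int, MethylKind, float]]] = {}
    kinds = [MethylKind.M1A, MethylKind.M3C, MethylKind.M1G]
    stoichs = [0.25, 0.5, 1.0]
    combo = list(itertools.product(kinds, stoichs))  # 9 sites

    def place_site(ref: ReferenceRecord, lo: int, hi: int, kind: MethylKind, st: float):
        base = METHYL_BASE[kind]
        for p in range(lo, hi):
            if ref.sequence[p] == base and not any(
                abs(p - q) < 3 for q, _, _ in ref_sites.get(ref.ref_id, [])
            ):
                ref_sites.setdefault(ref.ref_id, []).append((p, kind, st))
                return p
        raise RuntimeError(f"no {base} found in {ref.ref_id}[{lo}:{hi}]")

    methylated_trnas = mature_trnas[:6]
    site_positions = {}
    for ref, (kind, st) in zip(methylated_trnas, combo[:6]):
        site_positions[ref.ref_id] = place_site(ref, 45, 70, kind, st)
    for ref, (kind, st) in zip(rrna_refs, combo[6:]):
        site_positions[ref.ref_id] = place_site(ref, 40, 90, kind, st)

    # --- species ----------------------------------------------------------
    species: list[SRNASpecies] = []
    term_cycle = itertools.cycle(
        [TerminusState(f, t) for f in FivePrime for t in ThreePrime]
    )

    def sites_for(ref: ReferenceRecord, span: tuple[int, int]) -> list[MethylSite]:
        out = []
        for p, kind, st in ref_sites.get(ref.ref_id, []):
            if span[0] <= p < span[1]:
                out.append(MethylSite(p - span[0], kind, st))
        return out

    def add_species(
        prefix: str,
        parent_class: str,
        ref: ReferenceRecord,
        span: tuple[int, int],
        terminus: Optional[TerminusState] = None,
        weight: float = 1.0,
        tissue_only: Optional[int] = None,
    ) -> None:
        seq = ref.sequence[span[0] : span[1]]
        if seq in used_seqs and parent_class != P_MIRNA:
            return
        used_seqs.add(seq)
        if terminus is None:
            terminus = next(term_cycle)
        if tissue_only is None:
            ab = tuple(weight for _ in tissues)
        else:
            ab = tuple(
                weight * n_tissues if i == tissue_only else 0.0
                for i in range(n_tissues)
            )
        species.append(
            SRNASpecies(
                id=f"{prefix}{len(species):03d}",
                sequence=seq,
                parent_class=parent_class,
                parent_id=ref.ref_id,
                parent_span=span,
                terminus=terminus,
                methyl_sites=sites_for(ref, span),
                abundance=ab,
            )
        )

    def random_window(ref: ReferenceRecord, length: int) -> tuple[int, int]:
        start = int(rng.integers(0, len(ref.sequence) - length + 1))
        return (start, start + length)

    # miRNA: canonical 5'-P / 3'-OH, unmethylated, used as the normalization
    # anchor across treatment groups.
    for ref in mirna_refs:
        add_species("sp", P_MIRNA, ref, (0, len(ref.sequence)),
                    terminus=TerminusState(FivePrime.P, ThreePrime.OH))

    # rsRNA: random windows plus one window per methylated rRNA covering its
    # site (so site depth is concentrated rather than diluted).
    for ref in rrna_refs:
        p = site_positions[ref.ref_id]
        lo = max(0, p - 15)
        add_species("sp", P_RSRNA, ref, (lo, min(len(ref.sequence), lo + 32)))
        for _ in range(3):
            add_species("sp", P_RSRNA, ref, random_window(ref, int(rng.integers(20, 37))))

    # tsRNA: one canonical fragment type per mature tRNA, plus a dedicated
    # site-covering fragment on each methylated tRNA.
    frag_types = itertools.cycle(["tRF5", "half5", "half3", "tRF3", "internal"])
    for ref in mature_trnas:
        ac_lo, ac_hi = ref.anticodon_span
        L = len(ref.sequence)
        ftype = next(frag_types)
        span = {
            "tRF5": (0, ac_lo - 3),
            "half5": (0, ac_hi),
            "half3": (ac_hi, L),
            "tRF3": (L - 19, L),
            "internal": (19, 50),
        }[ftype]
        add_species("sp", P_TSRNA, ref, span)
        add_species("sp", P_TSRNA, ref, (12, 44))  # second fragment per tRNA
    for ref in methylated_trnas:
        p = site_positions[ref.ref_id]
        lo = max(0, p - 20)
        add_species("sp", P_TSRNA, ref, (lo, min(len(ref.sequence), lo + 36)), weight=1.5)

    # pre-tsRNA: 5' leaders and 3' trailers on precursors.
    for i, ref in enumerate(pre_trnas[:8]):
        m_lo, m_hi = ref.mature_span
        if i % 2 == 0:
            span = (m_lo - 30, m_lo + int(rng.integers(0, 4)))
        else:
            span = (m_hi - int(rng.integers(0, 4)), m_hi + 30)
        add_species("sp", P_PRE_TSRNA, ref, span)

    for ref in pirna_refs:
        for _ in range(5):
            add_species("sp", P_PIRNA, ref, random_window(ref, int(rng.integers(26, 31))))
    for ref in mito_trnas:
        add_species("sp", P_MT_TSRNA, ref, (0, int(rng.integers(28, 37))))
    for ref in sn_refs:
        # snRNA-derived fragments are 5'-anchored (cap-carrying in vivo).
        add_species("sp", P_SNSRNA, ref, (0, int(rng.integers(22, 37))))
        add_species("sp", P_SNSRNA, ref, (4, 4 + int(rng.integers(20, 33))))
        add_species("sp", P_SNSRNA, ref, (60, 60 + int(rng.integers(20, 33))))
    for ref in sno_refs:
        add_species("sp", P_SNOSRNA, ref, (0, int(rng.integers(22, 37))))
        add_species("sp", P_SNOSRNA, ref, random_window(ref, int(rng.integers(20, 34))))
    for ref in lnc_refs:
        add_species("sp", P_LNCSRNA, ref, (0, int(rng.integers(22, 37))))
        add_species("sp", P_LNCSRNA, ref, (5, 5 + int(rng.integers(20, 33))))
        add_species("sp", P_LNCSRNA, ref, random_window(ref, int(rng.integers(20, 34))))
    for ref in mrna_refs:
        for _ in range(3):
            add_species("sp", P_MRNA_SRNA, ref, random_window(ref, int(rng.integers(20, 37))))
    # "other": intergenic genome windows placed clear of precursor flanks.
    other_centers = []
    for _, _, s, e in trna_loci:
        other_centers.append(e + 100 + 60)  # middle of the flank-free gap zone
    for i in range(10):
        c = other_centers[i % len(other_centers)] + (i // len(other_centers)) * 37
        add_species("sp", P_OTHER, genome_ref, (c, c + int(rng.integers(22, 37))))

    # Single-tissue species: last two species of each class get routed to one
    # tissue only (weight scaled so per-tissue sampling stays comparable).
    by_class: dict[str, list[SRNASpecies]] = {}
    for sp in species:
        by_class.setdefault(sp.parent_class, []).append(sp)
    t_idx = 0
    for cls, members in by_class.items():
        if cls == P_MIRNA:
            continue  # keep the normalization anchor in every tissue
        # Methylation-carrying species stay multi-tissue so every planted
        # site keeps coverage in every condition.
        eligible = [sp for sp in reversed(members) if not sp.methyl_sites][:2]
        for sp in eligible:
            only = t_idx % n_tissues
            w = sp.abundance[0]
            sp.abundance = tuple(
                w * n_tissues if i == only else 0.0 for i in range(n_tissues)
            )
            t_idx += 1

    counts = {c: len(m) for c, m in by_class.items()}
    missing = [c for c in PARENT_CLASSES if counts.get(c, 0) < 8]
    if missing or len(species) < 120:
        raise RuntimeError(f"scenario underfilled: {counts}")
    return Scenario(species=species, references=refs, tissues=tissues)
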