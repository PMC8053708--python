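"""Treatment algebra, ligatability, reverse transcription and library
simulation."""

from __future__ import annotations

import numpy as np
import pytest

import srnachem as s
from srnachem.simchem import FivePrime, MethylKind, ThreePrime

from conftest import all_plans, all_states


def plan(label):
    return s.TreatmentPlan.from_label(label)


def state(five, three):
    return s.TerminusState(FivePrime(five), ThreePrime(three))


class TestApplyTreatments:
    @pytest.mark.parametrize(
        "before,label,after",
        [
            (("cap_m7G", "OH"), "C", ("P", "OH")),  # decapping enables 5' ligation
            (("OH", "P"), "P", ("P", "OH")),  # kinase repairs both ends
            (("P", "aa"), "untreated", ("P", "OH")),  # deacylation alone
            (("ppp", "cP"), "CPA", ("P", "OH")),
            (("OH", "aa"), "C", ("OH", "OH")),  # Cap-Clip does not touch 5'-OH
        ],
    )
    def test_known_transitions(self, before, label, after):
        out, residual = s.apply_treatments(state(*before), [], plan(label))
        assert out == state(*after)
        assert residual == []

    def test_empty_plan_is_identity(self):
        empty = s.TreatmentPlan(deacylate=False, label="none")
        for st in all_states():
            out, _ = s.apply_treatments(st, [], empty)
            assert out == st

    def test_idempotent_at_full_efficiency(self):
        for st in all_states():
            for p in all_plans():
                once, _ = s.apply_treatments(st, [], p)
                twice, _ = s.apply_treatments(once, [], p)
                assert twice == once

    def test_full_plan_maps_everything_to_ligatable(self):
        for st in all_states():
            out, _ = s.apply_treatments(st, [], plan("CPA"))
            assert out == state("P", "OH")
            assert s.is_ligatable(out)

    def test_alkb_strips_realized_marks(self):
        sites = [s.MethylSite(3, MethylKind.M1A, 1.0)]
        _, residual = s.apply_treatments(state("P", "OH"), sites, plan("CPA"))
        assert residual == []
        _, residual = s.apply_treatments(state("P", "OH"), sites, plan("CP"))
        assert residual == sites


class TestLigatability:
    def test_only_p_oh_ligates(self):
        for st in all_states():
            expected = st.five_prime is FivePrime.P and st.three_prime is ThreePrime.OH
            assert s.is_ligatable(st) is expected


class TestReverseTranscription:
    def cfg(self, **kw):
        base = dict(seed=1, seq_error_rate=0.0, misinc_rate=0.0, stop_rate=0.0)
        base.update(kw)
        return s.SimConfig(**base)

    def test_clean_molecule_copies_exactly(self):
        rng = np.random.default_rng(0)
        assert s.reverse_transcribe("ACGTACGT", [], rng, self.cfg()) == "ACGTACGT"

    def test_certain_misincorporation_substitutes_the_site(self):
        rng = np.random.default_rng(0)
        seq = "ACGTACGTACGT"
        site = s.MethylSite(4, MethylKind.M1A, 1.0)
        out = s.reverse_transcribe(seq, [site], rng, self.cfg(misinc_rate=1.0))
        assert out is not None and len(out) == len(seq)
        diffs = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert diffs == [4]

    def test_certain_stop_drops_molecule(self):
        rng = np.random.default_rng(0)
        site = s.MethylSite(2, MethylKind.M3C, 1.0)
        assert s.reverse_transcribe("AACAA", [site], rng, self.cfg(stop_rate=1.0)) is None


class TestSimulateLibrary:
    def test_clean_single_species_library(self):
        sp = s.SRNASpecies(id="x", sequence="ACGTACGTACGTACGTACGT", parent_class="other")
        cfg = s.SimConfig(
            seed=3, n_reads=100, seq_error_rate=0.0, pcr_dup_mean=1.0,
            umi5_len=2, umi3_len=2,
        )
        records, truth = s.simulate_library([sp], 0, s.TreatmentPlan.from_label("CPA"), cfg)
        assert len(records) == 100
        for _, read, qual in records:
            assert read[2:22] == sp.sequence
            assert set(qual) == {"F"}
        assert truth.loc[0, "n_reads"] == 100

    def test_unligatable_species_yields_no_reads(self):
        sp = s.SRNASpecies(
            id="x",
            sequence="ACGTACGTACGTACGTACGT",
            parent_class="other",
            terminus=s.TerminusState(FivePrime.CAP_M7G, ThreePrime.OH),
        )
        cfg = s.SimConfig(seed=3, n_reads=50)
        records, truth = s.simulate_library([sp], 0, s.TreatmentPlan.from_label("PA"), cfg)
        assert records == []
        assert truth.loc[0, "n_drawn"] == 50
        assert truth.loc[0, "n_ligatable"] == 0

    def test_errors(self):
        cfg = s.SimConfig(seed=1, n_reads=10)
        with pytest.raises(ValueError):
            s.simulate_library([], 0, s.TreatmentPlan.from_label("CPA"), cfg)
        sp = s.SRNASpecies(id="x", sequence="ACGT" * 5, parent_class="other")
        with pytest.raises(ValueError):
            s.simulate_library(
                [sp], 0, s.TreatmentPlan.from_label("CPA"), s.SimConfig(seed=1, n_reads=0)
            )

    def test_rerun_is_byte_identical(self, scenario):
        cfg = s.SimConfig(seed=11, n_reads=5_000)
        plan_ = s.TreatmentPlan.from_label("CA")
        r1, t1 = s.simulate_library(
            scenario.species, 0, plan_, cfg, np.random.default_rng(11)
        )
        r2, t2 = s.simulate_library(
            scenario.species, 0, plan_, cfg, np.random.default_rng(11)
        )
        assert r1 == r2
        assert t1.equals(t2)


class TestDetectionMonotonicity:
    def test_reduced_plan_detects_subset_of_full(self, scenario):
        """With full efficiencies and no RT stops, a reduced treatment can
        only reveal species the full treatment also reveals."""
        cfg = s.SimConfig(seed=5, n_reads=60_000, stop_rate=0.0)
        study = s.run_simulated_study(scenario, ["CPA", "CA"], cfg)
        active = {sp.sequence for sp in scenario.species if sp.abundance[0] > 0}
        det = {}
        for lab in ("CPA", "CA"):
            col = study.table.counts[lab]
            det[lab] = set(col.index[col > 0]) & active
        assert det["CA"] <= det["CPA"]


class TestDefaultScenario:
    def test_deterministic(self):
        a = s.default_scenario(3)
        b = s.default_scenario(3)
        assert a.species_table().equals(b.species_table())
        assert [r.sequence for r in a.references] == [r.sequence for r in b.references]

    def test_class_coverage(self, scenario):
        from collections import Counter

        counts = Counter(sp.parent_class for sp in scenario.species)
        assert len(scenario.species) >= 120
        assert all(counts[c] >= 8 for c in s.simchem.PARENT_CLASSES)

    def test_terminus_state_coverage(self, scenario):
        combos = {
            (sp.terminus.five_prime, sp.terminus.three_prime) for sp in scenario.species
        }
        assert len(combos) == 20

    def test_methylation_kinds_and_stoichiometries(self, scenario):
        seen = {
            (site.kind, site.stoichiometry)
            for sp in scenario.species
            for site in sp.methyl_sites
        }
        kinds = {k for k, _ in seen}
        stoichs = {st for _, st in seen}
        assert kinds == {MethylKind.M1A, MethylKind.M3C, MethylKind.M1G}
        assert stoichs == {0.25, 0.5, 1.0}

    def test_single_tissue_species_exist(self, scenario):
        single = [
            sp
            for sp in scenario.species
            if sum(a > 0 for a in sp.abundance) == 1
        ]
        assert len(single) >= scenario.tissues.__len__()

    def test_species_match_their_parent_span(self, scenario):
        refs = {r.ref_id: r for r in scenario.references}
        for sp in scenario.species:
            parent = refs[sp.parent_id]
            lo, hi = sp.parent_span
            assert sp.sequence == parent.sequence[lo:hi]
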