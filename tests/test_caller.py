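"""Editing-site calling: filter thresholds, pooling, efficiency and recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastedit import dna
from plastedit.calling import (
    apply_replicate_filter,
    call_candidates,
    compute_efficiency,
    recover_sites,
    round_percent,
)
from plastedit.ingest import PileupSet
from plastedit.simulate import GroundTruthSite

GENOME = "ACGTC" * 40  # 200 bp; C at 0-based 1, 4, 6, 9, ...


def _pileup(spec, conditions=None):
    """spec: {rep: {(pos0, strand): {base: count}}}"""
    conditions = conditions or {}
    pileup = PileupSet(len(GENOME))
    for rep, cols in spec.items():
        by = pileup._ensure(rep, conditions.get(rep, "fronds"))
        for (pos0, strand), counts in cols.items():
            for base, n in counts.items():
                by[strand][getattr(dna, base), pos0] = n
    return pileup


C_POS = 4  # GENOME[4] == 'C'


class TestCandidates:
    def test_below_coverage_rejected(self):
        pileup = _pileup({"f1": {(C_POS, "+"): {"C": 4, "T": 5}}})  # depth 9
        result = call_candidates(pileup, GENOME)
        assert result.candidates == []

    def test_fig4_like_counts_accepted(self):
        pileup = _pileup({"f1": {(C_POS, "+"): {"C": 31, "T": 2}}})
        result = call_candidates(pileup, GENOME)
        assert len(result.candidates) == 1
        c = result.candidates[0]
        assert c.genome_position == C_POS + 1
        assert c.per_replicate["f1"] == (2, 33)

    def test_single_edited_read_rejected(self):
        pileup = _pileup({"f1": {(C_POS, "+"): {"C": 32, "T": 1}}})
        assert call_candidates(pileup, GENOME).candidates == []

    def test_non_c_reference_never_editing(self):
        # position 0 is A on the forward strand; A->G mismatches are not editing
        pileup = _pileup({"f1": {(0, "+"): {"A": 20, "G": 5}}})
        result = call_candidates(pileup, GENOME)
        assert result.candidates == []
        assert any(v.ref_base == "A" and v.alt_base == "G" for v in result.non_canonical)

    def test_minus_strand_site(self):
        g_pos = 2  # GENOME[2] == 'G'; transcribed '-' base is C
        pileup = _pileup({"f1": {(g_pos, "-"): {"C": 20, "T": 10}}})
        result = call_candidates(pileup, GENOME)
        assert [c.strand for c in result.candidates] == ["-"]

    def test_genic_positions_restricted_to_transcript_strand(self):
        from plastedit.genes import GeneModel

        gene = GeneModel(name="g", strand="-", exons=[(1, 60)], cds=[(4, 57)])
        pileup = _pileup({"f1": {(C_POS, "+"): {"C": 20, "T": 10}}})
        result = call_candidates(pileup, GENOME, [gene])
        assert result.candidates == []  # '+' evidence inside a '-' gene is ignored

    @given(
        min_cov=st.integers(1, 30),
        min_edited=st.integers(1, 8),
        extra_cov=st.integers(0, 10),
        extra_edited=st.integers(0, 4),
    )
    def test_filter_monotonicity(self, min_cov, min_edited, extra_cov, extra_edited):
        rng = np.random.default_rng(min_cov * 100 + min_edited)
        spec = {}
        for rep in ("f1", "f2"):
            cols = {}
            for pos0 in (1, 4, 6, 9, 11):
                depth = int(rng.integers(0, 40))
                t = int(rng.integers(0, depth + 1))
                cols[(pos0, "+")] = {"C": depth - t, "T": t}
            spec[rep] = cols
        pileup = _pileup(spec)
        loose = call_candidates(pileup, GENOME, min_coverage=min_cov, min_edited_reads=min_edited)
        tight = call_candidates(
            pileup, GENOME,
            min_coverage=min_cov + extra_cov,
            min_edited_reads=min_edited + extra_edited,
        )
        n_loose = sum(len(c.candidate_replicates) for c in loose.candidates)
        n_tight = sum(len(c.candidate_replicates) for c in tight.candidates)
        assert n_tight <= n_loose
        assert len(apply_replicate_filter(tight.candidates, 2)) <= len(
            apply_replicate_filter(loose.candidates, 2)
        )


class TestReplicateFilter:
    def _candidates(self, n_supporting):
        spec = {}
        conditions = {}
        for i in range(8):
            rep = f"r{i}"
            conditions[rep] = "fronds" if i < 4 else "turions"
            t = 5 if i < n_supporting else 0
            spec[rep] = {(C_POS, "+"): {"C": 30 - t, "T": t}}
        return call_candidates(_pileup(spec, conditions), GENOME).candidates

    def test_single_replicate_dropped(self):
        assert apply_replicate_filter(self._candidates(1), 2) == []

    def test_two_replicates_kept(self):
        calls = apply_replicate_filter(self._candidates(2), 2)
        assert len(calls) == 1 and calls[0].replicate_support == 2

    def test_min_one_is_pass_through(self):
        candidates = self._candidates(1)
        assert len(apply_replicate_filter(candidates, 1)) == len(candidates)

    def test_pooling_consistency(self):
        calls = apply_replicate_filter(self._candidates(3), 2)
        c = calls[0]
        edited, total = c.pooled()
        assert edited == sum(e for e, _ in c.per_replicate.values())
        assert total == sum(t for _, t in c.per_replicate.values())
        per_rep_effs = [
            100 * e / t for e, t in c.per_replicate.values() if t > 0
        ]
        pooled_eff = 100 * edited / total
        assert min(per_rep_effs) <= pooled_eff <= max(per_rep_effs)

    def test_within_condition_support_flag(self):
        # two supporting replicates but in different conditions
        spec, conditions = {}, {}
        for i, rep in enumerate(("f1", "f2", "t1", "t2")):
            conditions[rep] = "fronds" if rep.startswith("f") else "turions"
            t = 5 if rep in ("f1", "t1") else 0
            spec[rep] = {(C_POS, "+"): {"C": 30 - t, "T": t}}
        candidates = call_candidates(_pileup(spec, conditions), GENOME).candidates
        assert len(apply_replicate_filter(candidates, 2, within_condition=False)) == 1
        assert apply_replicate_filter(candidates, 2, within_condition=True) == []


class TestEfficiency:
    @pytest.mark.parametrize(
        "edited,total,pct,rounded",
        [
            (2, 33, 6.0606, 6),
            (18, 33, 54.5454, 55),
            (0, 50, 0.0, 0),
            (50, 50, 100.0, 100),
        ],
    )
    def test_values(self, edited, total, pct, rounded):
        eff = compute_efficiency(edited, total)
        assert eff == pytest.approx(pct, abs=1e-3)
        assert round_percent(eff) == rounded

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_efficiency(0, 0)

    def test_edited_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            compute_efficiency(10, 5)

    def test_half_up_rounding(self):
        assert round_percent(54.5) == 55
        assert round_percent(54.4999) == 54


class TestRecovery:
    def test_exact_match(self):
        spec = {
            "f1": {(C_POS, "+"): {"C": 20, "T": 10}},
            "f2": {(C_POS, "+"): {"C": 20, "T": 10}},
        }
        calls = apply_replicate_filter(call_candidates(_pileup(spec), GENOME).candidates, 2)
        truth = [GroundTruthSite(C_POS + 1, "+", 0.33, 0.33)]
        report = recover_sites(calls, truth)
        assert report.sensitivity == 1.0 and report.fdr == 0.0

    def test_false_positive_and_negative(self):
        spec = {
            "f1": {(C_POS, "+"): {"C": 20, "T": 10}},
            "f2": {(C_POS, "+"): {"C": 20, "T": 10}},
        }
        calls = apply_replicate_filter(call_candidates(_pileup(spec), GENOME).candidates, 2)
        truth = [GroundTruthSite(7, "+", 0.5, 0.5)]  # GENOME[6] == 'C', never called
        report = recover_sites(calls, truth)
        assert report.false_positives == [(C_POS + 1, "+")]
        assert report.false_negatives == [(7, "+")]

    def test_zero_efficiency_site_never_called(self, small_plastome):
        """A site with efficiency 0 yields no call across seeds: sequencing
        errors alone do not pass the edited-read and replicate filters."""
        from plastedit.ingest import build_pileup, place_reads, qc_filter
        from plastedit.simulate import SimulationConfig, implant_editing_sites, simulate_reads

        genome, genes = small_plastome
        site = implant_editing_sites(genome, genes, 1, [(0.0, 0.0)], seed=6)[0]
        called = 0
        for seed in range(10):
            cfg = SimulationConfig(
                genome_length=4000, gene_count=4, intron_fraction=0.5,
                mean_coverage=200.0, error_rate=0.001, seed=3000 + seed,
            )
            alns = []
            for r, rep in ((0, "f1"), (1, "f2")):
                reads = simulate_reads(genome, [site], "fronds", rep, cfg, replicate_index=r)
                kept, _ = qc_filter(reads)
                a, _ = place_reads(kept, genome)
                alns.extend(a)
            pileup = build_pileup(alns, genome)
            calls = apply_replicate_filter(
                call_candidates(pileup, genome, genes).candidates, 2
            )
            called += any(
                c.genome_position == site.genome_position for c in calls
            )
        assert called == 0
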