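"""Ancestral consensus, periodicity detection and motif reduction."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

import ferredup as fd
from ferredup.ancestral import AncestralConsensus, Provenance


def _aln(h1: str, h2: str) -> fd.HalfAlignment:
    split = fd.HalfSplit(parent_id="t", split_index=len(h1), half1=h1, half2=h2)
    return fd.align_halves(split, mode="ungapped-offset")


class TestReconstructAncestor:
    def test_identical_halves_all_shared(self):
        cons = fd.reconstruct_ancestor(_aln("ACDG", "ACDG"))
        assert cons.residues == "ACDG"
        assert all(p == Provenance.SHARED for p in cons.provenance)

    def test_disagreeing_halves_undetermined(self):
        cons = fd.reconstruct_ancestor(_aln("AC", "GD"))
        assert cons.residues == "--"
        assert all(p == Provenance.UNDETERMINED for p in cons.provenance)

    def test_rescue_fires_from_either_half(self):
        cons = fd.reconstruct_ancestor(_aln("SA", "AS"), rescue_set={"S"})
        assert cons.residues == "SS"
        assert all(p == Provenance.RESCUE for p in cons.provenance)

    def test_worked_example_consensus(self, fd_consensus):
        """The ferredoxin half alignment yields a 27-position consensus whose
        shared positions use 7 distinct amino-acid types."""
        assert len(fd_consensus) == 27
        assert fd_consensus.shared_letter_count == 7
        assert fd_consensus.residues == "----ADSC-SCG-CAS-CPV-A-SQ--"

    @given(s=st.text(alphabet="ACDGSV", min_size=4, max_size=20))
    def test_symmetric_in_halves(self, s):
        h1, h2 = s[: len(s) // 2], s[len(s) // 2 : 2 * (len(s) // 2)]
        a = fd.reconstruct_ancestor(_aln(h1, h2))
        b = fd.reconstruct_ancestor(_aln(h2, h1))
        assert a.residues == b.residues

    def test_unknowns_never_enter_consensus(self):
        cons = fd.reconstruct_ancestor(_aln("XA", "XA"))
        assert cons.residues == "-A"


class TestPeriodicity:
    def test_clean_period_three(self):
        cons = AncestralConsensus.from_string("CAACAACAA")
        (p,) = [x for x in fd.detect_periodicity(cons) if x.residue == "C"]
        assert p.period == 3 and p.phase == 1 and p.break_positions == ()

    def test_worked_example_cysteine_cycle_and_break(self, fd_consensus):
        """Cysteines recur in cycles of three, interrupted just past the
        consensus midpoint (position 15)."""
        byres = {p.residue: p for p in fd.detect_periodicity(fd_consensus)}
        assert byres["C"].period == 3
        assert byres["C"].break_positions == (15,)
        assert byres["C"].supporting_positions == (8, 11, 14, 18)

    def test_min_support_skips_rare_letters(self):
        cons = AncestralConsensus.from_string("CAC")
        assert fd.detect_periodicity(cons) == []
        with pytest.raises(ValueError):
            fd.detect_periodicity(cons, min_support=2)

    @given(s=st.text(alphabet="CA", min_size=6, max_size=15))
    def test_period_matches_bruteforce(self, s):
        """The reported period equals an exhaustive scan over periods 2..L/2
        for the longest equal-spacing run of occurrences."""
        cons = AncestralConsensus.from_string(s)
        results = {p.residue: p for p in fd.detect_periodicity(cons)}
        for residue in "CA":
            occ = [i + 1 for i, r in enumerate(s) if r == residue]
            if len(occ) < 3:
                assert residue not in results
                continue
            best_p, best_len = None, 1
            for period in range(2, max(2, len(s) // 2) + 1):
                run = longest = 1
                for a, b in zip(occ, occ[1:]):
                    run = run + 1 if b - a == period else 1
                    longest = max(longest, run)
                if longest > best_len:
                    best_p, best_len = period, longest
            if best_p is None:
                assert residue not in results
            else:
                assert results[residue].period == best_p

    def test_segments_split_at_breaks(self, fd_consensus):
        byres = {p.residue: p for p in fd.detect_periodicity(fd_consensus)}
        assert byres["C"].segments() == ((8, 11, 14), (18,))


class TestMotifReduction:
    def test_perfect_repeat_all_conforming(self):
        cons = AncestralConsensus.from_string("ADSGADSG")
        red = fd.reduce_to_motif(cons, "ADSG", frame=1)
        assert len(red.conforming_positions) == 8
        assert red.nonconforming_positions == ()

    def test_partition_is_exhaustive(self, fd_consensus):
        red = fd.reduce_to_motif(fd_consensus, "ADSG", frame=1)
        det = set(fd_consensus.determined_positions)
        assert set(red.conforming_positions) | set(red.nonconforming_positions) == det
        assert not set(red.conforming_positions) & set(red.nonconforming_positions)

    @given(
        s=st.text(alphabet="ADSGC-", min_size=2, max_size=10),
        motif=st.text(alphabet="ADSG", min_size=1, max_size=3),
        frame=st.integers(min_value=1, max_value=3),
    )
    def test_matches_positionwise_bruteforce(self, s, motif, frame):
        cons = AncestralConsensus.from_string(s)
        red = fd.reduce_to_motif(cons, motif, frame)
        for i in cons.determined_positions:
            expected = s[i - 1] == motif[(i - frame) % len(motif)]
            assert (i in red.conforming_positions) == expected

    def test_empty_motif_rejected(self, fd_consensus):
        with pytest.raises(ValueError):
            fd.reduce_to_motif(fd_consensus, "")


class TestInferMotif:
    def test_pure_repeat_recovered(self):
        cons = AncestralConsensus.from_string("ADSGADSGADSG")
        red = fd.infer_motif(cons, k=4)
        assert red.motif == "ADSG"
        assert len(red.conforming_positions) == 12

    def test_all_undetermined_rejected(self):
        with pytest.raises(ValueError):
            fd.infer_motif(AncestralConsensus.from_string("----"), k=2)

    @given(s=st.text(alphabet="AD-", min_size=2, max_size=8))
    def test_matches_exhaustive_motif_search_k2(self, s):
        """The modal construction attains the same best conforming count as
        scoring every 2-letter motif over every frame."""
        cons = AncestralConsensus.from_string(s)
        if not cons.determined_positions or len(s) < 2:
            return
        red = fd.infer_motif(cons, k=2)
        best = 0
        for motif in map("".join, itertools.product("ACDEFGHIKLMNPQRSTVWY", repeat=2)):
            for frame in (1, 2):
                n = len(fd.reduce_to_motif(cons, motif, frame).conforming_positions)
                best = max(best, n)
        assert len(red.conforming_positions) == best


class TestSyntheticRecovery:
    def test_zero_substitution_recovers_ancestor_exactly(self):
        config = fd.SimulationConfig(half_length=40, substitution_probability=0.0, n_replicates=5, seed=8)
        for fam in fd.simulate_family(config):
            split = fd.split_halves(fam.record)
            cons = fd.reconstruct_ancestor(fd.align_halves(split, mode="ungapped-offset"))
            assert cons.residues == fam.true_ancestor_half

    def test_shared_accuracy_degrades_with_mu(self):
        """The fraction of SHARED positions matching the true ancestor can
        only degrade as the per-site substitution probability grows."""
        fractions = []
        for mu in (0.05, 0.15, 0.3):
            config = fd.SimulationConfig(
                half_length=80, substitution_probability=mu, n_replicates=60, seed=21
            )
            good = total = 0
            for fam in fd.simulate_family(config):
                split = fd.split_halves(fam.record)
                cons = fd.reconstruct_ancestor(fd.align_halves(split, mode="ungapped-offset"))
                for i, (r, p) in enumerate(zip(cons.residues, cons.provenance)):
                    if p == Provenance.SHARED:
                        total += 1
                        good += r == fam.true_ancestor_half[i]
            fractions.append(good / total)
        assert fractions[0] >= fractions[1] >= fractions[2]
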