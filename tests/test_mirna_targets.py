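"""Conserved-miRNA filter, nucleus matching and the nearest-neighbor duplex
energy model."""

import numpy as np
import pytest

from orthoscreen.errors import ConfigError, InputError
from orthoscreen.mirna_targets import (DEFAULT_ENERGY_CUTOFF, NucleusSite,
                                       TargetConfig, duplex_energy,
                                       filter_conserved, nucleus_match,
                                       predict_targets)
from orthoscreen.seqio import MiRnaRecord
from orthoscreen.synthetic_data import build_site_window
from orthoscreen.utr_inference import UtrCall
from tests.oracles import duplex_dg_oracle, load_raw_nn_table

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
SPECIES = ["human", "chimpanzee", "mouse", "rat", "dog", "cat", "horse",
           "cow", "panda"]


def copies(family, seq, n, mutate=()):
    out = []
    for i, sp in enumerate(SPECIES[:n]):
        s = seq
        if sp in mutate:
            s = ("G" if s[0] != "G" else "C") + s[1:]
        out.append(MiRnaRecord(family, sp, s))
    return out


def _utr_call(seq, gene="COMT"):
    return UtrCall(gene_symbol=gene, species="panda", utr_seq=seq,
                   utr_length=len(seq), pas_motif="AATAAA",
                   pas_start=max(1, len(seq) - 24), cleavage_offset=19)


class TestFilterConserved:
    SEQ = "UGAGGUAGUAGGUUGUAUAGUU"

    def test_six_identical_species_kept(self):
        fams = filter_conserved(copies("let-7", self.SEQ, 6))
        assert len(fams) == 1
        assert fams[0].consensus_seq == self.SEQ
        assert fams[0].max_mismatch_observed == 0

    def test_five_species_dropped(self):
        assert filter_conserved(copies("let-7", self.SEQ, 5)) == []

    def test_two_mismatches_in_one_copy_dropped(self):
        recs = copies("let-7", self.SEQ, 7)
        bad = self.SEQ
        bad = "C" + bad[1:10] + "C" + bad[11:]  # 2 substitutions
        recs[3] = MiRnaRecord("let-7", recs[3].species, bad)
        assert filter_conserved(recs) == []

    def test_one_mismatch_per_copy_allowed(self):
        recs = copies("let-7", self.SEQ, 7, mutate={"mouse", "rat"})
        fams = filter_conserved(recs)
        assert len(fams) == 1 and fams[0].max_mismatch_observed == 1

    def test_unequal_lengths_drop_family(self):
        recs = copies("let-7", self.SEQ, 6)
        recs[0] = MiRnaRecord("let-7", "human", self.SEQ[:-1])
        assert filter_conserved(recs) == []

    def test_consensus_tie_breaks_to_reference_base(self):
        # 3 copies A, 3 copies G at position 0; human holds G
        recs = []
        for i, sp in enumerate(SPECIES[:6]):
            base = "G" if sp == "human" or i >= 4 else "A"
            recs.append(MiRnaRecord("m", sp, base + self.SEQ[1:]))
        fams = filter_conserved(recs, max_mismatch=1)
        assert fams and fams[0].consensus_seq[0] == "G"

    def test_monotone_in_species_and_threshold(self):
        recs = copies("let-7", self.SEQ, 6)
        kept = filter_conserved(recs)
        more = recs + [MiRnaRecord("let-7", "horse", self.SEQ)]
        assert len(filter_conserved(more)) >= len(kept)
        assert filter_conserved(recs, min_species=7) == []

    def test_reference_mode_exposed(self):
        recs = copies("let-7", self.SEQ, 6)
        assert filter_conserved(recs, mode="reference")
        with pytest.raises(ConfigError):
            filter_conserved(recs, mode="bogus")


class TestNucleusMatch:
    MIR = "UGAGGUAGUAGGUUGUAUAGUU"

    def _target(self, a, b):
        """UTR 5'->3' complement of miRNA positions a..b, non-pairing
        flanks."""
        core = "".join(COMP[c] for c in self.MIR[a - 1:b])[::-1]
        return core

    def test_perfect_7mer_site(self):
        # the miRNA has no C, so G flanks can never Watson-Crick pair and
        # cannot extend the planted run (G:U wobble is excluded in nucleus)
        flank = "GGGGGGGGGG"
        utr = flank + self._target(2, 8) + flank
        sites = nucleus_match(self.MIR, utr, seed_min=7)
        assert sites == [NucleusSite(len(flank) + 1, 7, 2)]

    def test_six_mer_rejected_at_seed_seven(self):
        flank = "GGGGGGGGGG"
        utr = flank + self._target(2, 7) + flank
        assert nucleus_match(self.MIR, utr, seed_min=7) == []
        assert nucleus_match(self.MIR, utr, seed_min=6) != []

    def test_eight_mer_reported_once_maximal(self):
        flank = "GGGGGGGGGG"
        utr = flank + self._target(1, 8) + flank
        sites = nucleus_match(self.MIR, utr, seed_min=7)
        assert sites == [NucleusSite(len(flank) + 1, 8, 1)]

    def test_seed_min_validation(self):
        with pytest.raises(ConfigError):
            nucleus_match(self.MIR, "ACGU", seed_min=0)

    def test_gu_not_counted_in_nucleus(self):
        # complement of positions 2..8 but with one pair turned into G:U
        core = list(self._target(2, 8))
        # miRNA position 5 is G; its partner sits at core index 8-5=3;
        # C -> U turns the Watson-Crick pair into G:U inside the nucleus
        assert self.MIR[4] == "G" and core[3] == "C"
        core[3] = "U"
        utr = "CCCCCCCCCC" + "".join(core) + "CCCCCCCCCC"
        assert nucleus_match(self.MIR, utr, seed_min=7) == []


class TestDuplexEnergy:
    def test_fully_mismatched_window(self, nn_params):
        m = "G" * 22
        utr = "A" * 22  # G:A never pairs
        site = NucleusSite(utr_start=22 - 7 + 1, nucleus_len=7,
                           mirna_start=1)
        dg = duplex_energy(m, utr, site, nn_params)
        assert dg == pytest.approx(
            nn_params.init_energy + 21 * nn_params.mismatch_penalty)

    def test_gc_duplex_equals_hand_sum(self, nn_params):
        m = "GCGCGCGC"
        utr = "".join(COMP[c] for c in m)[::-1]
        site = NucleusSite(utr_start=1, nucleus_len=8, mirna_start=1)
        dg = duplex_energy(m, utr, site, nn_params)
        stacks, init, _, _ = load_raw_nn_table()
        expected = init + 4 * stacks["GC/CG"] + 3 * stacks["CG/GC"]
        assert dg == pytest.approx(expected)

    def test_central_mismatch_destabilizes(self, nn_params):
        m = "UGAGGUAGUAGGUUGUAUAGUU"
        perfect = "".join(COMP[c] for c in m)[::-1]
        damaged = list(perfect)
        damaged[11] = "A" if perfect[11] != "A" else "C"
        site = NucleusSite(utr_start=len(m) - 9 + 1, nucleus_len=9,
                           mirna_start=1)
        dg_perfect = duplex_energy(m, perfect, site, nn_params)
        dg_damaged = duplex_energy(m, "".join(damaged), site, nn_params)
        assert dg_perfect < dg_damaged

    def test_window_out_of_bounds_rejected(self, nn_params):
        m = "UGAGGUAGUAGGUUGUAUAGUU"
        site = NucleusSite(utr_start=1, nucleus_len=7, mirna_start=2)
        with pytest.raises(InputError):
            duplex_energy(m, "ACGUACGU", site, nn_params)

    def test_oracle_equivalence_randomized(self, nn_params, rng):
        """dG equals an independent run-enumeration summation, including
        windows with short paired patches and wobble pairs."""
        bases = list("ACGU")
        for _ in range(100):
            L = int(rng.integers(4, 11))
            m = "".join(rng.choice(bases, size=L))
            window = "".join(rng.choice(bases, size=L))
            nuc = min(7, L)
            site = NucleusSite(utr_start=L - nuc + 1, nucleus_len=nuc,
                               mirna_start=1)
            got = duplex_energy(m, window, site, nn_params)
            assert got == pytest.approx(duplex_dg_oracle(m, window)), (
                m, window)


class TestPredictTargets:
    MIR = "UGAGGUAGUAGGUUGUAUAGUU"

    def _families(self):
        return filter_conserved(copies("let-7", self.MIR, 9))

    def _planted_utr(self, band, nucleus_len=7, rng_seed=1, n=600):
        rng = np.random.default_rng(rng_seed)
        params = TargetConfig().params
        window, dg = build_site_window(self.MIR, nucleus_len, band, params)
        while True:
            utr = "".join(rng.choice(list("ACGT"), size=n))
            if "AATAAA" not in utr and "ATTAAA" not in utr:
                break
        p = 200
        utr = utr[:p] + window + utr[p + len(window):]
        expected_start = p + len(window) - nucleus_len + 1
        return utr, expected_start, dg

    def test_planted_passing_site_recovered(self):
        utr, start, dg = self._planted_utr((-35.0, -25.0))
        sites = predict_targets([_utr_call(utr)], self._families())
        assert [(s.gene_symbol, s.family, s.utr_start)
                for s in sites] == [("COMT", "let-7", start)]
        assert sites[0].duplex_dg == pytest.approx(dg)
        assert sites[0].passes_energy

    def test_site_above_cutoff_rejected(self):
        utr, _, dg = self._planted_utr((-15.0, -10.0))
        assert dg > DEFAULT_ENERGY_CUTOFF
        assert predict_targets([_utr_call(utr)], self._families()) == []

    def test_cutoff_boundary_is_inclusive(self):
        utr, start, dg = self._planted_utr((-35.0, -25.0))
        at = predict_targets([_utr_call(utr)], self._families(),
                             TargetConfig(energy_cutoff=dg))
        below = predict_targets([_utr_call(utr)], self._families(),
                                TargetConfig(energy_cutoff=dg - 0.01))
        assert [s.utr_start for s in at] == [start]
        assert below == []

    def test_empty_family_list(self):
        utr, _, _ = self._planted_utr((-35.0, -25.0))
        assert predict_targets([_utr_call(utr)], []) == []

    def test_output_invariant_to_input_order(self):
        utr1, _, _ = self._planted_utr((-35.0, -25.0), rng_seed=2)
        utr2, _, _ = self._planted_utr((-35.0, -25.0), rng_seed=3)
        calls = [_utr_call(utr1, "GB"), _utr_call(utr2, "GA")]
        fams = self._families()
        a = predict_targets(calls, fams)
        b = predict_targets(calls[::-1], fams[::-1])
        assert a == b
        assert [s.gene_symbol for s in a] == sorted(s.gene_symbol
                                                    for s in a)
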