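"""Initiation-context extraction, classification and cross-species
comparison."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoscreen.benchmarks import load_kozak_benchmark, window_from_flags
from orthoscreen.errors import InputError
from orthoscreen.kozak import (IDX_MINUS3, IDX_PLUS1, IDX_PLUS4, WINDOW_LEN,
                               KozakContext, classify, compare_strength,
                               extract_context, position_index, screen_kozak)
from orthoscreen.synthetic_data import SimulationConfig, make_panel
from tests.conftest import make_record


def ctx(window: str, valid: bool = True) -> KozakContext:
    return KozakContext("G", "panda", window, valid=valid)


class TestPositionArithmetic:
    def test_no_position_zero(self):
        with pytest.raises(InputError):
            position_index(0)

    def test_minus_one_abuts_plus_one(self):
        assert position_index(-1) + 1 == position_index(1)
        assert position_index(1) == IDX_PLUS1 == 25
        assert position_index(-3) == IDX_MINUS3 == 22
        assert position_index(4) == IDX_PLUS4 == 28


class TestExtractContext:
    def test_plus_strand_window_is_bases_1_to_30(self):
        oriented = "ACGTA" * 6 + "ATGCCCTAA" + "G" * 5
        rec = make_record(oriented, cds_start=26, cds_end=34)
        c = extract_context(rec)
        assert c.valid and c.window == oriented[:30]

    def test_insufficient_upstream_flagged_not_error(self):
        oriented = "A" * 9 + "ATGTAA" + "C" * 40
        rec = make_record(oriented, cds_start=10, cds_end=15)
        c = extract_context(rec)
        assert not c.valid and c.reason == "insufficient_upstream"

    def test_minus_strand_window_from_reverse_complement(self):
        # hand-built 60-nt locus: reading strand has ATG at oriented pos 26
        oriented = "C" * 22 + "A" + "CC" + "ATG" + "GA" + "T" * 30
        assert len(oriented) == 60
        rec = make_record(oriented, cds_start=26, cds_end=40, strand="-")
        c = extract_context(rec)
        assert c.valid
        assert c.window == oriented[:30]
        call = classify(c)
        assert call.has_aug and call.minus3_r and call.plus4_g
        assert call.strength == "S"


class TestClassify:
    def test_exhaustive_truth_table(self):
        for minus3, plus4 in itertools.product([True, False], repeat=2):
            call = classify(ctx(window_from_flags(True, plus4, minus3)))
            expected = {(True, True): "S", (True, False): "A",
                        (False, True): "A", (False, False): "W"}[
                            (minus3, plus4)]
            assert call.strength == expected
            assert call.pattern == (minus3, plus4)

    def test_no_aug_excluded(self):
        call = classify(ctx(window_from_flags(False, True, True)))
        assert not call.has_aug and call.strength == "EXCLUDED"

    def test_invalid_context_excluded(self):
        call = classify(ctx("", valid=False))
        assert call.strength == "EXCLUDED"

    def test_softmask_uppercased_hardmask_nonmatch(self):
        w = window_from_flags(True, True, True).lower()
        assert classify(ctx(w)).strength == "S"
        w2 = list(window_from_flags(True, True, True))
        w2[IDX_MINUS3] = "N"
        assert classify(ctx("".join(w2))).strength == "A"
        w2[IDX_PLUS4] = "N"
        assert classify(ctx("".join(w2))).strength == "W"

    @settings(derandomize=True, max_examples=150)
    @given(st.lists(st.sampled_from("ACGTN"), min_size=WINDOW_LEN,
                    max_size=WINDOW_LEN))
    def test_only_criterion_positions_matter(self, bases):
        """Replacing every non-criterion position never changes the call."""
        base = window_from_flags(True, True, False)
        mutated = list(bases)
        for idx in (IDX_MINUS3, IDX_PLUS1, IDX_PLUS1 + 1, IDX_PLUS1 + 2,
                    IDX_PLUS4):
            mutated[idx] = base[idx]
        assert classify(ctx("".join(mutated))).strength == \
            classify(ctx(base)).strength

    def test_published_flag_rows_reproduced(self):
        df = load_kozak_benchmark()
        for _, row in df.iterrows():
            call = classify(ctx(window_from_flags(
                row.atg == "y", row.g_plus4 == "y", row.r_minus3 == "y")))
            assert call.strength == row.strength, row.gene_symbol


class TestCompareStrength:
    @pytest.mark.parametrize("q,r,expected", [
        ("W", "A", "weaker"), ("S", "S", "same"), ("S", "A", "stronger"),
        ("W", "S", "weaker"), ("A", "W", "stronger"),
    ])
    def test_ordering(self, q, r, expected):
        flags = {"S": (True, True), "A": (True, False), "W": (False, False)}
        qc = classify(ctx(window_from_flags(True, flags[q][1], flags[q][0])))
        rc = classify(ctx(window_from_flags(True, flags[r][1], flags[r][0])))
        assert qc.strength == q and rc.strength == r
        assert compare_strength(qc, rc) == expected

    def test_antisymmetric(self):
        flags = {"S": (True, True), "A": (False, True), "W": (False, False)}
        opposite = {"weaker": "stronger", "stronger": "weaker",
                    "same": "same"}
        calls = {s: classify(ctx(window_from_flags(True, g, r)))
                 for s, (r, g) in flags.items()}
        for a in calls.values():
            for b in calls.values():
                assert compare_strength(a, b) == \
                    opposite[compare_strength(b, a)]

    def test_excluded_input_rejected(self):
        good = classify(ctx(window_from_flags(True, True, True)))
        bad = classify(ctx(window_from_flags(False, True, True)))
        with pytest.raises(InputError):
            compare_strength(bad, good)


class TestScreenKozak:
    def test_planted_strength_pairs_recovered(self):
        plan = {}
        genes = [f"G{i:03d}" for i in range(1, 11)]
        for g in genes[:4]:
            plan[(g, "panda")] = "W"          # weaker than default strong
        for g in genes[4:7]:
            plan[(g, "panda")] = "A"          # weaker, pattern differs
        # remaining genes keep the default identical pattern
        config = SimulationConfig(rng_seed=17, n_genes=10,
                                  protein_length=60, kozak_plan=plan)
        panel, _ = make_panel(config)
        result = screen_kozak(panel, "panda")
        assert sorted(result.differing) == sorted(genes[:7])
        assert sorted(result.weaker) == sorted(genes[:7])
        assert sorted(result.same_pattern) == sorted(genes[7:])
        assert result.excluded == {}

    def test_identical_panel_zero_differing(self):
        config = SimulationConfig(rng_seed=23, n_genes=5, protein_length=60)
        panel, _ = make_panel(config)
        result = screen_kozak(panel, "panda")
        assert result.differing == []
        assert len(result.same_pattern) == 5

    def test_no_aug_genes_excluded_first(self):
        config = SimulationConfig(
            rng_seed=29, n_genes=3, protein_length=60,
            kozak_plan={("G002", "panda"): "no-AUG"})
        panel, _ = make_panel(config)
        result = screen_kozak(panel, "panda")
        assert result.excluded == {"G002": "no_aug_start"}
        assert "G002" not in result.differing + result.same_pattern

    def test_missing_ortholog_reason_coded(self):
        config = SimulationConfig(rng_seed=31, n_genes=2, protein_length=60)
        panel, _ = make_panel(config)
        del panel.genes["G001"]["panda"]
        result = screen_kozak(panel, "panda")
        assert result.excluded["G001"] == "missing_query_ortholog"
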