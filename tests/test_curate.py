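import numpy as np
import pytest

from venomminer.curate import (FILTER_RULES, assign_names, filter3,
                               has_long_repeat, merge_methods,
                               read_candidates, venn_counts,
                               write_candidates)
from venomminer.frameworks import FrameworkRegistry, load_registry
from venomminer.seqio import ProtRecord

SIGNAL = "MKR" + "LVLFLILVLF" + "AEA"  # passes the n/h/c rules, cleavage at 16
GOOD_MATURE = "CDAFGHIKWCDEFGNIKWCDEFGHIKWCDEFGHIKWDEHW"  # 40 aa, benign
GOOD = SIGNAL + GOOD_MATURE  # 56 aa precursor


class TestHasLongRepeat:
    def test_single_residue_run(self):
        assert has_long_repeat("WDAAAAAAWD")       # run of 6
        assert not has_long_repeat("WDAAAAAWD")    # run of 5 allowed

    def test_tandem_unit_repeat(self):
        assert has_long_repeat("W" + "AG" * 6 + "W")     # unit of 2, 6 times
        assert not has_long_repeat("W" + "AG" * 5 + "W")

    def test_clean_sequence(self):
        assert not has_long_repeat(GOOD)


class TestFilter3:
    def test_accepts_valid_precursor(self):
        (cand,) = filter3([ProtRecord("ok", GOOD)])
        assert cand.passed and cand.primary_flag is None

    def test_short_precursor_flagged(self):
        seq = SIGNAL + GOOD_MATURE[:33]  # 49 aa
        (cand,) = filter3([ProtRecord("short", seq)])
        assert not cand.passed and cand.primary_flag == "short"

    def test_early_stop_flagged(self):
        seq = GOOD[:30] + "*" + GOOD[31:]
        (cand,) = filter3([ProtRecord("stop", seq)])
        assert not cand.passed and cand.primary_flag == "early_stop"

    def test_terminal_stop_is_not_early(self):
        (cand,) = filter3([ProtRecord("ok", GOOD + "*")])
        assert not cand.flags["early_stop"]

    def test_repeat_flagged(self):
        seq = SIGNAL + GOOD_MATURE[:20] + "AAAAAA" + GOOD_MATURE[20:34]
        (cand,) = filter3([ProtRecord("rep", seq)])
        assert not cand.passed and cand.primary_flag == "repeat"

    def test_missing_signal_flagged(self):
        seq = "MDENQHDENWHQDENW" + GOOD_MATURE
        (cand,) = filter3([ProtRecord("nosig", seq)])
        assert not cand.passed and cand.primary_flag == "no_signal"

    def test_first_failing_rule_is_primary(self):
        # short AND repeat AND no signal: rule order 1-4 decides
        seq = "MDDDD" + "AAAAAA" * 3 + "DDDDDDDDDDD"
        (cand,) = filter3([ProtRecord("multi", seq)])
        assert cand.primary_flag == "short"

    def test_output_subset_of_input(self, rng):
        from conftest import random_protein

        prots = [
            ProtRecord(f"p{i}", "M" + random_protein(rng, 70))
            for i in range(30)
        ]
        cands = filter3(prots)
        assert len(cands) == len(prots)
        assert {c.id for c in cands} == {p.id for p in prots}
        for c in cands:
            assert c.passed == (not any(c.flags.values()))
            assert set(c.flags) == set(FILTER_RULES)


class TestMergeAndVenn:
    def test_same_mature_merges_methods(self):
        a = filter3([ProtRecord("a", GOOD)], method=1)
        b = filter3([ProtRecord("b", GOOD)], method=3)
        merged = merge_methods({1: a, 3: b})
        assert len(merged) == 1
        assert merged[0].methods == {1, 3}

    def test_disjoint_sets_venn(self):
        seqs = [GOOD, SIGNAL + "W" + GOOD_MATURE, SIGNAL + "HH" + GOOD_MATURE]
        per_method = {
            m: filter3([ProtRecord(f"p{m}", seqs[m - 1])], method=m)
            for m in (1, 2, 3)
        }
        merged = merge_methods(per_method)
        venn = venn_counts(merged)
        assert venn == {"1": 1, "2": 1, "3": 1, "1&2": 0, "1&3": 0,
                        "2&3": 0, "1&2&3": 0}

    def test_venn_regions_sum_to_total(self):
        a = filter3([ProtRecord("a", GOOD)], method=1)
        b = filter3([ProtRecord("b", GOOD)], method=2)
        c = filter3([ProtRecord("c", SIGNAL + "W" + GOOD_MATURE)], method=3)
        merged = merge_methods({1: a, 2: b, 3: c})
        assert sum(venn_counts(merged).values()) == len(merged)

    def test_empty_inputs(self):
        assert merge_methods({}) == []


def _candidate_with_framework(registry, label, cand_id="c1"):
    from venomminer.frameworks import span
    from venomminer.simulate import gen_mature

    rng = np.random.default_rng(8)
    lo, _ = span(registry[label])
    mature = gen_mature(registry[label], lo + 12, rng)
    (cand,) = filter3([ProtRecord(cand_id, SIGNAL + mature)],
                      registry=registry)
    assert cand.passed and cand.framework_label == label
    return cand


class TestAssignNames:
    def test_anmtx_numbering_within_group(self, registry):
        c1 = _candidate_with_framework(registry, "3a", "c1")
        c2 = _candidate_with_framework(registry, "3a", "c2")
        named = assign_names([c1, c2], registry,
                             homology={"c1": 1e-8, "c2": 1e-5})
        assert [n.name for n in named] == ["AnmTX Cj 3a-1", "AnmTX Cj 3a-2"]

    def test_new_framework_becomes_toxin_like(self, registry):
        mature = "CCAAC" + "W" * 30  # novel motif, < 60 aa
        (cand,) = filter3([ProtRecord("c1", SIGNAL + mature)],
                          registry=registry)
        named = assign_names([cand], registry, homology={})
        assert named[0].toxin_class == "CjTL"
        assert named[0].name == "CjTL1"

    def test_weak_homology_excluded_from_anmtx(self, registry):
        cand = _candidate_with_framework(registry, "8a")
        named = assign_names([cand], registry, homology={"c1": 0.5})
        assert named[0].toxin_class == "CjTL"

    def test_long_precursor_is_venom_protein(self, registry):
        seq = SIGNAL + "W" * 200
        (cand,) = filter3([ProtRecord("c1", seq)], registry=registry)
        named = assign_names([cand], registry)
        assert named[0].toxin_class == "CjVP"

    def test_names_unique_and_stable(self, registry):
        cands = [
            _candidate_with_framework(registry, lab, f"c{i}")
            for i, lab in enumerate(["3a", "8a", "3a"])
        ]
        hom = {c.id: 1e-9 for c in cands}
        names1 = [n.name for n in assign_names(cands, registry, hom)]
        names2 = [n.name for n in assign_names(cands, registry, hom)]
        assert names1 == names2
        assert len(set(names1)) == len(names1)


class TestCandidateTable:
    def test_roundtrip(self, tmp_path, registry):
        cands = filter3(
            [ProtRecord("a", GOOD), ProtRecord("b", "M" + "W" * 30)],
            registry=registry, method=3, group_bin="3a",
        )
        path = tmp_path / "cands.tsv"
        write_candidates(cands, path)
        back = read_candidates(path)
        assert len(back) == len(cands)
        for x, y in zip(cands, back):
            assert (x.id, x.methods, x.precursor.seq, x.passed,
                    x.primary_flag) == (
                y.id, y.methods, y.precursor.seq, y.passed, y.primary_flag)
            assert (x.mature.seq if x.mature else None) == (
                y.mature.seq if y.mature else None)

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "cands.tsv"
        write_candidates([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")
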