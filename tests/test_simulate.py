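import numpy as np
import pytest

import venomminer as vm
from venomminer.frameworks import matches, parse_motif, span
from venomminer.orfs import six_frame_orfs
from venomminer.proteomics import tryptic_digest
from venomminer.simulate import (gen_evidence, gen_mature, gen_precursor,
                                 gen_reads, gen_reference_sets,
                                 gen_transcriptome, make_scenario,
                                 read_origin, reverse_translate)
from venomminer.seqio import NucRecord


class TestGenMature:
    def test_exact_motif_forces_cys_positions(self, rng):
        fw = parse_motif("C8C3C11C5CC6")
        mature = gen_mature(fw, 39, rng)
        positions = [i + 1 for i, c in enumerate(mature) if c == "C"]
        assert positions == [1, 10, 14, 26, 32, 33]

    def test_linear(self, rng):
        mature = gen_mature(vm.LINEAR, 30, rng)
        assert len(mature) == 30 and "C" not in mature

    def test_below_min_span_errors(self, rng):
        with pytest.raises(ValueError):
            gen_mature(parse_motif("C8C3C11C5CC6"), 38, rng)

    def test_above_max_span_with_exact_trailing_errors(self, rng):
        with pytest.raises(ValueError):
            gen_mature(parse_motif("C8C3C11C5CC6"), 40, rng)

    def test_unconstrained_tail_absorbs_surplus(self, rng, registry):
        fw = registry["8a"]
        lo, _ = span(fw)
        mature = gen_mature(fw, lo + 15, rng)
        assert len(mature) == lo + 15 and matches(mature, fw)


class TestGenPrecursor:
    def test_mature_matches_declared_framework(self, rng, registry):
        for label in ("1a", "3a", "8a"):
            fw = registry[label]
            lo, _ = span(fw)
            prec = gen_precursor(fw, lo + 12, rng)
            call = vm.score_signal(prec)
            assert call.present
            assert matches(prec.seq[call.cleavage_pos :], fw)


class TestGenTranscriptome:
    def test_decoys_only(self, rng, registry):
        txs, truth = gen_transcriptome(0, 10, rng, registry=registry)
        assert len(txs) == 10 and truth.planted == []
        assert len(truth.decoy_ids) == 10

    def test_planted_orf_recoverable_verbatim(self, rng, registry):
        txs, truth = gen_transcriptome(5, 0, rng, registry=registry)
        for tx, planted in zip(txs, truth.planted):
            orfs = six_frame_orfs(tx, min_len_aa=30)
            assert planted.precursor.seq in {o.aa_seq for o in orfs}

    def test_planted_matures_satisfy_frameworks(self, rng, registry):
        _, truth = gen_transcriptome(8, 0, rng, registry=registry)
        for p in truth.planted:
            assert matches(p.mature_seq, registry[p.framework_label])

    def test_deterministic_under_seed(self, registry):
        a = gen_transcriptome(3, 5, np.random.default_rng(42),
                              registry=registry)
        b = gen_transcriptome(3, 5, np.random.default_rng(42),
                              registry=registry)
        assert [t.seq for t in a[0]] == [t.seq for t in b[0]]


class TestGenReads:
    def test_error_free_reads_are_substrings(self, rng, registry):
        txs, _ = gen_transcriptome(2, 0, rng, registry=registry)
        reads = gen_reads(txs, rng, depth=10, read_len=100, sub_rate=0.0)
        by_id = {t.id: t for t in txs}
        for r in reads:
            tx = by_id[read_origin(r)]
            assert (r.seq in tx.seq
                    or r.reverse_complement().seq in tx.seq)

    def test_read_count_near_poisson_expectation(self, registry):
        rng = np.random.default_rng(11)
        txs, _ = gen_transcriptome(3, 10, rng, registry=registry)
        depth, read_len = 20, 120
        lam = sum(depth * len(t.seq) / min(read_len, len(t.seq)) for t in txs)
        reads = gen_reads(txs, rng, depth=depth, read_len=read_len)
        assert abs(len(reads) - lam) <= 3 * np.sqrt(lam)

    def test_tiny_depth_may_be_empty(self, rng):
        tx = NucRecord("t", "ACGT" * 30)
        reads = gen_reads([tx], rng, depth=0.001, read_len=60)
        assert isinstance(reads, list)

    def test_substitution_rate_observed(self, registry):
        rng = np.random.default_rng(13)
        txs, _ = gen_transcriptome(2, 0, rng, registry=registry)
        reads = gen_reads(txs, rng, depth=30, read_len=150, sub_rate=0.05)
        by_id = {t.id: t for t in txs}
        mismatches = total = 0
        for r in reads[:100]:
            tx = by_id[read_origin(r)]
            pos = int(r.description.split("pos=")[1].split()[0])
            strand = r.description.split("strand=")[1].split()[0]
            frag = r.seq if strand == "+" else r.reverse_complement().seq
            ref = tx.seq[pos : pos + len(frag)]
            mismatches += sum(a != b for a, b in zip(frag, ref))
            total += len(frag)
        assert 0.03 < mismatches / total < 0.07


class TestGenEvidence:
    def test_emitted_peptides_are_valid_tryptic(self, rng, registry):
        _, truth = gen_transcriptome(4, 0, rng, registry=registry)
        gen_evidence(truth, rng, peptides_per_protein=3)
        for p in truth.planted:
            digest = {tp.seq for tp in tryptic_digest(p.precursor,
                                                      cys_fixed_mod=True)}
            for pep in truth.emitted_peptides[p.protein_id]:
                assert pep in digest and len(pep) >= 6

    def test_unvalidatable_gets_at_most_one(self, rng, registry):
        _, truth = gen_transcriptome(4, 0, rng, registry=registry)
        unval = [truth.planted[0].protein_id]
        gen_evidence(truth, rng, peptides_per_protein=3, unvalidatable=unval)
        assert len(truth.emitted_peptides[unval[0]]) <= 1

    def test_zero_noise_masses_exact(self, rng, registry):
        _, truth = gen_transcriptome(2, 0, rng, registry=registry)
        obs = gen_evidence(truth, rng, mass_noise_ppm=0.0)
        for ob in obs:
            assert ob.mono_mass == pytest.approx(
                vm.mono_mass(ob.seq, cys_fixed_mod=True), abs=1e-9
            )


class TestScenario:
    def test_scenario_wiring(self, small_scenario):
        sc = small_scenario
        assert len(sc.truth.planted) == 5
        assert len(sc.truth.decoy_ids) == 30
        assert sc.toxin_db.records
        labels = {gs.label for gs in sc.group_sets}
        assert {p.framework_label for p in sc.truth.planted} <= labels

    def test_reverse_translate_roundtrip(self, rng):
        from oracles import translate_codon_by_codon

        aa = "MKTAYIAKQRQISFVK"
        assert translate_codon_by_codon(reverse_translate(aa, rng)) == aa
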