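import numpy as np
import pytest
from pyteomics import mass as pymass
from pyteomics import parser as pyparser

from conftest import random_protein
from venomminer.proteomics import (CARBAMIDOMETHYL, WATER_MONO, match_evidence,
                                   mono_mass, tryptic_digest)
from venomminer.seqio import ObservedPeptide, ProtRecord


class TestTrypticDigest:
    def test_single_site(self):
        peps = tryptic_digest(ProtRecord("a", "AAKGG"))
        assert [p.seq for p in peps] == ["AAK", "GG"]

    def test_kp_suppression(self):
        peps = tryptic_digest(ProtRecord("a", "AAKPGG"))
        assert [p.seq for p in peps] == ["AAKPGG"]

    def test_missed_cleavage_enumeration(self):
        peps = tryptic_digest(ProtRecord("a", "AKRG"), max_missed=1)
        assert {(p.seq, p.missed) for p in peps} == {
            ("AK", 0), ("R", 0), ("G", 0), ("AKR", 1), ("RG", 1)
        }

    def test_spans_consistent(self):
        prot = ProtRecord("a", "MKTAYRIAKQRQISK")
        for p in tryptic_digest(prot, max_missed=2):
            assert prot.seq[p.span[0] : p.span[1]] == p.seq

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest(ProtRecord("a", "MK*"))

    def test_agrees_with_pyteomics_cleave(self, rng):
        for _ in range(20):
            seq = "M" + random_protein(rng, 60)
            ours = {p.seq for p in tryptic_digest(ProtRecord("a", seq),
                                                  max_missed=1)}
            # simple K/R-not-before-P rule (the library's named 'trypsin'
            # rule adds WKP/MRP exceptions this model deliberately omits)
            theirs = set(pyparser.cleave(seq, r"[KR](?=[^P])",
                                         missed_cleavages=1))
            assert ours == theirs


class TestMonoMass:
    def test_diglycine(self):
        assert mono_mass("GG") == pytest.approx(132.05349, abs=1e-5)

    def test_cys_fixed_mod_additivity(self):
        assert mono_mass("C", cys_fixed_mod=True) == pytest.approx(
            mono_mass("C") + CARBAMIDOMETHYL
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mono_mass("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            mono_mass("GJG")

    def test_agrees_with_pyteomics(self, rng):
        for _ in range(20):
            pep = random_protein(rng, int(rng.integers(2, 25)))
            assert mono_mass(pep) == pytest.approx(
                pymass.calculate_mass(sequence=pep, monoisotopic=True),
                abs=1e-6,
            )


class TestDigestConservation:
    def test_partition_and_mass_sum(self, rng):
        """With no missed cleavages the peptides partition the protein and
        their masses sum to the protein mass plus (k-1) waters."""
        for _ in range(50):
            seq = random_protein(rng, int(rng.integers(5, 120)))
            peps = tryptic_digest(ProtRecord("a", seq), max_missed=0)
            assert "".join(p.seq for p in peps) == seq
            total = sum(p.mono_mass for p in peps)
            expected = mono_mass(seq) + (len(peps) - 1) * WATER_MONO
            assert total == pytest.approx(expected, abs=1e-6)


def _protein_with_peptides():
    # two tryptic peptides of 10 aa each on a 50 aa protein
    seq = "WDEFGHIWDK" + "YMNQYENQWK" + "W" * 30
    return ProtRecord("prot1", seq)


class TestMatchEvidence:
    def test_two_peptides_validate_with_coverage(self):
        prot = _protein_with_peptides()
        obs = [
            ObservedPeptide("o1", seq="WDEFGHIWDK"),
            ObservedPeptide("o2", seq="YMNQYENQWK"),
        ]
        (rep,) = match_evidence(obs, [prot], tol_ppm=10)
        assert rep.validated and rep.n_distinct_peptides == 2
        assert rep.coverage == pytest.approx(20 / 50)

    def test_single_peptide_not_validated(self):
        prot = _protein_with_peptides()
        obs = [ObservedPeptide("o1", seq="WDEFGHIWDK")]
        (rep,) = match_evidence(obs, [prot])
        assert not rep.validated and rep.n_distinct_peptides == 1

    def test_mass_only_match_within_tolerance(self):
        prot = _protein_with_peptides()
        target = mono_mass("WDEFGHIWDK", cys_fixed_mod=True)
        obs = [ObservedPeptide("o1", mono_mass=target * (1 + 4e-6))]
        (rep,) = match_evidence(obs, [prot], tol_ppm=5)
        assert rep.matched and rep.matched[0].mode == "mass"
        assert abs(rep.matched[0].ppm_error) == pytest.approx(4, rel=0.01)

    def test_mass_outside_tolerance_ignored(self):
        prot = _protein_with_peptides()
        target = mono_mass("WDEFGHIWDK", cys_fixed_mod=True)
        obs = [ObservedPeptide("o1", mono_mass=target * (1 + 2e-5))]
        (rep,) = match_evidence(obs, [prot], tol_ppm=5)
        assert rep.n_distinct_peptides == 0

    def test_monotone_in_observations(self):
        prot = _protein_with_peptides()
        obs = [
            ObservedPeptide("o1", seq="WDEFGHIWDK"),
            ObservedPeptide("o2", seq="YMNQYENQWK"),
        ]
        (r1,) = match_evidence(obs[:1], [prot])
        (r2,) = match_evidence(obs, [prot])
        assert r2.n_distinct_peptides >= r1.n_distinct_peptides
        assert r2.coverage >= r1.coverage

    def test_coverage_bounds(self, rng):
        prot = ProtRecord("p", random_protein(rng, 80))
        peps = tryptic_digest(prot, max_missed=1, cys_fixed_mod=True)
        obs = [ObservedPeptide(f"o{i}", seq=p.seq)
               for i, p in enumerate(peps)]
        (rep,) = match_evidence(obs, [prot])
        assert 0.0 <= rep.coverage <= 1.0
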