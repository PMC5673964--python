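import pytest
from hypothesis import given, settings, strategies as st

from venomminer.frameworks import (Exact, FrameworkRegistry, LINEAR, Open,
                                   Range, classify, cys_count,
                                   extract_framework, format_motif,
                                   load_registry, matches, normalize_motif,
                                   parse_motif, span)

# Published motif strings (as printed, mixed alphabets and dashes)
CJTL7 = "С1С-3-С3С-4-С3С-3-С1С3"       # Cyrillic С
CJTL8 = "C8C-3-C11C-5-CC6"
CJTL6 = "C27C4C4-CCC"
GENERAL_GROUP1 = "C1C##C[6–9]C-[6–9]-CC#"  # en-dashes


class TestNormalize:
    def test_cyrillic_and_decorative_hyphens(self):
        assert normalize_motif(CJTL7) == "C1C3C3C4C3C3C1C3"

    def test_decorative_hyphens_only(self):
        assert normalize_motif(CJTL8) == "C8C3C11C5CC6"

    def test_endash_inside_range(self):
        assert normalize_motif("C[6–9]C") == "C[6-9]C"

    def test_bad_character_named(self):
        with pytest.raises(ValueError, match="'Z'"):
            normalize_motif("C3ZC")


class TestParse:
    def test_symmetric_eight_cys_motif(self):
        fw = parse_motif("C1C3C3C4C3C3C1C3")
        assert fw.n_cys == 8
        assert [t.n for (t,) in fw.gaps] == [1, 3, 3, 4, 3, 3, 1]
        assert fw.trailing == (Exact(3),)

    def test_single_cys(self):
        fw = parse_motif("C")
        assert fw.n_cys == 1 and fw.gaps == () and fw.trailing is None

    def test_open_and_range_terms(self):
        fw = parse_motif("C1C##C[6-9]C[6-9]CC#")
        assert fw.n_cys == 6
        assert fw.gaps[0] == (Exact(1),)
        assert fw.gaps[1] == (Open(), Open())
        assert fw.gaps[2] == (Range(6, 9),)
        assert fw.gaps[4] == (Exact(0),)
        assert fw.trailing == (Open(),)

    @pytest.mark.parametrize("bad", ["123", "C[6-9", "C[9-6]C", "C[9-9]C"])
    def test_parse_errors(self, bad):
        with pytest.raises(ValueError):
            parse_motif(bad)


class TestArithmetic:
    def test_cjtl7_span_and_count(self):
        fw = parse_motif(CJTL7)
        assert span(fw) == (29, 29)
        assert cys_count(fw) == 8

    def test_cjtl8_span(self):
        assert span(parse_motif(CJTL8)) == (39, 39)

    def test_cjtl6_cys_count(self):
        assert cys_count(parse_motif(CJTL6)) == 6

    def test_general_motif_min_span(self):
        # minimal realisation: 6 Cys + spacers 1+1+1+6+6+0 + trailing 1 = 22
        lo, hi = span(parse_motif(GENERAL_GROUP1))
        assert lo == 22 and hi is None

    def test_single_cys_span(self):
        assert span(parse_motif("C")) == (1, 1)


class TestExtract:
    def test_adjacent_flanked(self):
        fw = extract_framework("CAC")
        assert format_motif(fw) == "C1C"
        assert fw.trailing == (Exact(0),) and fw.leading_offset == 0

    def test_leading_offset_recorded_not_printed(self):
        fw = extract_framework("GGCACAA")
        assert format_motif(fw) == "C1C2"
        assert fw.leading_offset == 2

    def test_cys_free_is_linear(self):
        assert extract_framework("AAAA") is LINEAR


class TestMatches:
    def test_self_match(self):
        for seq in ("CAC", "GGCACAA", "AAAA", "CCC"):
            assert matches(seq, extract_framework(seq))

    def test_positional_realisation(self):
        # 39 aa, Cys at 1-based 1,10,14,26,32,33, six trailing residues
        seq = list("A" * 39)
        for pos in (1, 10, 14, 26, 32, 33):
            seq[pos - 1] = "C"
        seq = "".join(seq)
        assert matches(seq, parse_motif(CJTL8))
        assert not matches(seq, parse_motif(CJTL6))

    def test_absent_trailing_flank_unconstrained(self):
        assert matches("CACAAAAAA", parse_motif("C1C"))
        assert not matches("CACA", parse_motif("C1C0"))


class TestClassify:
    def test_linear(self, registry):
        assert classify("AAAAPPPGGG", registry) == "linear"

    def test_registry_framework(self, registry):
        fw = registry["8a"]
        seq = ("C" + "A" * 6 + "C" + "A" * 4 + "C" + "A" * 9 + "C" + "A" * 3
               + "CC" + "A" * 12)
        assert matches(seq, fw)
        assert classify(seq, registry) == "8a"

    def test_unknown_framework_is_new(self, registry):
        assert classify("CCAACCAAACC", registry) == "new"

    def test_most_specific_pattern_wins(self):
        reg = FrameworkRegistry.from_pairs(
            [("broad", "C#C#C"), ("tight", "C2C3C"), ("linear", "-")]
        )
        seq = "CAAC" + "AAA" + "CGGGG"
        assert matches(seq, reg["broad"]) and matches(seq, reg["tight"])
        assert classify(seq, reg) == "tight"

    def test_invariant_to_non_cys_identity(self, registry):
        a = "C" + "A" * 6 + "C" + "A" * 4 + "C" + "A" * 9 + "C" + "A" * 3 + "CC"
        b = a.replace("A", "W")
        assert classify(a, registry) == classify(b, registry)


# --- property tests -------------------------------------------------------

spacer = st.one_of(
    st.integers(min_value=0, max_value=30).map(Exact),
    st.tuples(st.integers(0, 10), st.integers(1, 20)).filter(
        lambda ab: ab[0] < ab[1]
    ).map(lambda ab: Range(*ab)),
    st.just(Open()),
)


@st.composite
def motif_strings(draw):
    n_cys = draw(st.integers(min_value=1, max_value=8))
    parts = []
    for i in range(n_cys):
        parts.append("C")
        if i < n_cys - 1:
            terms = draw(st.lists(spacer, min_size=0, max_size=2))
            parts.append("".join(str(t) for t in terms))
    if draw(st.booleans()):
        parts.append(str(draw(st.integers(1, 20))))
    return "".join(parts)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(motif_strings())
def test_format_parse_roundtrip(motif):
    fw = parse_motif(motif)
    canonical = format_motif(fw)
    assert parse_motif(canonical) == fw
    assert format_motif(parse_motif(canonical)) == canonical


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
def test_extract_self_match_property(seq):
    assert matches(seq, extract_framework(seq))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACW", min_size=2, max_size=40).filter(lambda s: "C" in s))
def test_exact_framework_span_equals_length(seq):
    """For fully exact frameworks, min span == max span == sequence length
    minus the leading offset (the canonical motif starts at the first Cys)."""
    fw = extract_framework(seq)
    lo, hi = span(fw)
    assert lo == hi == len(seq) - fw.leading_offset
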