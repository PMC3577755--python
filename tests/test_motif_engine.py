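"""NPA boxes, diagnostic-residue anchoring, pattern grammar, SDP filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mipscan.motif_engine import (
    PatternError,
    compile_pattern,
    extract_signature,
    find_npa_boxes,
    match_at,
    match_pattern,
    match_sdp_filters,
    render_pattern,
    scan_phospho_motifs,
    sdp_filter_table,
)
from mipscan.seqio import ProteinRecord
from mipscan.synthetic_data import (
    ARR_TETRADS,
    archetype_spec,
    make_archetype,
    pseudogenize,
)
from mipscan.topology import predict_topology


def built(gene, seed=0):
    spec = archetype_spec(gene)
    p, _ = make_archetype(spec, seed=seed)
    return spec, p, predict_topology(p)


class TestNpaBoxes:
    def test_canonical_pip(self):
        _, p, topo = built("GmPIP1;1")
        b1, b2 = find_npa_boxes(p, topo)
        assert (b1.triplet, b1.status) == ("NPA", "canonical")
        assert (b2.triplet, b2.status) == ("NPA", "canonical")

    def test_sip_first_box_npt(self):
        _, p, topo = built("GmSIP1;1")
        b1, b2 = find_npa_boxes(p, topo)
        assert (b1.triplet, b1.status) == ("NPT", "variant")
        assert b2.status == "canonical"

    def test_xip_first_box_spv(self):
        _, p, topo = built("GmXIP1;1")
        b1, b2 = find_npa_boxes(p, topo)
        assert (b1.triplet, b1.status) == ("SPV", "variant")
        assert b2.status == "canonical"

    def test_ablated_box_reported_absent(self):
        spec, p, _ = built("GmPIP2;1")
        lesioned = pseudogenize(p, ("ablate_box", 2), spec)
        topo = predict_topology(lesioned)
        b1, b2 = find_npa_boxes(lesioned, topo)
        assert b1.status == "canonical" and b2.status == "absent"
        assert b2.position is None


class TestAnchoring:
    def test_pip_p2_p3(self):
        _, p, topo = built("GmPIP1;1")
        sig = extract_signature(p, topo)
        assert (sig.p2, sig.p3) == ("S", "A")

    def test_pip_p6_p7(self):
        _, p, topo = built("GmPIP1;1")
        sig = extract_signature(p, topo)
        assert (sig.p6, sig.p7) == ("C", "G")

    def test_absent_second_box_is_precondition_error(self):
        from mipscan.motif_engine import NpaBox, anchor_diagnostic_positions

        spec, p, topo = built("GmPIP1;1")
        boxes = (NpaBox.absent("B"), NpaBox.absent("E"))
        with pytest.raises(ValueError):
            anchor_diagnostic_positions(p, topo, boxes)

    @pytest.mark.parametrize("gene,tetrad", [
        ("GmPIP1;1", ("F", "H", "T", "R")),
        ("GmNIP2;1", ("G", "S", "G", "R")),
        ("GmNIP5;1", ("A", "I", "G", "R")),
        ("GmTIP5;1", ("S", "V", "G", "C")),
    ])
    def test_arR_tetrads(self, gene, tetrad):
        _, p, topo = built(gene)
        assert extract_signature(p, topo).arR == tetrad

    def test_planted_recovery_all_archetypes_many_seeds(self):
        """Extraction returns exactly the planted residues: 12 subgroup
        archetypes x 50 seeds, 100% recovery."""
        representatives = [
            "GmPIP1;1", "GmTIP1;1", "GmTIP1;9", "GmTIP2;1", "GmTIP3;1",
            "GmTIP4;1", "GmTIP5;1", "GmNIP1;1", "GmNIP5;1", "GmNIP7;1",
            "GmNIP2;1", "GmNIP6;1", "GmNIP6;2", "GmSIP1;1", "GmSIP1;3",
            "GmSIP1;5", "GmXIP1;1", "GmXIP1;2",
        ]
        for gene in representatives:
            spec = archetype_spec(gene)
            for seed in range(50):
                p, _ = make_archetype(spec, seed=[seed, 17])
                topo = predict_topology(p)
                sig = extract_signature(p, topo)
                assert sig.arR == tuple(spec.arR), (gene, seed)
                assert (sig.p1, sig.p2, sig.p3, sig.p4, sig.p5, sig.p6,
                        sig.p7) == spec.froger, (gene, seed)
                assert sig.npa1.triplet == spec.npa1
                assert sig.npa2.triplet == spec.npa2


class TestPhosphoMotifs:
    def test_pip_n_terminal_motif(self):
        _, p, _ = built("GmPIP1;1")
        n_hit, _ = scan_phospho_motifs(p)
        assert n_hit.name == "RKXSXXR/K"
        assert n_hit.match == "RKLSAER" and n_hit.acceptor == "S"

    def test_pip2_c_terminal_sfrs(self):
        _, p, _ = built("GmPIP2;3")
        _, c_hit = scan_phospho_motifs(p)
        assert c_hit.name == "SFRS"
        assert p.sequence.endswith("SFRS")

    def test_thr_acceptor_reported_in_tips(self):
        _, p, _ = built("GmTIP1;1")
        n_hit, c_hit = scan_phospho_motifs(p)
        assert n_hit.acceptor == "T"
        assert c_hit is None

    def test_poly_a_matches_nothing(self):
        p = ProteinRecord(id="x", sequence="A" * 120)
        assert scan_phospho_motifs(p) == (None, None)

    @pytest.mark.parametrize("gene,cname", [
        ("GmNIP1;1", "KXXSXXK"), ("GmNIP2;1", "KSXXR"), ("GmNIP4;1", "KIFKT"),
        ("GmNIP5;1", "XSFRR"), ("GmNIP7;1", "XPFCS"),
    ])
    def test_nip_c_motifs(self, gene, cname):
        _, p, _ = built(gene)
        _, c_hit = scan_phospho_motifs(p)
        assert c_hit.name == cname


class TestPatternGrammar:
    def test_example_filter_matches_expansion(self):
        pat = compile_pattern("Fxx(K/N)xxxFxxT")
        assert len(pat) == 11
        assert match_at(pat, "FAAKQQQFAAT", 0)
        assert not match_at(pat, "FAAKQQQFAAA", 0)

    def test_fixed_tail_required(self):
        pat = compile_pattern("DxxWxDxW")
        assert not match_at(pat, "DAAWADAA", 0)
        assert match_at(pat, "DAAWADAW", 0)

    def test_urea_filter_tokenization(self):
        pat = compile_pattern("A/PxxG/SxG/SxN")
        assert len(pat) == 8
        assert pat.n_alternative_sets == 3

    def test_whitespace_cosmetic(self):
        a = compile_pattern("Txx IxxxHxxP")
        b = compile_pattern("TxxIxxxHxxP")
        assert a.tokens == b.tokens

    def test_unbalanced_parenthesis_rejected(self):
        with pytest.raises(PatternError):
            compile_pattern("Fxx(K/N")

    def test_compile_render_identity_on_all_filters(self):
        table = sdp_filter_table()
        assert len(table) == 15
        for text in table["filter"]:
            pat = compile_pattern(text)
            again = compile_pattern(render_pattern(pat))
            assert again.tokens == pat.tokens

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACDEFGHIKx", min_size=1, max_size=6),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40),
    )
    def test_match_equals_brute_force_sliding(self, pattern_text, seq):
        """Token matcher agrees with a naive character-by-character oracle."""
        pat = compile_pattern(pattern_text)
        for start in range(len(seq) - len(pat) + 1):
            naive = all(
                tok == "x" or seq[start + k] in tok
                for k, tok in enumerate(pat.tokens)
            )
            assert match_at(pat, seq, start) == naive


class TestSdpFilters:
    def test_nip_iii_is_h2o2_transporter(self):
        _, p, topo = built("GmNIP2;1")
        filters = match_sdp_filters(p, topo)
        assert filters["h2o2"] is True
        assert filters["urea"] is False and filters["ammonia"] is False

    def test_nip_iia_h2o2_and_urea(self):
        _, p, topo = built("GmNIP5;1")
        filters = match_sdp_filters(p, topo)
        assert filters["h2o2"] is True and filters["urea"] is True

    def test_silicic_acid_always_false(self, family):
        for p in family.proteins[::9]:
            topo = predict_topology(p)
            assert match_sdp_filters(p, topo)["silicic_acid"] is False

    def test_sip_and_xip_transport_nothing(self):
        for gene in ("GmSIP1;1", "GmSIP1;5", "GmXIP1;1", "GmXIP1;2"):
            _, p, topo = built(gene)
            filters = match_sdp_filters(p, topo)
            assert not any(filters.values()), gene

    def test_family_substrates_match_planted_truth(self, family, family_truth):
        for p in family.proteins[::5]:
            topo = predict_topology(p)
            got = {s for s, ok in match_sdp_filters(p, topo).items() if ok}
            planted = set(filter(None,
                                 family_truth.loc[p.id, "substrates"].split(";")))
            assert got == planted, p.id
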