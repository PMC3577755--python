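"""NG86 Ka/Ks counting, codon alignment, selection-regime calls."""

import itertools

import numpy as np
import pytest

from mipscan.config import EvolutionConfig
from mipscan.evolution import (
    CODON_TABLE,
    STOP_CODONS,
    KaKsError,
    KaKsResult,
    codon_align,
    ng86_kaks,
    pairwise_differences,
    selection_regime,
    synonymous_site_fraction,
)
from mipscan.msa_phylo import Alignment, global_align
from mipscan.seqio import CodingRecord, ProteinRecord
from mipscan.synthetic_data import (
    archetype_spec,
    back_translate,
    evolve_cds_pair,
    make_archetype,
)


def brute_force_differences(c1, c2):
    """Independent path-enumeration oracle for codon difference counts."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    usable = []
    for order in itertools.permutations(diff):
        cur, steps, stop = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            stop = stop or nxt in STOP_CODONS
            steps.append((cur, nxt))
            cur = nxt
        usable.append((stop, steps))
    kept = [s for flag, s in usable if not flag] or [s for _, s in usable]
    sd = sum(CODON_TABLE.get(a) == CODON_TABLE.get(b)
             for s in kept for a, b in s
             if a not in STOP_CODONS and b not in STOP_CODONS)
    total = sum(len(s) for s in kept)
    return sd / len(kept), (total - sd * 1.0) / len(kept) if kept else 0


class TestCounting:
    def test_phe_codon_site_fractions(self):
        # TTT: only the third position has a synonymous change (TTC)
        assert synonymous_site_fraction("TTT") == pytest.approx(1 / 3)
        assert synonymous_site_fraction("TTC") == pytest.approx(1 / 3)

    def test_fourfold_degenerate_third_position(self):
        # glycine GGN: all third-position changes synonymous
        assert synonymous_site_fraction("GGG") == pytest.approx(1.0)

    def test_single_synonymous_difference(self):
        sd, nd = pairwise_differences("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)

    @pytest.mark.parametrize("c1,c2", [
        ("TTT", "TTC"), ("TTT", "CTC"), ("ATG", "TGG"), ("AAA", "GGG"),
        ("TGT", "TGG"), ("TCA", "ACT"),
    ])
    def test_path_average_matches_enumeration_oracle(self, c1, c2):
        sd, nd = pairwise_differences(c1, c2)
        o_sd, o_nd = brute_force_differences(c1, c2)
        assert sd == pytest.approx(o_sd)
        assert sd + nd == pytest.approx(len([i for i in range(3)
                                             if c1[i] != c2[i]]))

    def test_site_count_conservation(self, family):
        cds = family.cds["GmPIP1;1"]
        codons = cds.codons()[:-1]
        pairs = list(zip(codons, codons))
        res = ng86_kaks(pairs)
        assert res.syn_sites + res.nonsyn_sites == pytest.approx(
            3 * res.n_codons, abs=1e-9
        )


class TestKaKs:
    def test_identical_sequences_ratio_undefined(self):
        pairs = [("ATG", "ATG"), ("GGA", "GGA")] * 20
        res = ng86_kaks(pairs)
        assert res.ks == pytest.approx(0.0) and res.ka == pytest.approx(0.0)
        assert res.ratio is None and res.regime == "undefined"

    def test_single_synonymous_change_in_context(self):
        """One Phe->Phe third-position change: ks > 0, ka = 0."""
        context = [("GAT", "GAT")] * 29
        res = ng86_kaks(context + [("TTT", "TTC")])
        assert res.ka == pytest.approx(0.0)
        assert res.ks > 0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        codons = [c for c in CODON_TABLE if c not in STOP_CODONS]
        pairs = []
        while len(pairs) < 60:  # moderately divergent pairs (0-1 base changes)
            c1 = codons[rng.integers(len(codons))]
            pos, base = rng.integers(3), "ACGT"[rng.integers(4)]
            c2 = c1[:pos] + base + c1[pos + 1 :] if rng.random() < 0.5 else c1
            if c2 not in STOP_CODONS:
                pairs.append((c1, c2))
        fwd = ng86_kaks(pairs)
        rev = ng86_kaks([(b, a) for a, b in pairs])
        assert fwd.ka == rev.ka and fwd.ks == rev.ks

    def test_too_few_codons_rejected(self):
        with pytest.raises(KaKsError, match="codons"):
            ng86_kaks([("TTT", "TTC")] * 5)

    def test_premature_stop_rejected(self):
        pairs = [("ATG", "ATG")] * 30 + [("TAA", "ATG")]
        with pytest.raises(KaKsError, match="stop"):
            ng86_kaks(pairs)

    def test_dnds_recovery_from_simulation(self):
        """Estimated ratio sits in [0.1, 0.35] when the true dN/dS is 0.2."""
        spec = archetype_spec("GmPIP1;1")
        ratios = []
        for rep in range(50):
            _, cds = make_archetype(spec, seed=[5, rep], with_cds=True)
            a, b = evolve_cds_pair(cds, dnds=0.2, target_ks=0.3, seed=[9, rep])
            pairs = list(zip(a.codons()[:-1], b.codons()[:-1]))
            ratios.append(ng86_kaks(pairs).ratio)
        ratios = np.array(ratios)
        assert 0.1 <= ratios.mean() <= 0.35
        assert (ratios > 0).all()


class TestCodonAlign:
    def test_identical_cds_all_paired(self, family):
        prot_aln_rows = []
        cds = family.cds["GmPIP1;1"]
        aa = cds.translate()
        aln = Alignment(rows=(("GmPIP1;1", aa), ("copy", aa)))
        copy = CodingRecord(id="copy", sequence=cds.sequence)
        pairs = codon_align(cds, copy, aln)
        assert len(pairs) == len(aa)
        assert all(a == b for a, b in pairs)

    def test_gap_excludes_exactly_one_codon(self):
        a = CodingRecord(id="a", sequence="ATGAAATTT")
        b = CodingRecord(id="b", sequence="ATGTTT")
        aln = Alignment(rows=(("a", "MKF"), ("b", "M-F")))
        pairs = codon_align(a, b, aln)
        assert pairs == [("ATG", "ATG"), ("TTT", "TTT")]

    def test_translation_mismatch_names_codon(self):
        a = CodingRecord(id="a", sequence="ATGAAA")
        b = CodingRecord(id="b", sequence="ATGTTT")
        aln = Alignment(rows=(("a", "MK"), ("b", "MK")))  # b really codes MF
        with pytest.raises(KaKsError, match="codon 2"):
            codon_align(a, b, aln)

    def test_roundtrip_through_real_alignment(self, family):
        a_prot = family.proteins[0]
        a_cds = family.cds[a_prot.id]
        _, b_cds = evolve_cds_pair(a_cds, dnds=0.3, target_ks=0.2, seed=21)
        b_prot = ProteinRecord(id=b_cds.id, sequence=b_cds.translate())
        aln, _ = global_align(a_prot, b_prot)
        # substitution-only evolution: gapless alignment
        assert all("-" not in row for _, row in aln.rows)
        pairs = codon_align(a_cds, b_cds, aln)
        rebuilt_a = "".join(p[0] for p in pairs)
        assert rebuilt_a == a_cds.sequence[:-3]  # pairing degaps to the CDS
        res = ng86_kaks(pairs)
        assert res.regime == "purifying"


class TestRegime:
    @pytest.mark.parametrize("ratio,expected", [
        (0.3, "purifying"), (1.4, "positive"), (1.02, "neutral_or_mixed"),
    ])
    def test_thresholds(self, ratio, expected):
        res = KaKsResult(ka=ratio, ks=1.0, ratio=ratio, regime="")
        assert selection_regime(res) == expected

    def test_zero_ks_undefined(self):
        res = KaKsResult(ka=0.1, ks=0.0, ratio=None, regime="")
        assert selection_regime(res) == "undefined"

    def test_epsilon_configurable(self):
        res = KaKsResult(ka=1.1, ks=1.0, ratio=1.1, regime="")
        assert selection_regime(res, EvolutionConfig(epsilon=0.2)) == "neutral_or_mixed"
        assert selection_regime(res, EvolutionConfig(epsilon=0.05)) == "positive"
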