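"""Nei–Gojobori (1986) Ka/Ks estimation for coding-sequence pairs.

Counting method: each codon position contributes a synonymous-site
fraction equal to the share of its three possible one-step changes that
preserve the amino acid (changes to stop codons count as nonsynonymous);
codons differing at several positions average their synonymous and
nonsynonymous difference counts over all minimal substitution paths,
excluding paths that cross a stop codon.  Proportions are corrected for
multiple hits with the Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3).

A ratio Ka/Ks > 1 indicates positive selection, < 1 purifying selection,
and a ratio near 1 a lack of selection (or a mixture that cancels out).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

from .config import DEFAULT, EvolutionConfig

BASES = "ACGT"
CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TABLE))


class KaKsError(ValueError):
    pass


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]  # None iff ks == 0
    regime: str
    n_codons: int = 0
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon (0..3); stop changes are nonsynonymous."""
    if codon in STOP_CODONS:
        raise KaKsError(f"stop codon {codon} has no site counts")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pairwise_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal substitution paths that avoid stop codons.

    If every path crosses a stop codon (rare), the average is taken over
    all paths instead so the pair still contributes.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return (0.0, 0.0)
    paths = []
    for order in itertools.permutations(diff_pos):
        current = c1
        steps = []
        crosses_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                crosses_stop = True
            steps.append((current, nxt))
            current = nxt
        paths.append((crosses_stop, steps))
    usable = [steps for crossed, steps in paths if not crossed]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in STOP_CODONS or b in STOP_CODONS:
                nd += 1.0  # only on the all-paths fallback
            elif CODON_TABLE[a] == CODON_TABLE[b]:
                sd += 1.0
            else:
                nd += 1.0
    return (sd / len(usable), nd / len(usable))


def jukes_cantor(p: float) -> float:
    import math

    if p < 0:
        raise KaKsError("negative proportion")
    if p >= 0.75:
        raise KaKsError(
            f"proportion {p:.3f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def codon_align(a, b, protein_aln) -> list[tuple[str, str]]:
    """Pair codons of two CDS through their protein alignment.

    Protein gaps expand to codon gaps and are excluded; the translations
    must match the aligned (degapped) proteins.  Terminal stop codons are
    trimmed before pairing.
    """
    rows = dict(protein_aln.rows)
    try:
        ga, gb = rows[a.id], rows[b.id]
    except KeyError as exc:
        raise KaKsError(f"record {exc} not in protein alignment") from exc
    codons_a = a.codons()
    codons_b = b.codons()
    if codons_a and codons_a[-1] in STOP_CODONS:
        codons_a = codons_a[:-1]
    if codons_b and codons_b[-1] in STOP_CODONS:
        codons_b = codons_b[:-1]
    for name, codons, gapped in ((a.id, codons_a, ga), (b.id, codons_b, gb)):
        aa_seq = gapped.replace("-", "")
        if len(codons) != len(aa_seq):
            raise KaKsError(
                f"{name}: {len(codons)} codons vs {len(aa_seq)} aligned residues"
            )
        for k, (codon, aa) in enumerate(zip(codons, aa_seq)):
            translated = CODON_TABLE.get(codon)
            if "N" in codon:
                continue
            if translated != aa and not (translated is None and aa == "X"):
                raise KaKsError(
                    f"{name}: codon {k + 1} ({codon}) translates to "
                    f"{translated}, aligned protein has {aa}"
                )
    pairs = []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca != "-" and cb != "-":
            pairs.append((codons_a[ia], codons_b[ib]))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return pairs


def ng86_kaks(pairs, config: EvolutionConfig = DEFAULT.evolution) -> KaKsResult:
    """NG86 Ka/Ks from a list of paired codons.

    Pairs containing ambiguous bases are skipped; a premature stop codon
    in either sequence is an error.
    """
    clean = []
    for k, (c1, c2) in enumerate(pairs):
        if "N" in c1 or "N" in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise KaKsError(f"premature stop codon at pair {k + 1}: {c1}/{c2}")
        clean.append((c1, c2))
    if len(clean) < config.min_codons:
        raise KaKsError(
            f"only {len(clean)} comparable codons; need >= {config.min_codons}"
        )
    S = N = sd = nd = 0.0
    for c1, c2 in clean:
        s = 0.5 * (synonymous_site_fraction(c1) + synonymous_site_fraction(c2))
        S += s
        N += 3.0 - s
        d_s, d_n = pairwise_differences(c1, c2)
        sd += d_s
        nd += d_n
    ks = jukes_cantor(sd / S) if S > 0 else 0.0
    ka = jukes_cantor(nd / N) if N > 0 else 0.0
    ratio = None if ks == 0.0 else ka / ks
    result = KaKsResult(
        ka=ka, ks=ks, ratio=ratio, regime="", n_codons=len(clean),
        syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd,
    )
    return dataclasses.replace(result, regime=selection_regime(result, config))


def selection_regime(result: KaKsResult,
                     config: EvolutionConfig = DEFAULT.evolution) -> str:
    """positive / purifying / neutral_or_mixed / undefined."""
    if result.ratio is None:
        return "undefined"
    if abs(result.ratio - 1.0) <= config.epsilon:
        return "neutral_or_mixed"
    return "positive" if result.ratio > 1.0 else "purifying"
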