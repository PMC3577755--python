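"""Synthetic MIP-like families with planted, machine-checkable ground truth.

The generator builds one archetype per family member on a shared scaffold:
six strongly hydrophobic helices (Ile/Val), hydrophilic loops, the two NPA
boxes in loops B and E, the ar/R tetrad, the Froger positions P1–P5, the
helix-3 discriminating pair P6/P7, the N-/C-terminal phosphorylation
motifs and (where the subgroup warrants it) the substrate SDP filter
instances — all at fixed, documented scaffold offsets.  Loop interiors
away from helix boundaries carry seeded random filler that mutates at a
configurable rate within a hydrophilic residue pool, so planted truth
stays exact while downstream extraction is exercised against sequence
noise.  Pseudogene archetypes apply the family table's lesion vocabulary
(box ablation/modification, helix deletion, truncation) and record the
planted reason as a truth label.

Everything is reproducible: the same seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import re
from typing import Optional

import numpy as np
import pandas as pd

from .evolution import CODON_TABLE, SENSE_CODONS, STOP_CODONS, synonymous_site_fraction
from .seqio import CodingRecord, GeneModel, ProteinRecord

# scaffold fill patterns (cycled); chosen so helices sit far above and loops
# far below the topology threshold, with mild 9-residue shoulders flanking
# each helix so detected boundaries are stable.  Loop fills are
# subfamily-specific permutations of the same residue sets: hydropathy is
# identical, but the loops carry lineage-marker residues so between-subfamily
# sequence divergence exceeds the within-subfamily spread, as in real
# families (helices stay identical, mirroring their strong conservation).
HELIX_FILL = "IV"
SHORT_LOOP_FILLS = {
    "PIP": "DSGK", "TIP": "KDGS", "NIP": "SKDG", "SIP": "GKSD", "XIP": "DKSG",
}
MILD_FILLS = {
    "PIP": "TSGS", "TIP": "STSG", "NIP": "GSTS", "SIP": "SGST", "XIP": "TGSS",
}
STRONG_FILLS = {
    "PIP": "QNSG", "TIP": "NQGS", "NIP": "SGQN", "SIP": "GSNQ", "XIP": "QSGN",
}
WILDCARD_FILL = "EGQT"          # fills pattern wildcards; never N/S before P
MUTATION_POOL = "SGNQTED"       # hydrophilic, creates no spurious motifs

MARGIN = 9  # unmutated shoulder inside long loops, in residues

BASE_GEOMETRY = {
    "nterm": 30, "tm1": 21, "loopA": 12, "tm2": 21, "loopB": 30, "tm3": 21,
    "loopC": 15, "tm4": 21, "loopD": 9, "tm5": 21, "loopE": 30, "tm6": 21,
    "cterm": 33,
}
REGION_ORDER = list(BASE_GEOMETRY)
GEOMETRY_OVERRIDES = {
    "PIP": {},
    "TIP": {"nterm": 18, "loopC": 10, "cterm": 18},
    "NIP": {"nterm": 25},
    "SIP": {"nterm": 18, "loopC": 8, "cterm": 9},
    "XIP": {"cterm": 38},
}

FROGER = {  # P1..P7 per subfamily
    "PIP": ("E", "S", "A", "F", "W", "C", "G"),
    "TIP": ("T", "S", "A", "Y", "W", "A", "A"),
    "NIP": ("F", "S", "A", "Y", "L", "C", "A"),
    "SIP": ("M", "A", "A", "Y", "W", "G", "G"),
    "XIP": ("M", "C", "A", "F", "W", "I", "G"),
}

ARR_TETRADS = {
    ("PIP", "I"): "FHTR",
    ("TIP", "IA"): "HIAV", ("TIP", "IB"): "HVAV", ("TIP", "IIA"): "HIGR",
    ("TIP", "IIB"): "HIAR", ("TIP", "IIC"): "HIAL", ("TIP", "III"): "SVGC",
    ("NIP", "I"): "WVAR", ("NIP", "IIA"): "AIGR", ("NIP", "IIB"): "AVGR",
    ("NIP", "III"): "GSGR", ("NIP", "IVA"): "NVSR", ("NIP", "IVB"): "TVGR",
    ("SIP", "I"): "ITPF", ("SIP", "II"): "VMPN", ("SIP", "III"): "NIPN",
}

SUBSTRATE_SETS = {
    ("PIP", "I"): frozenset({"boric_acid", "co2", "h2o2", "urea"}),
    ("NIP", "I"): frozenset({"ammonia"}),
    ("NIP", "IIA"): frozenset({"h2o2", "urea"}),
    ("NIP", "IIB"): frozenset({"ammonia"}),
    ("NIP", "III"): frozenset({"h2o2"}),
    ("NIP", "IVA"): frozenset({"boric_acid", "urea"}),
    ("NIP", "IVB"): frozenset({"boric_acid", "urea", "h2o2"}),
}

# SDP filter plant instances: substrate -> list of (region, offset, template)
# '.' fills from WILDCARD_FILL by absolute position
SDP_PLANTS = {
    "ammonia": [("loopC", 1, "F..K...F..T"), ("cterm", 8, "D..L.E.T")],
    "boric_acid": [("tm2", 10, "T..I...H..P"), ("tm4", 9, "E"),
                   ("tm5", 1, "L..L.T.P")],
    "co2": [("tm3", -3, "V..I...C..A"), ("loopD", 3, "I"),
            ("loopE", 19, "D..W.D.W")],
    "h2o2": [("tm3", 14, "A..A...V..V"), ("tm6", 12, "I..F.A.P")],
    "urea": [("loopB", 13, "H..P...F..A"), ("tm4", 12, "L"),
             ("loopE", 1, "A..G.G.N")],
}

_GENE_RE = re.compile(r"^(?:Gm|Pseudo)(PIP|TIP|NIP|SIP|XIP)(\d+);(\d+)")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Everything needed to build one family member deterministically."""

    name: str
    subfamily: str
    subgroup: str                  # fine label, e.g. "IIA"
    geometry: dict
    npa1: str
    npa2: str
    arR: str                       # 4 letters: H2, H5, LE1, LE2
    froger: tuple                  # P1..P7
    n_motif: str
    c_motif: Optional[str]
    substrates: frozenset

    @property
    def length(self) -> int:
        return sum(self.geometry.values())

    @property
    def subgroup_coarse(self) -> str:
        return self.subgroup.rstrip("ABC")

    def region_start0(self, region: str) -> int:
        start = 0
        for name in REGION_ORDER:
            if name == region:
                return start
            start += self.geometry[name]
        raise KeyError(region)

    def region_of0(self, pos: int) -> str:
        start = 0
        for name in REGION_ORDER:
            start += self.geometry[name]
            if pos < start:
                return name
        raise IndexError(pos)

    def helix_interval0(self, k: int) -> tuple[int, int]:
        start = self.region_start0(f"tm{k}")
        return start, start + self.geometry[f"tm{k}"] - 1


def _subgroup_for(subfamily: str, fam: int, iso: int) -> str:
    if subfamily == "PIP" or subfamily == "XIP":
        return "I"
    if subfamily == "TIP":
        if fam == 1:
            return "IB" if iso == 9 else "IA"
        return {2: "IIA", 3: "IIC" if iso <= 2 else "IIB", 4: "IIB", 5: "III"}[fam]
    if subfamily == "NIP":
        return {1: "I", 2: "III", 4: "I", 5: "IIA",
                6: "IVA" if iso == 1 else "IVB", 7: "IIB"}[fam]
    if subfamily == "SIP":
        return {1: "I", 2: "I", 3: "II", 4: "II", 5: "III", 6: "III"}[iso]
    raise ValueError(subfamily)


def _boxes_for(subfamily: str, fam: int, iso: int, name: str) -> tuple[str, str]:
    if subfamily == "NIP" and (fam, iso) in ((5, 1), (6, 1), (6, 2)):
        return ("NPA", "NPV")
    if subfamily == "SIP":
        return ("NPT" if iso <= 4 else "NPS", "NPA")
    if subfamily == "XIP":
        return ("SPV", "NPA") if iso == 1 else ("NPI", "SPA")
    return ("NPA", "NPA")


def _n_motif_for(subfamily: str, name: str) -> str:
    overrides = {
        "GmPIP1;2": "RKLTAER", "GmSIP1;5": "RKLHAEK", "GmSIP1;6": "RKLRAEK",
    }
    if name in overrides:
        return overrides[name]
    return {"PIP": "RKLSAER", "TIP": "RKLTAEK", "NIP": "RKLPAER",
            "SIP": "RKLTAEK", "XIP": "RKLTAER"}[subfamily]


def _c_motif_for(subfamily: str, fam: int) -> Optional[str]:
    if subfamily == "PIP":
        return "PFKT" if fam == 1 else "SFRS"
    if subfamily == "NIP":
        return {1: "KAASAAK", 2: "KSAAR", 4: "KIFKT",
                5: "ASFRR", 6: "ASFRR", 7: "APFCS"}[fam]
    return None


def archetype_spec(gene_name: str) -> ArchetypeSpec:
    """The archetype for one family-table gene name."""
    m = _GENE_RE.match(gene_name)
    if not m:
        raise ValueError(f"unrecognized gene name {gene_name!r}")
    subfamily, fam, iso = m.group(1), int(m.group(2)), int(m.group(3))
    subgroup = _subgroup_for(subfamily, fam, iso)
    if subfamily == "XIP":
        arr = "VIVR" if iso == 1 else "VIAR"
    else:
        arr = ARR_TETRADS[(subfamily, subgroup)]
    npa1, npa2 = _boxes_for(subfamily, fam, iso, gene_name)
    geometry = dict(BASE_GEOMETRY, **GEOMETRY_OVERRIDES[subfamily])
    substrates = SUBSTRATE_SETS.get(
        (subfamily, subgroup),
        frozenset({"h2o2", "urea"}) if subfamily == "TIP" else frozenset(),
    )
    return ArchetypeSpec(
        name=gene_name, subfamily=subfamily, subgroup=subgroup,
        geometry=geometry, npa1=npa1, npa2=npa2, arR=arr,
        froger=FROGER[subfamily], n_motif=_n_motif_for(subfamily, gene_name),
        c_motif=_c_motif_for(subfamily, fam), substrates=substrates,
    )


# ---------------------------------------------------------------------------
# Scaffold construction


def _base_fill(spec: ArchetypeSpec) -> list[str]:
    short_loop = SHORT_LOOP_FILLS[spec.subfamily]
    mild = MILD_FILLS[spec.subfamily]
    strong = STRONG_FILLS[spec.subfamily]
    chars: list[str] = []
    for region in REGION_ORDER:
        ln = spec.geometry[region]
        if region.startswith("tm"):
            chars.extend(HELIX_FILL[i % len(HELIX_FILL)] for i in range(ln))
        elif region in ("loopA", "loopD"):
            chars.extend(short_loop[i % len(short_loop)] for i in range(ln))
        else:  # long loops and termini: mild shoulders, strong interior
            for i in range(ln):
                if i < MARGIN or i >= ln - MARGIN:
                    chars.append(mild[i % len(mild)])
                else:
                    chars.append(strong[i % len(strong)])
    return chars


def _plants(spec: ArchetypeSpec) -> list[tuple[int, str]]:
    """(absolute 0-based position, residue) of every planted position."""
    out: list[tuple[int, str]] = []

    def plant(region: str, offset: int, template: str):
        start = spec.region_start0(region) + offset
        for k, c in enumerate(template):
            pos = start + k
            if c == ".":
                # pattern wildcard: keep the hydrophobic base fill inside
                # helices; in loops pin a safe hydrophilic residue so the
                # position is fixed and never N/S ahead of a planted Pro
                if spec.region_of0(pos).startswith("tm"):
                    continue
                residue = WILDCARD_FILL[pos % len(WILDCARD_FILL)]
            else:
                residue = c
            out.append((pos, residue))

    for substrate in sorted(spec.substrates):
        for region, offset, template in SDP_PLANTS[substrate]:
            plant(region, offset, template)

    p1, p2, p3, p4, p5, p6, p7 = spec.froger
    h2, h5, le1, le2 = spec.arR
    plant("nterm", 0, "M")
    plant("nterm", 4, spec.n_motif)
    plant("tm2", 12, h2)
    plant("loopB", 10, spec.npa1)
    plant("tm3", 10, p1)
    plant("tm3", 12, "Q")
    plant("tm3", 18, p6)
    plant("tm3", 19, p7)
    plant("tm5", 12, h5)
    plant("loopE", 5, le1)
    plant("loopE", 8, spec.npa2)
    plant("loopE", 12, p2)
    plant("loopE", 16, p3)
    plant("loopE", 17, le2)
    plant("tm6", 3, p4)
    plant("tm6", 10, p5)
    if spec.c_motif:
        plant("cterm", spec.geometry["cterm"] - len(spec.c_motif), spec.c_motif)
    return out


def _mutable_mask(spec: ArchetypeSpec, planted: set[int]) -> np.ndarray:
    mask = np.zeros(spec.length, dtype=bool)
    for region in ("nterm", "loopB", "loopC", "loopE", "cterm"):
        start = spec.region_start0(region)
        ln = spec.geometry[region]
        lo = start + (11 if region == "nterm" else MARGIN)
        hi = start + ln - MARGIN - 1
        if hi >= lo:
            mask[lo : hi + 1] = True
    for pos in planted:
        if 0 <= pos < spec.length:
            mask[pos] = False
    return mask


def make_archetype(spec: ArchetypeSpec, seed, mutation_rate: float = 0.05,
                   with_cds: bool = False
                   ) -> tuple[ProteinRecord, Optional[CodingRecord]]:
    """Build one archetype; same (spec, seed) gives identical output."""
    rng = np.random.default_rng(seed)
    chars = _base_fill(spec)
    planted = _plants(spec)
    for pos, residue in planted:
        chars[pos] = residue
    mask = _mutable_mask(spec, {pos for pos, _ in planted})
    hit = rng.random(spec.length) < mutation_rate
    pool = list(MUTATION_POOL)
    for pos in np.nonzero(hit & mask)[0]:
        chars[pos] = pool[rng.integers(len(pool))]
    seq = "".join(chars)
    protein = ProteinRecord(
        id=spec.name, sequence=seq,
        description=f"synthetic {spec.subfamily} subgroup {spec.subgroup}",
    )
    cds = back_translate(protein, rng) if with_cds else None
    return protein, cds


_CODONS_FOR = {}
for _codon, _aa in CODON_TABLE.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()


def back_translate(protein: ProteinRecord, rng) -> CodingRecord:
    """Uniform synonymous-codon back-translation, terminal TAA stop."""
    codons = [
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))]
        for aa in protein.sequence
    ]
    return CodingRecord(id=protein.id, sequence="".join(codons) + "TAA",
                        description="synthetic CDS")


# ---------------------------------------------------------------------------
# Pseudogenization

# directive vocabulary mirrors the family table's comment column
PSEUDO_DIRECTIVES = [
    # (pseudo name, base gene, directives, planted reasons)
    ("PseudoPIP#1", "GmPIP1;1", (("delete_helix", 3),), ("tm_missing",)),
    ("PseudoPIP#2", "GmPIP2;1", (("ablate_box", 2),), ("npa2_missing",)),
    ("PseudoPIP#3", "GmPIP1;3", (("modify_box", 1, "NPS"),), ("npa_modified",)),
    ("PseudoPIP#4", "GmPIP2;2", (("truncate_to", 128),), ("not_full_length",)),
    ("PseudoTIP#1", "GmTIP1;1", (("ablate_box", 2),), ("npa2_missing",)),
    ("PseudoTIP#2", "GmTIP2;1", (("ablate_box", 2),), ("npa2_missing",)),
    ("PseudoTIP#3", "GmTIP1;2", (("truncate_to", 188),), ("not_full_length",)),
    ("PseudoNIP#1", "GmNIP1;1", (("truncate_to", 216),), ("not_full_length",)),
    ("PseudoNIP#2", "GmNIP1;1", (("delete_helix", 5),), ("tm_missing",)),
    ("PseudoNIP#3", "GmNIP1;2", (("truncate_to", 182),), ("not_full_length",)),
    ("PseudoNIP#4", "GmNIP1;3", (("truncate_to", 185),), ("not_full_length",)),
    ("PseudoNIP#5", "GmNIP1;4", (("truncate_to", 229),), ("not_full_length",)),
    ("PseudoNIP#6", "GmNIP2;1", (("ablate_box", 1),), ("npa1_missing",)),
    ("PseudoNIP#7", "GmNIP7;1", (("truncate_to", 217),), ("not_full_length",)),
    ("PseudoNIP#8", "GmNIP7;2", (("truncate_to", 220),), ("not_full_length",)),
    ("PseudoNIP#9", "GmNIP5;1", (("ablate_box", 1),), ("npa1_missing",)),
    ("PseudoNIP#10", "GmNIP6;1", (("truncate_to", 229),), ("not_full_length",)),
    ("PseudoNIP#11", "GmNIP1;5Nod26", (("truncate_to", 92),), ("not_full_length",)),
    ("PseudoNIP#12", "GmNIP4;1", (("truncate_to", 60),), ("not_full_length",)),
    ("PseudoSIP#1", "GmSIP1;1", (("truncate_to", 141),), ("not_full_length",)),
    ("PseudoSIP#2", "GmSIP1;3", (("delete_helix", 6),), ("tm_missing",)),
    ("PseudoSIP#3", "GmSIP1;5", (("delete_helix", 1),), ("tm_missing",)),
    ("PseudoXIP#1", "GmXIP1;1", (("truncate_to", 202),), ("not_full_length",)),
]


def pseudogenize(protein: ProteinRecord, directive: tuple,
                 spec: ArchetypeSpec, new_id: str = None) -> ProteinRecord:
    """Apply one lesion directive to an archetype protein."""
    seq = protein.sequence
    kind = directive[0]
    if kind == "truncate_to":
        n = directive[1]
        if n > len(seq):
            raise ValueError(f"cannot truncate to {n}: sequence is {len(seq)}")
        seq = seq[:n]
    elif kind == "delete_helix":
        k = directive[1]
        lo, hi = spec.helix_interval0(k)
        seq = seq[:lo] + seq[hi + 1 :]
    elif kind in ("ablate_box", "modify_box"):
        which = directive[1]
        region = "loopB" if which == 1 else "loopE"
        pos = spec.region_start0(region) + (10 if which == 1 else 8)
        replacement = "GSG" if kind == "ablate_box" else directive[2]
        seq = seq[:pos] + replacement + seq[pos + 3 :]
    else:
        raise ValueError(f"unknown directive {kind!r}")
    return ProteinRecord(
        id=new_id or protein.id, sequence=seq,
        description=f"{protein.description}; lesion {directive}",
    )


# ---------------------------------------------------------------------------
# Family assembly


@dataclass(frozen=True)
class FamilyBuild:
    proteins: list            # 66 full-length ProteinRecords
    pseudos: list             # 23 lesioned ProteinRecords
    truth: pd.DataFrame       # planted ground truth, one row per record
    cds: dict                 # id -> CodingRecord (full-length only)


def family_gene_names() -> list[str]:
    from .seqio import packaged_family_table

    return [r.gene_name for r in packaged_family_table() if not r.is_pseudo]


def make_family(seed: int, mutation_rate: float = 0.05,
                with_cds: bool = False, include_pseudo: bool = True
                ) -> FamilyBuild:
    """The full 66-member family (plus the 23 pseudogene lesions)."""
    proteins, rows, cds = [], [], {}
    for idx, name in enumerate(family_gene_names()):
        spec = archetype_spec(name)
        protein, coding = make_archetype(
            spec, seed=[seed, idx], mutation_rate=mutation_rate,
            with_cds=with_cds,
        )
        proteins.append(protein)
        if coding is not None:
            cds[name] = coding
        rows.append({
            "gene": name, "subfamily": spec.subfamily,
            "subgroup": spec.subgroup_coarse, "subgroup_fine": spec.subgroup,
            "npa1": spec.npa1, "npa2": spec.npa2, "arR": spec.arR,
            "is_pseudo": False, "planted_reasons": "",
            "substrates": ";".join(sorted(spec.substrates)),
        })
    pseudos = []
    if include_pseudo:
        for idx, (name, base, directives, reasons) in enumerate(PSEUDO_DIRECTIVES):
            spec = archetype_spec(base)
            protein, _ = make_archetype(
                spec, seed=[seed, 1000 + idx], mutation_rate=mutation_rate,
            )
            for directive in directives:
                protein = pseudogenize(protein, directive, spec, new_id=name)
            pseudos.append(protein)
            rows.append({
                "gene": name, "subfamily": spec.subfamily,
                "subgroup": spec.subgroup_coarse, "subgroup_fine": spec.subgroup,
                "npa1": spec.npa1, "npa2": spec.npa2, "arR": spec.arR,
                "is_pseudo": True, "planted_reasons": ";".join(reasons),
                "substrates": "",
            })
    return FamilyBuild(proteins=proteins, pseudos=pseudos,
                       truth=pd.DataFrame.from_records(rows), cds=cds)


# ---------------------------------------------------------------------------
# CDS pair evolution (for Ka/Ks recovery tests)


def evolve_cds_pair(cds: CodingRecord, dnds: float, target_ks: float,
                    seed) -> tuple[CodingRecord, CodingRecord]:
    """Evolve a copy of a CDS to a requested synonymous distance and dN/dS.

    Substitutions are proposed uniformly over positions and accepted with
    probabilities that realize the requested nonsynonymous/synonymous rate
    ratio; proposals creating stop codons are rejected.  The process stops
    once the expected synonymous divergence (per synonymous site, before
    multiple-hit correction) reaches ``target_ks``.
    """
    if dnds <= 0:
        raise ValueError("dnds must be positive")
    if not 0 < target_ks <= 0.5:
        raise ValueError("target_ks must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    codons = cds.codons()
    if codons and codons[-1] in STOP_CODONS:
        stop = codons[-1]
        codons = codons[:-1]
    else:
        stop = ""
    S = sum(synonymous_site_fraction(c) for c in codons)
    target_syn = max(1, round(target_ks * S))
    p_syn = min(1.0, 1.0 / dnds)
    p_non = min(1.0, dnds)
    accepted_syn = 0
    guard = 0
    max_iter = 2000 * len(codons)
    while accepted_syn < target_syn:
        guard += 1
        if guard > max_iter:
            raise RuntimeError("substitution process failed to converge")
        ci = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        base = "ACGT"[int(rng.integers(4))]
        codon = codons[ci]
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        synonymous = CODON_TABLE[alt] == CODON_TABLE[codon]
        accept_p = p_syn if synonymous else p_non
        if rng.random() >= accept_p:
            continue
        codons[ci] = alt
        if synonymous:
            accepted_syn += 1
    derived = CodingRecord(id=cds.id + "_derived",
                           sequence="".join(codons) + stop,
                           description="evolved copy")
    return cds, derived


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_ct_table(true_re: dict, noise_sd: float = 0.1,
                      replicates: int = 3, seed=0, condition: str = "PEG",
                      reference: str = "REF", ref_ct: float = 20.0):
    """Simulate a Ct table with known relative expressions.

    ``true_re`` maps gene -> {timepoint: RE}; an RE of None plants an
    unavailable measurement (Ct 31, outside the validity window).
    Ct_gene = ref_ct - log2(RE) + Gaussian noise.
    """
    from .expression import CtTable

    rng = np.random.default_rng(seed)
    records = []
    timepoints = sorted({t for m in true_re.values() for t in m})
    for t in timepoints:
        for rep in range(1, replicates + 1):
            records.append({
                "gene": reference, "condition": condition, "timepoint": t,
                "replicate": rep,
                "ct": ref_ct + rng.normal(0.0, noise_sd),
            })
    for gene in sorted(true_re):
        for t, re_val in sorted(true_re[gene].items()):
            for rep in range(1, replicates + 1):
                if re_val is None:
                    ct = 31.0
                else:
                    if re_val <= 0:
                        raise ValueError("true RE must be positive")
                    ct = ref_ct - np.log2(re_val) + rng.normal(0.0, noise_sd)
                records.append({
                    "gene": gene, "condition": condition, "timepoint": t,
                    "replicate": rep, "ct": float(ct),
                })
    return CtTable(data=pd.DataFrame.from_records(records), reference=reference)


# ---------------------------------------------------------------------------
# Gene models (exon/intron structure)

_INTRON_COUNTS = {
    "PIP": 3, "TIP": 2, "NIP": 4, "SIP": 2, "XIP": 1,
}
_INTRON_OVERRIDES = {
    "GmPIP2;13": 4,
    "GmTIP1;7": 1, "GmTIP1;8": 1, "GmTIP1;9": 1, "GmTIP5;1": 3,
    "GmNIP1;4": 5, "GmNIP4;1": 5, "GmNIP5;1": 3, "GmNIP6;2": 2,
    "GmSIP1;5": 0, "GmSIP1;6": 0,
}


def gene_model_for(gene_name: str, exon_len: int = 300,
                   intron_len: int = 200, start: int = 1001) -> GeneModel:
    """A schematic gene model with the subfamily's canonical intron count."""
    m = _GENE_RE.match(gene_name)
    if not m:
        raise ValueError(f"unrecognized gene name {gene_name!r}")
    n_introns = _INTRON_OVERRIDES.get(gene_name, _INTRON_COUNTS[m.group(1)])
    exons = []
    pos = start
    for _ in range(n_introns + 1):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    return GeneModel(id=gene_name, exons=tuple(exons), strand="+")
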