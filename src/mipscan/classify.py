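"""Subfamily/subgroup assignment, functional typing and pseudogene flags.

Plant MIPs split into five subfamilies (PIP, TIP, NIP, SIP, XIP) and, in
this family, twelve ar/R subgroups.  The classifier works from sequence
evidence alone: the helix-3 discriminating pair (P6, P7) picks the
subfamily, the ar/R tetrad the subgroup, the Froger positions the
water/glycerol functional type, and the NPA-box and full-length checks the
pseudogene status.  A phylogenetic tree can arbitrate the rare (P6, P7)
ambiguities that box and C-terminal-motif evidence cannot resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .config import DEFAULT, Config
from .motif_engine import (
    MotifHit,
    ResidueSignature,
    extract_signature,
    match_sdp_filters,
)
from .topology import TopologyResult, is_full_length, predict_topology

SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")

# helix-3 discriminating pair, per subfamily
P6_SETS = {
    "PIP": set("CSV"),
    "TIP": set("AIMTV"),
    "NIP": set("CLS"),
    "SIP": set("GV"),
    "XIP": set("I"),
}
P7_SETS = {"PIP": {"G"}, "TIP": {"A"}, "NIP": {"A"}, "SIP": {"G"}, "XIP": {"G"}}

# NPA-box triplets expected in intact members of each subfamily
EXPECTED_BOXES = {
    "PIP": ({"NPA"}, {"NPA"}),
    "TIP": ({"NPA"}, {"NPA"}),
    "NIP": ({"NPA", "NPS"}, {"NPA", "NPV"}),
    "SIP": ({"NPT", "NPS"}, {"NPA"}),
    "XIP": ({"SPV", "NPI"}, {"NPA", "SPA"}),
}

# C-terminal phosphorylation motif -> subfamily evidence
_C_MOTIF_SUBFAMILY = {
    "SFRS": "PIP", "PFK/ST/S": "PIP",
    "KXXSXXK": "NIP", "KSXXR": "NIP", "KIFKT": "NIP",
    "XSFRR": "NIP", "XPFCS": "NIP",
}

# Froger-position consensus sets
AQP_SETS = {
    "p1": set("TAMQEV"), "p2": set("SA"), "p3": set("AS"),
    "p4": set("FY"), "p5": set("WIL"),
}
GLPF_SETS = {
    "p1": set("YF"), "p2": set("D"), "p3": set("RK"),
    "p4": set("PA"), "p5": set("IVALMW"),
}


@dataclass(frozen=True)
class SubfamilyCall:
    subfamily: str  # PIP/TIP/NIP/SIP/XIP/unclassified
    subgroup: Optional[str] = None           # coarse label (I, II, III, IV)
    subgroup_fine: Optional[str] = None      # e.g. IIA
    subgroup_exact: bool = True
    evidence: tuple = ()
    tie_broken_by_tree: bool = False


@dataclass(frozen=True)
class TransportProfile:
    functional_type: str  # AQP-like / GlpF-like / aquaglyceroporin / unclassified
    votes: dict = field(default_factory=dict)  # p1..p5 -> AQP/GlpF/both/neither
    substrates: frozenset = frozenset()


@dataclass(frozen=True)
class PseudogeneFlag:
    is_pseudo: bool
    reasons: tuple = ()


# ---------------------------------------------------------------------------
# Subfamily


def assign_subfamily(sig: ResidueSignature, tree=None, leaf_id: str = None,
                     leaf_subfamilies: dict = None) -> SubfamilyCall:
    """Assign a subfamily from the residue signature.

    Precedence: (P6, P7) membership, then NPA-box evidence, then
    C-terminal motif class, then nearest assigned neighbor in the tree.
    """
    evidence = []
    if sig.p6 is not None and sig.p7 is not None:
        candidates = [
            s for s in SUBFAMILIES
            if sig.p6 in P6_SETS[s] and sig.p7 in P7_SETS[s]
        ]
        if candidates:
            evidence.append(f"P6/P7=({sig.p6},{sig.p7})")
    else:
        candidates = list(SUBFAMILIES)
    if len(candidates) == 1:
        return SubfamilyCall(subfamily=candidates[0], evidence=tuple(evidence))

    # NPA-box evidence
    t1 = sig.npa1.triplet
    t2 = sig.npa2.triplet
    if t1 in ("NPT", "NPS") and "SIP" in candidates:
        evidence.append(f"npa1={t1}")
        return SubfamilyCall(subfamily="SIP", evidence=tuple(evidence))
    if (t1 in ("SPV", "NPI") or t2 == "SPA") and "XIP" in candidates:
        evidence.append(f"boxes={t1}/{t2}")
        return SubfamilyCall(subfamily="XIP", evidence=tuple(evidence))
    if t1 == "NPA":
        narrowed = [s for s in candidates if s not in ("SIP", "XIP")]
        if len(narrowed) == 1:
            evidence.append("npa1=NPA excludes SIP/XIP")
            return SubfamilyCall(subfamily=narrowed[0], evidence=tuple(evidence))
        if narrowed:
            candidates = narrowed

    # C-terminal motif class
    if sig.c_term_motif is not None:
        hint = _C_MOTIF_SUBFAMILY.get(sig.c_term_motif.name)
        if hint in candidates:
            evidence.append(f"c-motif={sig.c_term_motif.name}")
            return SubfamilyCall(subfamily=hint, evidence=tuple(evidence))

    # tree tie-break: nearest leaf with a confident assignment
    if tree is not None and leaf_id is not None and leaf_subfamilies:
        try:
            me = tree.find(leaf_id)
        except Exception:
            me = None
        if me is not None:
            best = None
            for tip in tree.tips():
                sub = leaf_subfamilies.get(tip.name)
                if sub is None or tip.name == leaf_id:
                    continue
                d = me.distance(tip)
                if best is None or d < best[0]:
                    best = (d, sub)
            if best is not None and best[1] in candidates:
                evidence.append(f"tree neighbor -> {best[1]}")
                return SubfamilyCall(subfamily=best[1], evidence=tuple(evidence),
                                     tie_broken_by_tree=True)

    return SubfamilyCall(subfamily="unclassified",
                         evidence=tuple(evidence) or ("no rule matched",))


# ---------------------------------------------------------------------------
# Subgroup

_ARR_TABLE = None


def arr_subgroup_table() -> pd.DataFrame:
    global _ARR_TABLE
    if _ARR_TABLE is None:
        ref = resources.files("mipscan") / "data" / "arr_subgroups.tsv"
        with resources.as_file(ref) as path:
            _ARR_TABLE = pd.read_csv(path, sep="\t")
    return _ARR_TABLE


def _collapse(fine: str) -> str:
    return fine.rstrip("ABC")


def assign_subgroup(subfamily: str, arR: tuple) -> Optional[tuple]:
    """(fine_label, coarse_label, exact) from the ar/R tetrad, or None.

    Exact lookup against the packaged tetrad table; nearest tetrad by
    Hamming distance as a flagged fallback, ties unresolved.
    """
    if subfamily not in SUBFAMILIES or any(r is None for r in arR):
        return None
    table = arr_subgroup_table()
    rows = table[table["subfamily"] == subfamily]
    tetrad = tuple(arR)
    scored = []
    for _, row in rows.iterrows():
        ref = (row["h2"], row["h5"], row["le1"], row["le2"])
        d = sum(a != b for a, b in zip(tetrad, ref))
        scored.append((d, row["subgroup"]))
    if not scored:
        return None
    best = min(d for d, _ in scored)
    hits = sorted({g for d, g in scored if d == best})
    if best == 0:
        return (hits[0], _collapse(hits[0]), True)
    if len(hits) == 1:
        return (hits[0], _collapse(hits[0]), False)
    return None  # ambiguous nearest tetrad


# ---------------------------------------------------------------------------
# Functional type


def functional_type(sig: ResidueSignature,
                    substrates: frozenset = frozenset()) -> TransportProfile:
    """Water (AQP) vs glycerol (GlpF) typing from the Froger positions.

    Each non-null P1–P5 residue is scored for compatibility with the
    AQP-type and GlpF-type consensus sets; at least two compatible
    positions on each side makes the protein an aquaglyceroporin,
    otherwise the larger side wins.
    """
    votes = {}
    a = g = known = 0
    for key, residue in zip(("p1", "p2", "p3", "p4", "p5"), sig.froger):
        if residue is None:
            votes[key] = None
            continue
        known += 1
        in_a = residue in AQP_SETS[key]
        in_g = residue in GLPF_SETS[key]
        a += in_a
        g += in_g
        votes[key] = {(True, True): "both", (True, False): "AQP",
                      (False, True): "GlpF", (False, False): "neither"}[(in_a, in_g)]
    if known < 3:
        return TransportProfile("unclassified", votes, substrates)
    if a >= 2 and g >= 2:
        ftype = "aquaglyceroporin"
    elif a > g:
        ftype = "AQP-like"
    elif g > a:
        ftype = "GlpF-like"
    else:
        ftype = "aquaglyceroporin"
    return TransportProfile(ftype, votes, substrates)


# ---------------------------------------------------------------------------
# Pseudogene flags


def flag_pseudogene(p, topo: TopologyResult, sig: ResidueSignature,
                    subfamily: str = None,
                    config: Config = DEFAULT) -> PseudogeneFlag:
    """Accumulate pseudogene reasons in the family table's vocabulary.

    npa1_missing / npa2_missing: a box is absent.
    npa_modified: a box is a variant triplet not expected for the called
        subfamily (e.g. a PIP with NPS).
    tm_missing: fewer than six helices while both boxes are intact.
    not_full_length: the full-length rule fails (helix count, boxes or
        length window).
    """
    reasons = []
    status = (sig.npa1.status, sig.npa2.status)
    if status[0] == "absent":
        reasons.append("npa1_missing")
    if status[1] == "absent":
        reasons.append("npa2_missing")
    if subfamily in EXPECTED_BOXES:
        exp1, exp2 = EXPECTED_BOXES[subfamily]
        if status[0] == "variant" and sig.npa1.triplet not in exp1:
            reasons.append("npa_modified")
        elif status[1] == "variant" and sig.npa2.triplet not in exp2:
            reasons.append("npa_modified")
    if topo.ntm < 6 and "absent" not in status:
        reasons.append("tm_missing")
    full, _ = is_full_length(p, topo, status, config.topology)
    if not full:
        reasons.append("not_full_length")
    return PseudogeneFlag(is_pseudo=bool(reasons), reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# One-stop classification


@dataclass(frozen=True)
class ClassificationResult:
    id: str
    topology: TopologyResult
    signature: ResidueSignature
    call: SubfamilyCall
    profile: TransportProfile
    pseudo: PseudogeneFlag


def classify_protein(p, config: Config = DEFAULT, tree=None,
                     leaf_subfamilies: dict = None) -> ClassificationResult:
    """Run topology, signature extraction and all classification rules."""
    topo = predict_topology(p, config.topology)
    sig = extract_signature(p, topo, config.motif)
    call = assign_subfamily(sig, tree=tree, leaf_id=p.id,
                            leaf_subfamilies=leaf_subfamilies)
    subgroup = None
    if call.subfamily in SUBFAMILIES:
        subgroup = assign_subgroup(call.subfamily, sig.arR)
    if subgroup is not None:
        call = SubfamilyCall(
            subfamily=call.subfamily, subgroup=subgroup[1],
            subgroup_fine=subgroup[0], subgroup_exact=subgroup[2],
            evidence=call.evidence, tie_broken_by_tree=call.tie_broken_by_tree,
        )
    substrates = frozenset(
        s for s, ok in match_sdp_filters(p, topo, config.motif).items() if ok
    )
    profile = functional_type(sig, substrates)
    pseudo = flag_pseudogene(p, topo, sig, subfamily=call.subfamily,
                             config=config)
    return ClassificationResult(
        id=p.id, topology=topo, signature=sig, call=call,
        profile=profile, pseudo=pseudo,
    )
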