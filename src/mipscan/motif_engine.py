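"""NPA boxes, diagnostic residues and motif pattern matching.

The pore of a MIP channel is built from two NPA boxes (loops B and E) and
the aromatic/arginine (ar/R) constriction; a handful of further residues
(the Froger positions P1–P5 and the subfamily-discriminating pair P6/P7 in
helix 3) separate water-transporting from glycerol-transporting channels
and the five plant subfamilies from each other.  This module locates the
boxes, anchors and extracts those residues, scans the N-/C-terminal
phosphorylation motifs, and applies the substrate specificity (SDP)
filters.

Anchoring strategy: the NPA boxes are found by exact scan and are the most
reliable sequence anchors, so helix reference points are derived from the
boxes at fixed scaffold offsets whenever a box is present (hydropathy
segment boundaries, which can jitter by a residue or two, are the
fallback).  The offsets are calibrated constants of the packaged scaffold
geometry and live in :class:`mipscan.config.MotifConfig`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional

import pandas as pd

from .config import DEFAULT, MotifConfig
from .topology import TopologyResult

NPA_VARIANTS = ("NPS", "NPT", "NPV", "NPI", "SPV", "SPA")

BoxStatus = Literal["canonical", "variant", "absent"]


@dataclass(frozen=True)
class NpaBox:
    loop: Literal["B", "E"]
    position: Optional[int]  # 1-based index of the first residue, None if absent
    triplet: Optional[str]
    status: BoxStatus

    @classmethod
    def absent(cls, loop) -> "NpaBox":
        return cls(loop=loop, position=None, triplet=None, status="absent")


@dataclass(frozen=True)
class MotifHit:
    name: str
    match: str
    start: int  # 1-based
    acceptor: Optional[str] = None


@dataclass(frozen=True)
class ResidueSignature:
    """All diagnostic residues of one protein."""

    npa1: NpaBox
    npa2: NpaBox
    p1: Optional[str] = None
    p2: Optional[str] = None
    p3: Optional[str] = None
    p4: Optional[str] = None
    p5: Optional[str] = None
    p6: Optional[str] = None
    p7: Optional[str] = None
    arR: tuple = (None, None, None, None)  # (H2, H5, LE1, LE2)
    n_term_motif: Optional[MotifHit] = None
    c_term_motif: Optional[MotifHit] = None
    warnings: tuple = ()

    @property
    def froger(self) -> tuple:
        return (self.p1, self.p2, self.p3, self.p4, self.p5)


# ---------------------------------------------------------------------------
# Pattern grammar
#
# uppercase letter  = fixed residue
# x                 = wildcard
# .                 = wildcard that is reported (phospho-acceptor slot)
# A/B or (A/B)      = alternative residue set
# whitespace        = cosmetic, ignored


@dataclass(frozen=True)
class MotifPattern:
    tokens: tuple  # each token: frozenset of letters, or "x", or "."
    region: str
    text: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_alternative_sets(self) -> int:
        return sum(
            1 for t in self.tokens if isinstance(t, frozenset) and len(t) > 1
        )


class PatternError(ValueError):
    pass


def compile_pattern(text: str, region: str = "full") -> MotifPattern:
    """Compile a filter string like ``Fxx(K/N)xxxFxxT`` into tokens."""
    s = re.sub(r"\s+", "", text)
    if not s:
        raise PatternError("empty pattern")
    tokens: list = []
    i = 0
    while i < len(s):
        c = s[i]
        if c in "xX":
            tokens.append("x")
            i += 1
        elif c == ".":
            tokens.append(".")
            i += 1
        elif c == "(":
            j = s.find(")", i)
            if j < 0:
                raise PatternError(f"unbalanced parenthesis in {text!r}")
            group = s[i + 1 : j].split("/")
            if not all(len(g) == 1 and g.isalpha() and g.isupper() for g in group):
                raise PatternError(f"bad alternative group in {text!r}")
            tokens.append(frozenset(group))
            i = j + 1
        elif c.isalpha() and c.isupper():
            letters = [c]
            i += 1
            while i + 1 < len(s) and s[i] == "/" and s[i + 1].isalpha() and s[i + 1].isupper():
                letters.append(s[i + 1])
                i += 2
            tokens.append(frozenset(letters))
        else:
            raise PatternError(f"unexpected character {c!r} in pattern {text!r}")
    return MotifPattern(tokens=tuple(tokens), region=region, text=text)


def render_pattern(pattern: MotifPattern) -> str:
    parts = []
    for t in pattern.tokens:
        if t in ("x", "."):
            parts.append(t)
        elif len(t) == 1:
            parts.append(next(iter(t)))
        else:
            parts.append("(" + "/".join(sorted(t)) + ")")
    return "".join(parts)


def _token_matches(token, residue: str) -> bool:
    if token in ("x", "."):
        return True
    return residue in token


def match_at(pattern: MotifPattern, seq: str, start0: int) -> bool:
    if start0 < 0 or start0 + len(pattern) > len(seq):
        return False
    return all(
        _token_matches(t, seq[start0 + k]) for k, t in enumerate(pattern.tokens)
    )


def match_in_window(pattern: MotifPattern, seq: str, lo0: int, hi0: int
                    ) -> Optional[int]:
    """First 0-based start in [lo0, hi0] where the pattern matches.

    The pattern must start inside the window; it may run past the window
    end (but not past the sequence)."""
    lo0 = max(lo0, 0)
    hi0 = min(hi0, len(seq) - len(pattern))
    for s in range(lo0, hi0 + 1):
        if match_at(pattern, seq, s):
            return s
    return None


# ---------------------------------------------------------------------------
# Region resolution


def _regions(p, topo: TopologyResult, config: MotifConfig) -> dict:
    """0-based inclusive (lo, hi) pattern-start windows for the named regions.

    Uses the first six detected segments when at least six are present,
    otherwise falls back to length fractions (approximate, used only for
    degraded sequences)."""
    n = len(p.sequence)
    tol = config.loop_tolerance
    out = {
        "full": (0, n - 1),
        "nterm": (0, config.nterm_scan - 1),
        "cterm": (n - config.cterm_scan, n - 1),
    }
    if topo is not None and topo.ntm >= 6:
        seg = [(s - 1, e - 1) for s, e in topo.segments[:6]]
        for k in range(6):
            out[f"tm{k + 1}"] = (seg[k][0] - tol, seg[k][1] + tol)
        loops = {"loopA": (0, 1), "loopB": (1, 2), "loopC": (2, 3),
                 "loopD": (3, 4), "loopE": (4, 5)}
        for name, (a, b) in loops.items():
            out[name] = (seg[a][1] + 1 - tol, seg[b][0] - 1 + tol)
    else:
        fr = lambda a, b: (int(a * n), int(b * n))
        out.update({
            "tm1": fr(0.08, 0.2), "tm2": fr(0.2, 0.3), "loopB": fr(0.28, 0.45),
            "tm3": fr(0.38, 0.5), "loopC": fr(0.48, 0.56), "tm4": fr(0.52, 0.64),
            "loopD": fr(0.6, 0.68), "tm5": fr(0.62, 0.75), "loopE": fr(0.7, 0.85),
            "tm6": fr(0.8, 0.92), "loopA": fr(0.16, 0.24),
        })
    out["tm2_loopB"] = (out["tm2"][0], out["loopB"][1])
    out["loopE_tm6"] = (out["loopE"][0], out["tm6"][1])
    out["tm5_loopE"] = (out["tm5"][0], out["loopE"][1])
    return out


def match_pattern(pattern: MotifPattern, p, topo: TopologyResult = None,
                  config: MotifConfig = DEFAULT.motif
                  ) -> tuple[bool, Optional[int]]:
    """Slide the pattern across its named region; returns (matched, 1-based
    start or None)."""
    regions = _regions(p, topo, config)
    if pattern.region not in regions:
        raise PatternError(f"unknown region {pattern.region!r}")
    lo0, hi0 = regions[pattern.region]
    s = match_in_window(pattern, p.sequence, lo0, hi0)
    return (s is not None, None if s is None else s + 1)


# ---------------------------------------------------------------------------
# NPA boxes


def _box_candidates(seq: str) -> list[tuple[int, str]]:
    """(0-based position, triplet) of every canonical or variant box."""
    out = []
    for i in range(len(seq) - 2):
        t = seq[i : i + 3]
        if t == "NPA" or t in NPA_VARIANTS:
            out.append((i, t))
    return out


def _pick_box(cands, lo0, hi0, expected0) -> Optional[tuple[int, str]]:
    inside = [(i, t) for i, t in cands if lo0 <= i <= hi0]
    for pool in ([c for c in inside if c[1] == "NPA"],
                 [c for c in inside if c[1] != "NPA"]):
        if pool:
            return min(pool, key=lambda c: (abs(c[0] - expected0), c[0]))
    return None


def find_npa_boxes(p, topo: TopologyResult,
                   config: MotifConfig = DEFAULT.motif) -> tuple[NpaBox, NpaBox]:
    """Locate the loop-B and loop-E boxes.

    Canonical NPA wins over variants; among equals the match nearest the
    expected loop position wins.  Search windows come from the detected
    topology when six segments are present and from length fractions
    otherwise (robust for truncated or helix-deleted pseudogene inputs).
    """
    seq = p.sequence
    n = len(seq)
    cands = _box_candidates(seq)
    tol = config.loop_tolerance
    if topo is not None and topo.ntm >= 6:
        seg = [(s - 1, e - 1) for s, e in topo.segments[:6]]
        b_lo, b_hi = seg[1][1] + 1 - tol, seg[2][0] - 1 + tol
        e_lo, e_hi = seg[4][1] + 1 - tol, seg[5][0] - 1 + tol
    else:
        b_lo, b_hi = int(0.20 * n), int(0.55 * n)
        e_lo, e_hi = int(0.55 * n), int(0.95 * n)
    pick_e = _pick_box(cands, e_lo, e_hi, (e_lo + e_hi) // 2)
    remaining = [c for c in cands if pick_e is None or c[0] != pick_e[0]]
    pick_b = _pick_box(remaining, b_lo, b_hi, (b_lo + b_hi) // 2)

    def mk(loop, pick):
        if pick is None:
            return NpaBox.absent(loop)
        i, t = pick
        return NpaBox(loop=loop, position=i + 1, triplet=t,
                      status="canonical" if t == "NPA" else "variant")

    return mk("B", pick_b), mk("E", pick_e)


# ---------------------------------------------------------------------------
# Anchored extraction


def _safe_residue(seq: str, idx0: Optional[int]) -> Optional[str]:
    if idx0 is None or not 0 <= idx0 < len(seq):
        return None
    return seq[idx0]


def _tm_start0(snapped: Optional[int], detected: Optional[int],
               tol: int) -> Optional[int]:
    if snapped is not None:
        if detected is None or abs(detected - snapped) <= tol:
            return snapped
        return detected
    return detected


def _detected_start0(topo, k: int) -> Optional[int]:
    if topo is not None and topo.ntm >= 6:
        return topo.segments[k - 1][0] - 1
    return None


def anchor_diagnostic_positions(p, topo: TopologyResult,
                                boxes: tuple[NpaBox, NpaBox],
                                config: MotifConfig = DEFAULT.motif
                                ) -> ResidueSignature:
    """Extract P1–P7 (and the ar/R tetrad) at the calibrated anchors.

    Requires the loop-E box; P2/P3 sit at fixed offsets after it, P4/P5 at
    fixed offsets into the last helix, and P1/P6/P7 around the conserved
    Gln of helix 3 (located by literal scan within the helix-3 window).
    """
    npa1, npa2 = boxes
    if npa2.status == "absent":
        raise ValueError("loop-E NPA box absent: diagnostic anchoring undefined")
    seq = p.sequence
    warnings: list[str] = []
    e0 = npa2.position - 1
    b0 = npa1.position - 1 if npa1.status != "absent" else None

    p2 = _safe_residue(seq, e0 + config.p2_from_npa2)
    p3 = _safe_residue(seq, e0 + config.p3_from_npa2)

    # helix 3 window and its conserved Q
    tm3 = _tm_start0(None if b0 is None else b0 + config.tm3_from_npa1,
                     _detected_start0(topo, 3), config.snap_tolerance)
    p1 = p6 = p7 = None
    if tm3 is None:
        warnings.append("helix 3 not located; P1/P6/P7 unset")
    else:
        window = range(max(tm3, 0), min(tm3 + 21, len(seq)))
        qs = [i for i in window if seq[i] == "Q"]
        if not qs:
            warnings.append("anchor Q not found in helix 3; P1/P6/P7 unset")
        else:
            expected_q = tm3 + config.q_from_tm3
            q0 = min(qs, key=lambda i: (abs(i - expected_q), i))
            p1 = _safe_residue(seq, q0 + config.p1_from_q)
            p6 = _safe_residue(seq, q0 + config.p6_from_q)
            p7 = _safe_residue(seq, q0 + config.p7_from_q)

    tm6 = _tm_start0(e0 + config.tm6_from_npa2, _detected_start0(topo, 6),
                     config.snap_tolerance)
    p4 = _safe_residue(seq, None if tm6 is None else tm6 + config.p4_from_tm6)
    p5 = _safe_residue(seq, None if tm6 is None else tm6 + config.p5_from_tm6)
    if p4 is None or p5 is None:
        warnings.append("last helix not located; P4/P5 unset")

    arR = extract_arR(p, topo, boxes, config=config, _warnings=warnings)
    n_hit, c_hit = scan_phospho_motifs(p, config=config)
    return ResidueSignature(
        npa1=npa1, npa2=npa2, p1=p1, p2=p2, p3=p3, p4=p4, p5=p5, p6=p6, p7=p7,
        arR=arR, n_term_motif=n_hit, c_term_motif=c_hit,
        warnings=tuple(warnings),
    )


def extract_arR(p, topo: TopologyResult, boxes: tuple[NpaBox, NpaBox],
                config: MotifConfig = DEFAULT.motif, _warnings=None
                ) -> tuple:
    """The ar/R tetrad (H2, H5, LE1, LE2)."""
    npa1, npa2 = boxes
    warnings = _warnings if _warnings is not None else []
    if npa2.status == "absent":
        warnings.append("loop-E box absent; ar/R unset")
        return (None, None, None, None)
    seq = p.sequence
    e0 = npa2.position - 1
    b0 = npa1.position - 1 if npa1.status != "absent" else None
    tm2 = _tm_start0(None if b0 is None else b0 + config.tm2_from_npa1,
                     _detected_start0(topo, 2), config.snap_tolerance)
    tm5 = _tm_start0(e0 + config.tm5_from_npa2, _detected_start0(topo, 5),
                     config.snap_tolerance)
    h2 = _safe_residue(seq, None if tm2 is None else tm2 + config.h2_from_tm2)
    h5 = _safe_residue(seq, None if tm5 is None else tm5 + config.h5_from_tm5)
    if h2 is None or h5 is None:
        warnings.append("helix 2 or 5 not located; ar/R partially unset")
    le1 = _safe_residue(seq, e0 + config.le1_from_npa2)
    le2 = _safe_residue(seq, e0 + config.le2_from_npa2)
    return (h2, h5, le1, le2)


# ---------------------------------------------------------------------------
# Phosphorylation motifs


def _load_table(name: str) -> pd.DataFrame:
    ref = resources.files("mipscan") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


_PHOSPHO = None


def phospho_motif_table() -> pd.DataFrame:
    global _PHOSPHO
    if _PHOSPHO is None:
        _PHOSPHO = _load_table("phospho_motifs.tsv")
    return _PHOSPHO


def scan_phospho_motifs(p, config: MotifConfig = DEFAULT.motif
                        ) -> tuple[Optional[MotifHit], Optional[MotifHit]]:
    """Scan the N-terminal (first 40) and C-terminal (last 30) regions for
    the known phosphorylation motifs; first table entry that matches wins."""
    seq = p.sequence
    table = phospho_motif_table()
    hits: dict[str, Optional[MotifHit]] = {"N": None, "C": None}
    for _, row in table.iterrows():
        terminus = row["terminus"]
        if hits[terminus] is not None:
            continue
        pattern = compile_pattern(row["pattern"])
        if terminus == "N":
            lo0, hi0 = 0, config.nterm_scan - len(pattern)
        else:
            lo0, hi0 = len(seq) - config.cterm_scan, len(seq) - len(pattern)
        s = match_in_window(pattern, seq, lo0, hi0)
        if s is not None:
            acc_idx = int(row["acceptor_index"]) - 1
            hits[terminus] = MotifHit(
                name=row["name"],
                match=seq[s : s + len(pattern)],
                start=s + 1,
                acceptor=seq[s + acc_idx],
            )
    return hits["N"], hits["C"]


# ---------------------------------------------------------------------------
# SDP substrate filters

_SDP = None

SUBSTRATES = ("ammonia", "boric_acid", "co2", "h2o2", "urea", "silicic_acid")


def sdp_filter_table() -> pd.DataFrame:
    global _SDP
    if _SDP is None:
        _SDP = _load_table("sdp_filters.tsv")
    return _SDP


def match_sdp_filters(p, topo: TopologyResult,
                      config: MotifConfig = DEFAULT.motif) -> dict:
    """Substrate -> bool; true iff all three of the substrate's region
    filters match.  Silicic acid has no filters in the family and is
    always false."""
    table = sdp_filter_table()
    result = {s: False for s in SUBSTRATES}
    for substrate, group in table.groupby("substrate"):
        ok = True
        for _, row in group.iterrows():
            pattern = compile_pattern(row["filter"], region=row["region"])
            matched, _ = match_pattern(pattern, p, topo, config)
            if not matched:
                ok = False
                break
        result[substrate] = ok
    result["silicic_acid"] = False
    return result


# ---------------------------------------------------------------------------
# Orchestration and alignment-based fallback


def extract_signature(p, topo: TopologyResult,
                      config: MotifConfig = DEFAULT.motif) -> ResidueSignature:
    """Boxes, P1–P7, ar/R and phospho motifs in one pass."""
    boxes = find_npa_boxes(p, topo, config)
    if boxes[1].status == "absent":
        n_hit, c_hit = scan_phospho_motifs(p, config=config)
        return ResidueSignature(
            npa1=boxes[0], npa2=boxes[1],
            n_term_motif=n_hit, c_term_motif=c_hit,
            warnings=("loop-E box absent; residue extraction skipped",),
        )
    return anchor_diagnostic_positions(p, topo, boxes, config)


def map_positions_through_alignment(query, reference, positions0,
                                    **align_kwargs) -> list[Optional[int]]:
    """Map 0-based reference positions onto a query via global alignment.

    Second extraction mode for real, indel-containing sequences: align the
    query against an ungapped reference of known geometry and read the
    diagnostic columns off the alignment.  Returns 0-based query indices
    (None where the reference column is deleted in the query).
    """
    from .msa_phylo import global_align

    aln, _ = global_align(reference, query, **align_kwargs)
    (_, gref), (_, gquery) = aln.rows
    ref_i = query_i = 0
    lookup: dict[int, Optional[int]] = {}
    for cr, cq in zip(gref, gquery):
        if cr != "-":
            lookup[ref_i] = query_i if cq != "-" else None
        if cr != "-":
            ref_i += 1
        if cq != "-":
            query_i += 1
    return [lookup.get(i) for i in positions0]
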