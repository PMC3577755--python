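"""Tunable parameters for the pipeline, grouped by module.

Every constant that the topology, motif and evolution modules rely on is
collected here so that a single config object can be threaded through the
pipeline (and overridden from a TOML file by the CLI).  Defaults are the
values the packaged synthetic scaffold was calibrated against; they are
sensible for real plant MIP sequences as well, but the anchor offsets are
scaffold geometry and should be re-calibrated for other scaffolds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass(frozen=True)
class TopologyConfig:
    """Hydropathy-based transmembrane segment detection.

    window:        Kyte-Doolittle smoothing window (odd, residues).
    threshold:     mean hydropathy above which a run counts as membrane-spanning.
    min_len:       shortest accepted segment (residues).
    merge_gap:     runs separated by fewer residues than this are merged.
    max_len:       longer runs are split at internal hydropathy minima.
    ntm_ok:        segment counts accepted as "six-helix" for full-length calls
                   (7 tolerated: several full-length family members report 7).
    full_length_range: plausible full-length polypeptide length window (aa).
    """

    window: int = 19
    threshold: float = 1.6
    min_len: int = 15
    merge_gap: int = 3
    max_len: int = 35
    ntm_ok: tuple[int, ...] = (6, 7)
    full_length_range: tuple[int, int] = (230, 330)


@dataclass(frozen=True)
class MotifConfig:
    """Anchor offsets for diagnostic-residue extraction.

    All offsets are 0-based and calibrated against the packaged scaffold
    geometry.  Helix reference starts are derived from the NPA boxes when
    present (the boxes are located by exact string scan and are therefore
    the most reliable anchors); detected hydropathy segments are the
    fallback when a box is missing.
    """

    # helix reference starts relative to the NPA boxes (residue indices)
    tm2_from_npa1: int = -31
    tm3_from_npa1: int = 20
    tm5_from_npa2: int = -29
    tm6_from_npa2: int = 22
    snap_tolerance: int = 6        # max |detected - snapped| to accept the snap
    # diagnostic residue offsets
    h2_from_tm2: int = 12          # ar/R H2 within helix 2
    h5_from_tm5: int = 12          # ar/R H5 within helix 5
    le1_from_npa2: int = -3        # ar/R LE1
    le2_from_npa2: int = 9         # ar/R LE2
    p2_from_npa2: int = 4          # Froger P2 (2nd residue after the box)
    p3_from_npa2: int = 8          # Froger P3 (6th residue after the box)
    p4_from_tm6: int = 3           # Froger P4 (4th residue of last helix)
    p5_from_tm6: int = 10          # Froger P5 (11th residue of last helix)
    q_from_tm3: int = 12           # expected anchor Gln offset within helix 3
    p1_from_q: int = -2
    p6_from_q: int = 6
    p7_from_q: int = 7
    nterm_scan: int = 40           # N-terminal phospho-motif search region
    cterm_scan: int = 30           # C-terminal phospho-motif search region
    loop_tolerance: int = 3        # slack added around loop regions when matching


@dataclass(frozen=True)
class EvolutionConfig:
    min_codons: int = 30           # minimum compared codons for a Ka/Ks call
    epsilon: float = 0.05          # |ratio - 1| tolerance for the neutral call


@dataclass(frozen=True)
class AlignConfig:
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "BLOSUM62"


@dataclass(frozen=True)
class Config:
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    align: AlignConfig = field(default_factory=AlignConfig)


DEFAULT = Config()


def from_mapping(mapping: dict) -> Config:
    """Build a Config from a nested mapping, e.g. parsed TOML.

    Keys follow the module grouping: ``{"topology": {"window": 21}, ...}``.
    Unknown keys raise ``ValueError`` so typos in config files surface early.
    """
    sections = {}
    for section_name, cls in (
        ("topology", TopologyConfig),
        ("motif", MotifConfig),
        ("evolution", EvolutionConfig),
        ("align", AlignConfig),
    ):
        values = dict(mapping.get(section_name, {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(
                f"unknown {section_name} config keys: {sorted(unknown)}"
            )
        for key in ("ntm_ok", "full_length_range"):
            if key in values and isinstance(values[key], list):
                values[key] = tuple(values[key])
        sections[section_name] = cls(**values)
    extra = set(mapping) - {"topology", "motif", "evolution", "align"}
    if extra:
        raise ValueError(f"unknown config sections: {sorted(extra)}")
    return Config(**sections)
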