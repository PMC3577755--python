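"""Transmembrane topology from hydropathy.

MIP channels are six-helix bundles; the pipeline predicts helices by
smoothing a Kyte–Doolittle hydropathy profile with a centered window and
calling maximal above-threshold runs, then uses the helix count, NPA-box
status and polypeptide length to decide whether a sequence is a plausible
full-length channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT, TopologyConfig

# Kyte & Doolittle (1982) hydropathy indices
KD_SCALE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class TopologyResult:
    """Detected transmembrane segments (1-based inclusive intervals)."""

    segments: tuple[tuple[int, int], ...]
    profile: np.ndarray

    @property
    def ntm(self) -> int:
        return len(self.segments)

    def loop(self, after_segment: int, before_segment: int) -> tuple[int, int]:
        """1-based inclusive interval between two detected segments."""
        start = self.segments[after_segment - 1][1] + 1
        end = self.segments[before_segment - 1][0] - 1
        return start, end


def hydropathy_profile(p, window: int = 19) -> np.ndarray:
    """Centered moving average of Kyte–Doolittle values.

    Near the termini the window shrinks to what is available, so the
    profile has one value per residue.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    seq = p.sequence
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 residues")
    values = np.array([KD_SCALE[c] for c in seq])
    half = window // 2
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    starts = np.maximum(np.arange(n) - half, 0)
    ends = np.minimum(np.arange(n) + half + 1, n)
    return (csum[ends] - csum[starts]) / (ends - starts)


def _split_long_run(start: int, end: int, profile: np.ndarray,
                    max_len: int) -> list[tuple[int, int]]:
    """Split a >max_len run at its deepest internal minimum, recursively."""
    if end - start + 1 <= max_len:
        return [(start, end)]
    interior = profile[start + 2 : end - 1]  # 0-based slice of interior
    k = start + 2 + int(np.argmin(interior))
    return _split_long_run(start, k - 1, profile, max_len) + _split_long_run(
        k + 1, end, profile, max_len
    )


def count_tm_segments(profile: np.ndarray,
                      config: TopologyConfig = DEFAULT.topology) -> TopologyResult:
    """Call transmembrane segments from a smoothed hydropathy profile.

    Maximal runs above ``threshold`` are found, runs separated by fewer
    than ``merge_gap`` residues are merged, runs shorter than ``min_len``
    dropped, and runs longer than ``max_len`` split at internal minima.
    """
    above = profile > config.threshold
    runs = []
    i = 0
    n = len(profile)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < config.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments = []
    for start, end in merged:
        if end - start + 1 < config.min_len:
            continue
        for s, e in _split_long_run(start, end, profile, config.max_len):
            if e - s + 1 >= config.min_len:
                segments.append((s + 1, e + 1))  # to 1-based inclusive
    return TopologyResult(segments=tuple(segments), profile=profile)


def predict_topology(p, config: TopologyConfig = DEFAULT.topology) -> TopologyResult:
    return count_tm_segments(hydropathy_profile(p, config.window), config)


def is_full_length(p, topo: TopologyResult, npa_status: tuple[str, str],
                   config: TopologyConfig = DEFAULT.topology
                   ) -> tuple[bool, list[str]]:
    """Full-length decision with reason codes.

    True iff the helix count is acceptable (6, tolerating 7), both NPA
    boxes are present or variant, and the length falls in the plausible
    full-length window.  Reasons: "ntm", "npa1", "npa2", "length".
    """
    reasons = []
    if topo.ntm not in config.ntm_ok:
        reasons.append("ntm")
    if npa_status[0] == "absent":
        reasons.append("npa1")
    if npa_status[1] == "absent":
        reasons.append("npa2")
    lo, hi = config.full_length_range
    if not lo <= len(p.sequence) <= hi:
        reasons.append("length")
    return (not reasons, reasons)
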