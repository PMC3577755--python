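# Methods

`mipscan` characterizes a plant MIP (major intrinsic protein / aquaporin)
gene family from sequence alone: subfamily and subgroup classification from
diagnostic residues, water-vs-glycerol functional typing, pseudogene
flagging, neighbor-joining phylogeny, Nei–Gojobori Ka/Ks, and ΔCt
expression calling.  This note records the models, the parameters that
matter, and the design decisions taken where the problem was genuinely
open.

## The sequence model

A MIP channel is a six-helix bundle with two re-entrant loops (B and E)
that each carry an NPA box; the pore constriction (the aromatic/arginine
or ar/R filter) is built from four residues at positions H2 (helix 2), H5
(helix 5), LE1 and LE2 (loop E, flanking the second box).  Five further
conserved residues (the Froger positions P1–P5) discriminate
water-transporting channels (AQP type) from glycerol facilitators (GlpF
type), and a pair of residues six and seven positions after the conserved
Gln of helix 3 (called P6/P7 here) separates the five plant subfamilies:

| subfamily | P6 | P7 | first box | second box |
|---|---|---|---|---|
| PIP | C/S/V | G | NPA | NPA |
| TIP | A/I/M/T/V | A | NPA | NPA |
| NIP | C/L/S | A | NPA (NPS) | NPA (NPV) |
| SIP | G/V | G | NPT/NPS | NPA |
| XIP | I | G | SPV/NPI | NPA/SPA |

The only genuinely ambiguous P6/P7 pair is (V, G), which fits both PIP and
SIP; it is resolved by the first box (SIPs never have a canonical NPA
there), then by the C-terminal phosphorylation motif class, then — if a
tree is supplied — by the nearest confidently assigned leaf.  This
precedence is the package's own; family classifications of this kind are
traditionally made by phylogeny plus manual inspection, which fixes no
explicit rule order.

Subgroups are an exact lookup of the ar/R tetrad in a packaged rule table
(`data/arr_subgroups.tsv`, 18 tetrads over 12 top-level subgroups:
1 PIP + 3 TIP + 4 NIP + 3 SIP + 1 XIP).  Two tetrads in the table are
reconstructed from described substitutions rather than an explicit tetrad (TIP IB's LE2 = Val;
the NIP IV tetrads) and are marked in the table's note column.  A
nearest-tetrad (Hamming) fallback is applied to non-exact tetrads and
flagged; ties stay unresolved.

Functional typing counts, over the non-null Froger positions, how many are
*compatible* with the AQP consensus and how many with the GlpF consensus
(a residue can be compatible with both).  At least two compatible
positions on each side makes the call "aquaglyceroporin"; otherwise the
larger side wins; fewer than three known positions is "unclassified".
Compatibility counting (rather than exclusive majority votes) is what
reproduces the observed pattern — every subfamily types as a water
facilitator except the NIPs, whose P1 (F) and P5 (L) are GlpF-compatible.

## Topology

Transmembrane segments come from a Kyte–Doolittle hydropathy profile
(window 19, centered, ends shrink), thresholded at 1.6: maximal
above-threshold runs, runs closer than 3 residues merged, runs shorter
than 15 dropped, runs longer than 35 split at internal minima.  These are
standard hydropathy-scan defaults; no parameterization is inherited from
external topology predictors.  A sequence is "full length" when
the helix count is 6 (7 tolerated — several genuine full-length members
report 7), both boxes are present or variant, and the length falls in
[230, 330] aa, a window bracketing the family table's full-length range (238–317).

## Anchoring the diagnostic residues

The NPA boxes are found by exact triplet scan (canonical NPA first, then
the variant set {NPS, NPT, NPV, NPI, SPV, SPA}) within the loop-B and
loop-E windows; the match nearest the expected loop position wins.  When
fewer than six helices are detected (truncated inputs), the windows fall
back to length fractions, which keeps box detection useful on degraded
sequences.

Residue extraction then anchors on the boxes, not on raw hydropathy
boundaries: helix reference starts are fixed offsets from the boxes
(helix 2 at box1 − 31, helix 5 at box2 − 29, helix 6 at box2 + 22, helix 3
at box1 + 20), and the diagnostic residues sit at fixed offsets from those
references (all configurable in `MotifConfig`).  The rationale: detected
threshold crossings jitter by a residue or two as loop composition varies,
while the boxes are exact sequence landmarks — in real MIP alignments the
loop B/E boxes are likewise the anchor columns.  Detected segment starts
are still used as a fallback when a box is absent, and a second,
alignment-based extraction mode (`map_positions_through_alignment`) maps
scaffold positions through a global alignment for indel-containing
sequences.  P1, P6 and P7 anchor on the conserved Gln of helix 3, located
by literal scan inside the helix-3 window with the candidate nearest the
calibrated offset winning.

The offsets are calibrated constants of the packaged scaffold geometry.
For sequences that do not follow that geometry the alignment mode is the
appropriate one; the anchor offsets should then be re-calibrated.

## Substrate (SDP) filters

The fifteen substrate filter strings (three region filters for each of
ammonia, boric acid, CO₂, H₂O₂ and urea) are shipped verbatim in
`data/sdp_filters.tsv` and compiled by a small pattern grammar: uppercase
letter = fixed residue, `x` = wildcard, `A/B` (with or without
parentheses) = alternatives, whitespace cosmetic.  A pattern matches if it
can start anywhere inside its named region (regions resolve from the
detected topology; loops get ±3 residues of slack, and a match may run
past the region end).  A substrate is called only when **all three** of
its region filters match — the conservative conjunctive reading (whether
one filter should suffice is not defined anywhere, so the strict rule is
used and documented).  Silicic acid
has no filters in this family and is always false.  Emphasis markings sometimes seen in published filter tables carry no
extra semantics here.

## Pseudogene flags

Reasons follow the family table's comment vocabulary: `npa1_missing` /
`npa2_missing` (a box absent), `npa_modified` (a box is a variant that the
called subfamily never carries, e.g. a PIP with NPS), `tm_missing` (fewer
than six helices while both boxes are intact — the "TM5 missing" pattern),
and `not_full_length` (the full-length rule fails for any reason).  A
sequence is a pseudogene candidate iff at least one reason fires.

## Phylogeny

Pairwise and profile alignment use an affine-gap Gotoh DP (BLOSUM62, gap
open 10, extend 0.5 — ClustalX-like defaults; configurable) with a fixed
traceback tie-break (diagonal > up > left) so results are deterministic.
The progressive MSA builds a UPGMA guide tree from 3-mer distances and
merges profiles leaf-to-root; profile columns are scored as
frequency-weighted BLOSUM sums.  Distances from the MSA use pairwise gap
deletion with p-distance (default) or Poisson correction
(d = −ln(1 − p)); there is no single canonical choice for family trees of
this kind, so both are offered with p-distance the default.  Neighbor joining is the standard Saitou–Nei agglomeration
with rate-corrected branch lengths, lowest-index tie-break, and negative
branch lengths clamped to zero with the deficit moved to the sister edge.
The root is an arbitrary trifurcation, so clade questions should use the
unrooted bipartition test (`is_unrooted_cluster`).  NJ on any additive
matrix reproduces the generating tree's path distances to 1e-9 (tested),
and the implementation is cross-checked against scikit-bio's NJ on noisy
matrices.

## Ka/Ks (NG86)

Synonymous site fractions per codon count, at each position, the share of
the three possible changes that preserve the amino acid; changes to stop
codons count as nonsynonymous.  Codons differing at more than one
position average their difference counts over all minimal substitution
paths, excluding paths that cross a stop codon (if every path does, the
average falls back to all paths so the pair still contributes).
Proportions are Jukes–Cantor corrected, d = −(3/4) ln(1 − 4p/3), undefined
at p ≥ 3/4.  The ratio is undefined when Ks = 0; the regime call is
positive (> 1), purifying (< 1) or neutral/mixed (|ratio − 1| ≤ ε,
ε = 0.05 by default — the qualitative "= 1" category made operational).
At least 30 compared codons are required by default.

Published per-gene values for this family came from unspecified software,
so they are comparable only qualitatively (<1 / >1), not numerically.  On
simulated neutral evolution the estimator averages ≈ 0.95: rejecting
stop-creating substitutions in the simulator slightly depresses the
realized nonsynonymous rate relative to NG86's site normalization.  This
small conservative bias is a known property of the counting method and is
why the neutral-calibration check uses a band ([0.9, 1.1]) rather than a
point.

## ΔCt expression

Relative expression is RE = 2^−(mean Ct_target − mean Ct_reference), with
replicates averaged on the Ct scale before exponentiation (the Winer ΔCt
convention).  Individual Ct values outside [15, 30] cycles are
unavailable and excluded; the window is applied uniformly to target and
reference replicates (the stricter of the two possible readings of the
validity rule).  Fold-change calls between time points are
descriptive — ratio > θ is "up", < 1/θ "down", θ = 2 by default — with no
attached test statistic, because none is defined for this design.

## The synthetic data generator

The generator emulates what the classification rules need from real MIPs:
six 21-residue hydrophobic helices (Ile/Val), hydrophilic loops, both
boxes, all diagnostic residues and motifs at fixed scaffold offsets, and —
per subgroup — the substrate filter instances, for all 66 family members
plus the 23 pseudogene lesions (box ablation/modification, helix deletion,
truncation; truncation lengths follow the family table's lengths where
those trip the full-length rule).  Subfamily geometries differ in N-terminal, loop C
and C-terminal lengths (242–290 aa, echoing the family table's range).  Loop fill
patterns are subfamily-specific permutations of the same residue sets, so
subfamilies carry lineage-marker residues and between-subfamily divergence
exceeds the within-subfamily spread — the property that makes the five
subfamilies recoverable as tree clades, as in the real family.

Randomness is confined to loop interiors at least 9 residues from any
helix boundary, mutating at 5% per position (default) within a
hydrophilic pool chosen so no spurious NPA variants, phospho motifs or
filter matches can arise; diagnostic positions never mutate.  Planted
truth therefore stays exact while extraction is exercised against noise.
Back-translation draws synonymous codons uniformly (no codon-usage bias —
irrelevant to NG86 counting).  CDS pair evolution proposes uniform base
changes, rejects stops, and accepts synonymous/nonsynonymous changes with
probabilities realizing the requested dN/dS, stopping at the requested
synonymous divergence.  Everything is seeded; identical seeds give
byte-identical output.

**What passing on synthetic data does and does not show.**  The generator
plants the published consensus residues at known offsets; recovery tests
therefore validate the *rules and their implementation*, not the rules'
biological accuracy on diverged real sequences.  Real MIPs have indels,
non-canonical helix lengths and noisier hydropathy; for those, the
alignment-based extraction mode and re-calibrated offsets are the intended
path, and results should be inspected alongside the evidence trail the
classifier records.

## Problem sizes and defaults used in checks

The shipped checks run the full 66 + 23 family for classification and
tree recovery, 50 replicates for dN/dS = 0.2 recovery (300-codon scale),
100 replicates × 500 codons for neutral calibration (target synonymous
divergence 0.2, where NG86 is well within its working range), and 100
noisy replicates for the ΔCt recovery and fold-change simulations — sizes
at which the Monte-Carlo standard errors are several times smaller than
the acceptance bands.

## Known limitations

- Offset-anchored extraction assumes the packaged scaffold geometry;
  indel-containing inputs need the alignment mode.
- The progressive MSA is a straightforward profile merger: no iterative
  refinement, no position-specific gap penalties.
- NG86 only; no maximum-likelihood (Goldman–Yang) models, no sliding
  windows.
- The generator has no indel process and no rate heterogeneity; it is a
  rule-embodiment harness, not a molecular-evolution simulator.
- Subcellular localization is transcribed from the family table, never
  predicted.
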