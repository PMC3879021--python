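# Methods

## Topology states

Input topology comes either as a per-residue posterior table (one
`(p_inside, p_membrane, p_outside)` triple per residue, the format TMHMM
emits) or as an explicit state TSV. From posteriors, a residue is `TM`
when `p_membrane > threshold` (default 0.9, strict comparison) and `nTM`
when the loop evidence exceeds the same threshold. Because inside and
outside are competing loop states, the default loop rule takes
`max(p_inside, p_outside)`; `ntm_rule = "sum"` is available for the
reading in which the two channels pool. Residues passing neither rule are
`ambiguous` — a third state of this package's own design, excluded from
both TM segments and nTM statistics, since behaviour between the two 90%
rules is otherwise undefined. `ambiguous` breaks helix runs exactly as
`nTM` does, so a segment is always a maximal run of confidently
membrane-assigned residues.

All file dialects are 1-based inclusive; memory is 0-based half-open.

A Kyte–Doolittle sliding-window fallback (`hydropathy_fallback`, window
19, cutoff 1.6 — the classic values for transmembrane detection) provides
deterministic states when no posterior table exists. It is a convenience
stand-in, not a topology predictor of publication quality.

## Motif extraction

An XYn motif fixes anchors X at offset *i* and Y at *i + n* and leaves
the *n − 1* residues between them free; `LG5` therefore means leucine and
glycine separated by four variable residues. Extraction is the exhaustive
window scan: one occurrence per (offset, n) pair that fits the segment,
for every n in `n_range` (default {4, 5, 6, 7}), overlaps all kept. For
an 'X'-free segment of length L the yield is exactly
`Σ_n max(0, L − n)`, which the test suite uses as an analytic oracle.
Windows containing the unknown residue 'X' anywhere are dropped and
logged, so 'X' can never contaminate anchor or variable-position
statistics. Motifs are extracted per segment and never cross a segment
boundary.

Hub motifs in reduced graphs are often written with the variable-position
count rather than the X→Y index difference (the same motif as `LL3` vs
`LL4`). The canonical label here always uses the index difference;
`label_convention = "gap"` switches exported text to the other numbering,
and `n_range` is fully configurable, so either reading of such outputs
can be reproduced without touching code.

## Motif-architectures

The statistical frame is a chain of exactly four motif occurrences in one
TM segment with no residue gap: each motif starts on the residue after
the previous one ends (`offset_{k+1} = offset_k + n_k + 1`). Enumeration
indexes occurrences by start offset and extends chains depth-first;
output order is deterministic (start offset, then lexicographic length
composition). Every (start, composition) path counts separately — there
is no overlap suppression and no collapsing of equal label tuples; the
graph layer aggregates multiplicity instead. The frame size is exposed as
`architecture_size` (default 4). Under the default `n_range`, an
architecture spans 20–32 residues, so a helix shorter than 20 confident
residues contributes none.

The independent counting oracle `count_architectures` sums
`max(0, L − span(c) + 1)` over all length compositions c; the test suite
checks it exhaustively against enumeration for L = 0…60 and against a
tuple-level brute force at small L.

## Graphs

Each architecture contributes its four motifs as nodes and its three
consecutive pairs as weight-1 edge increments (identical consecutive
labels accumulate on a self-loop). Per-segment graphs are the sum of
their architectures' graphs; the main graph merges all segment graphs.
Two merge semantics exist because "increase the weight by one" is
ambiguous at the merge stage: `sum` (default) adds per-segment weights,
preserving architecture multiplicity and giving the testable conservation
law *total edge weight = 3 × number of architectures*; `presence` counts
the number of segments containing the edge. The chosen mode is recorded
in the run manifest.

Reduction keeps edges with `weight ≥ edge_threshold` and then removes
nodes that lost their last incident edge (pre-isolated nodes survive, so
threshold 0 is the identity). No default threshold is baked in — the
sensible value depends entirely on dataset size — so `run` exports the
unreduced graph plus a weight histogram unless `edge_threshold` is given
explicitly.

Hub score = weighted in-degree + weighted out-degree (self-loops counted
twice), capturing "participates in many architectures with many
partners"; fancier centralities are deliberately out of scope. Edge
colours are equal-width bins over [min, max] weight (top bin = heaviest /
"red"); `bin_mode = "frequency"` switches to quantile bins. Exports:
GraphML (lossless round trip), DOT, and a flat edge TSV, all carrying
`topology_state`, `occurrence_count`, `weight`, and `color_bin`.

## Log-odds profiles and topology prediction

For each (motif, state) pair the residues at variable positions are
tallied from occurrences harvested separately from TM segments and from
maximal nTM runs (the same extractor runs on both, so both states'
statistics are symmetric by construction). With counts `k_pa` over `N`
occurrences, background `q_a`, and pseudocount `c` (default 1.0):

    LOP[p][a] = log2( ((k_pa + c·q_a) / (N + c)) / q_a )

Base-2 logs and background-proportional pseudocounts are the standard
sequence-profile conventions; both the base and the pseudocount are
config keys since other conventions differ only there. A pseudocount of 0
recovers raw log-odds and is rejected when any count is zero.

The background ("nature occurrence") table can be the empirical residue
frequency of the input dataset (default; +1 pseudocount per residue), a
packaged Swiss-Prot average composition, or a user TSV.

Per-motif prediction: each profile's strength is its observed-frequency-
weighted mean log-odds, `S = Σ_p Σ_a f(a,p) · LOP[p][a]` with
`f = k/N`; the predicted state is the argmax of the two strengths, exact
ties unclassified. When only one state's profile exists the motif is
assigned that state only if backed by at least `min_occurrences`
occurrences (default 5) — the guard that lets a motif seen only in loops
be called `nTM` while a handful of chance matches stays unclassified. All
four evidence numbers (both scores, both counts) are exported per motif
so users can re-threshold downstream.

A deliberate limitation of this decision rule: for a motif observed in
*both* states, each strength is essentially the divergence of that
state's variable-position composition from the shared background, so the
comparison reflects the compositions, not the motif's occurrence balance
— and sparsely observed minority profiles overestimate their own
strength. The rule is therefore most meaningful for state-exclusive or
strongly skewed motifs, which is exactly the regime the parameter-
recovery experiment probes: it synthesises, per motif, ≥200 occurrences
in a single generating state (variable positions i.i.d. from that state's
composition table) and requires ≥90% of motifs to be classified back to
that state. Defaults pass at 100%. Re-weighting the decision by
occurrence counts is a possible extension, left out to keep the exported
scores interpretable as pure profile strengths.

## Synthetic data

The generator emulates the structure the pipeline assumes and nothing
more: proteins alternate loop / helix / … / loop; helix lengths 18–28,
loop lengths 5–40, 1–7 helices per protein (seven-helix bundles being the
canonical polytopic family); residues i.i.d. from a hydrophobic-enriched
helix table (elevated A, L, V, I, G, F; Jensen–Shannon divergence to the
loop table ≈ 0.14 bit) and a polar-enriched loop table (elevated S, N, P,
Y, D, K). Architectures can be planted: anchor residues are written at
the chained offsets of a randomly chosen, non-overlapping stretch of a
helix and the location is recorded in a truth table, giving an exact
recall target for the whole pipeline. Optional posterior emission puts
probability 1 on the true channel (loops alternate inside/outside), so
state assignment inverts it exactly.

One `numpy` generator seeded from the single config seed drives all
sampling; identical config + seed gives byte-identical files. Not
simulated, by design: helical periodicity, amphipathic patterning,
evolutionary correlation between positions, and sequence redundancy.
Passing tests on this data therefore validates the machinery (counting,
chaining, merging, conservation, recovery), not biological conclusions
about real membrane proteomes.

## Pipeline and reproducibility

`motifgraph run` executes parse → assign → segment → extract → enumerate
→ per-segment graphs → main graph → profiles/classification → annotate →
(optional) reduce → export, failing atomically with a stage-named error
and removing partial outputs. The JSON manifest embeds the full config,
SHA-256 digests of the inputs, and counts at every stage; every manifest
number is recomputable from the exported tables, and repeated runs on
identical inputs are byte-identical (no timestamps anywhere).

`scripts/acceptance.py` regenerates all headline quantities from scratch
at a given seed. Problem sizes used there: 1,000 random segments for the
occurrence oracle, L = 1…60 for the architecture oracle, a 500-protein
dataset (~390k architectures) for the conservation ratio and graph-size
figures, a 10-planting fixture for recall, 40 motifs × 200 occurrences
for profile recovery, and 200 random graphs for the merge/filter algebra
— sizes at which every quantity is stable while the whole script runs in
well under a minute on one core.

## Numerical and edge-case choices

- Strict `>` at the 0.9 posterior threshold; 0.9 exactly is ambiguous.
- Posterior triples must sum to 1 ± 0.02 (tolerance for rounded files).
- Empty segments, empty graphs, and empty datasets are valid inputs to
  every operation that can meet them, returning empty results; errors are
  reserved for contract violations (bad probabilities, duplicate
  positions, gapped chains, oversized plantings).
- Hub ties break alphabetically; single-weight graphs put all edges in
  the top colour bin.
- The `X` unknown residue is legal in sequences but quarantined from all
  statistics (occurrence windows containing it are dropped).
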