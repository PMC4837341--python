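# Methods

## The layered network model

All evidence layers share one container: an undirected graph whose nodes
carry a *set* of roles from {component, target, pathway_protein, metabolite}
and whose edges are typed (component-target, protein-protein,
pathway-metabolite), provenance-tagged (text, dock, curated) and optionally
confidence-weighted. Role sets rather than single labels matter because a
protein can be both a candidate drug target and a member of a metabolite's
enriched pathway; such dual-role nodes participate in both capacities during
traversal. Networks are stored undirected; the semantic direction
(component → protein → metabolite) is imposed only at traversal time by the
roles, which keeps the layer unions trivial (node-role union, edge
deduplication on endpoints + type with provenance union; when the same edge
arrives with two confidences the larger is kept).

## Dock-score cutoff

Docking evidence is reduced with the positive-control rule: each protein's
cutoff is the dock score of its co-crystallized ligand, and a component
passes only if its score *strictly* beats that cutoff in the engine's
favorable direction. Score orientation is declared per engine
(`greater_better` for scoring functions that maximize, `lesser_better` for
energy-like scores) and must be supplied explicitly — there is no safe
cross-engine default. Comparisons are exact by default; a `tolerance`
parameter exists for engines with coarse score grids and defaults to 0.
The rule is invariant under order-preserving affine rescaling of
(score, control) pairs, which the tests check.

## PPI filtering and MPPI construction

Protein-protein edges are kept when their combined confidence is strictly
above `min_conf` (default 0.8, the conventional "high confidence" level).
STRING-style integer exports (0–1000) are auto-detected — any score above 1
triggers division by 1000, logged — so both export dialects load unchanged.

For the metabolite layer, every (metabolite, pathway) enrichment row with
p strictly below `alpha` (default 0.05) contributes the pathway's member
proteins as pathway-protein nodes linked to the metabolite. Members are then
extended to their PPI neighbors. "Nearest neighbors" is taken as exactly one
hop in the confidence-filtered PPI — the add-interactors convention — with
the depth exposed as `neighbor_depth` for sensitivity analysis. The same
0.8 confidence level is used for the extension as for the target-protein
interactions by default; the two thresholds are separate parameters.

## Prioritization semantics

A target t is retained iff (i) at least one component-target edge touches t
and (ii) a metabolite is reachable from t along protein-protein edges that
stay within protein-role nodes, followed by a single pathway-metabolite
edge. A dual-role target sitting directly on a pathway-metabolite edge
satisfies (ii) with a length-1 path. Retention is decided by reachability
rather than path enumeration — on realistic networks the number of simple
paths explodes combinatorially while reachability is linear — but one
witness path per retained target is recorded for explainability, found by
breadth-first search with lexicographically ordered neighbor expansion, so
the witness is the deterministic shortest. Paths may pass through other
target-role nodes (they are proteins too); the evidence record flags when a
witness does. Re-entering the component layer is forbidden: components are
initial nodes only. Output order is descending component-degree, ties
lexicographic; the underlying method defines an unordered set, and the fixed
order only aids diffing.

The published analysis this generalizes reports both 25 and 26 retained
targets in different sections for its own dataset; the discrepancy is left
unadjudicated here and does not affect the semantics.

Component-degree strata for enrichment profiling are 1–9 (low), 10–19
(middle) and ≥ 20 (high); the upper band is open-ended because the observed
maximum in any one dataset is not a cap.

## Over-representation analysis

The enrichment statistic is the upper-tail hypergeometric probability
P(X ≥ k), the one-sided Fisher exact equivalent, which is what the common
enrichment servers compute; `fisher_enrich` is an alias. The background
defaults to all distinct genes in the annotation table and can be overridden
with an explicit universe. Raw p-values with a strict p < alpha "key" flag
mirror the conventional report; Benjamini–Hochberg correction is available
behind `bh_correction` as a clearly labeled extension, off by default.

## Chemical space

The seven descriptors (molecular weight, aromatic rings, H-bond donors,
H-bond acceptors, topological polar surface area, rotatable bonds, logP) are
computed with RDKit; the logP is RDKit's Crippen value and is reported as
the toolkit's native estimate, since atom-contribution parameterizations
differ across software. Descriptor tables may also be ingested precomputed.
PCA runs on centered, unit-variance-scaled columns because the descriptors
carry incommensurate units; whether to autoscale was a genuinely open choice
and the raw-covariance alternative is one flag away in any downstream use of
the returned loadings. The sign indeterminacy is fixed by orienting each
loading so its largest-magnitude entry is positive. Constant columns are
centered but not scaled.

Drug-likeness comparison runs, per descriptor, the two-sided two-sample
Kolmogorov–Smirnov test (distribution) and the two-sided Wilcoxon rank-sum /
Mann–Whitney test (location). The rank-sum form is the two-*sample* one: the
compared compound sets are independent, so the paired signed-rank variant
would be wrong. Exact null distributions are used up to n = 20 per side,
asymptotic (with continuity correction for the rank-sum) above.

Similarity screening uses circular (Morgan) fingerprints, radius 2, 2048
bits — the de-facto standard family — configurable in both parameters, with
the Tanimoto threshold inclusive (≥ 0.85 retains a pair at exactly 0.85).
Unparseable structures are collected into a per-record error report instead
of aborting the screen.

## Assay data reduction

Percentage inhibition is the linear rescue of optical density between the
TNF-α-only control (0%) and the no-TNF-α control (100%); the value is not
clamped, so responses beyond either control are visible, and the formula is
invariant under a common offset on all three ODs. Equal controls are a
degenerate-input error.

The binding fit is the steady-state 1:1 Langmuir isotherm
R(C) = R_max·C/(K_D + C), least squares over individual points (replicates
are not pre-averaged; an averaging helper exists for the users who want it).
Initialization is R_max⁰ = max response and K_D⁰ = the concentration nearest
half-max, which is robust for geometric dilution designs; bounds keep both
parameters positive and the optimizer runs to tolerances of 1e-12, well
inside the 1e-8 relative-parameter contract. Kinetic k_on/k_off fitting from
full sensorgrams is out of scope — only the equilibrium constant is modeled.
All-zero responses are rejected (R_max at the boundary leaves K_D
unidentifiable). The default `dilution_series()` is 6.25–400 in two-fold
steps, i.e. seven concentrations. No confidence interval on K_D is emitted
by default (the SSE is); a bootstrap would be the natural extension.

## Synthetic data: what it emulates and what it does not

`generate_fixture` produces a full input bundle with a planted set of
connected targets. Ground truth is enforced *constructively*: every planted
target gets at least one component edge and a PPI backbone edge into the
pathway-protein layer, every pathway protein is a member of one enriched
pathway, and each metabolite owns one enriched (p ~ U(0.001, 0.045)) and one
non-enriched (p ~ U(0.06, 0.95)) pathway. Decoy targets alternate between
the two failure modes — component edge but no metabolite path, and the
converse (the latter receive only sub-cutoff dock records). Random extra PPI
edges are drawn only inside node groups that cannot create an accidental
component-to-metabolite route, which guarantees the planted truth without
rejection sampling and therefore terminates by construction. The generator
verifies the invariant by running the full pipeline before returning.

Defaults mirror the motivating study's layer sizes — 48 components, 61
candidate targets (25 connected), 44 pathway proteins, 13 metabolite
biomarkers — so the default integrated network at the four reduced layer
sizes (48/25/44/13) has 130 nodes. Edge probabilities: dock hit rate 0.12
and text hit rate 0.10 per (component, edge-bearing target) pair, giving a
component-target density near the observed ~0.19; PPI density 0.04 with
confidences U(0.81, 0.99), i.e. above the 0.8 filter. Structures for
synthetic components are drawn from the pool of vetted SMILES in the
packaged catalog so the chemistry operations stay exercisable.

What the simulation does **not** emulate: realistic per-protein docking
score distributions, correlated text-mining and docking evidence, scale-free
PPI topology, metabolite chemistry, or annotation-term hierarchies. Passing
the planted-truth suites therefore validates the *integration and
prioritization semantics* — that the pipeline retains exactly the targets
that connect components to metabolites — not the biological accuracy of any
particular evidence source.

The packaged catalog transcribes the 48-compound table; SMILES are included
only for the 21 compounds whose RDKit-computed molecular formula exactly
matches the printed formula, and the structure field is empty otherwise
(chemistry operations skip such rows with a warning; network operations keep
them).

## Numerical and scale choices

Strictness everywhere the thresholds appear (dock cutoff, PPI > 0.8,
enrichment p < 0.05, key flag) follows the stated rules exactly; all
filters are monotone in their thresholds and property-tested as such.
Problem sizes in the test and acceptance suites — 200 random ≤ 40-node
networks against a simple-path enumeration oracle, exhaustive hypergeometric
enumeration for universes up to N = 12, 50 study-scale planted bundles, 200
noisy binding replicates — were chosen to exercise the combinatorial oracles
exhaustively at sizes where they are exact while keeping the default suite
in the seconds-to-minutes range on one CPU.

## Known limitations

- Protein identifiers are opaque case-sensitive strings; no gene-symbol
  normalization or cross-database id mapping.
- No GO DAG propagation or ontology-aware enrichment; annotation tables are
  flat.
- No diffusion, random-walk or edge-weight propagation scoring — retention
  is plain connectivity, by design.
- No docking execution, no live STRING/MetaboAnalyst/TTD queries, no
  text-mining NLP: those upstream results are ingested as tables.
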