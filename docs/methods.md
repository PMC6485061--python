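# Methods

## The problem

Eph receptors (the largest receptor tyrosine-kinase subfamily) and their
membrane-attached ephrin ligands diverge quickly outside bilaterians: in
sponges, cnidarians, ctenophores and choanoflagellates the homologs share as
little as ~25% identity with well-annotated family members, gene models are
frequently fragmentary, and the ephrin receptor-binding domain is a
cupredoxin-fold β-sandwich that has lost the copper-binding site of its
relatives. This package implements the inference chain needed to find and
characterise such proteins from sequence alone, and a synthetic proteome
generator that makes every stage testable against planted ground truth.

## Profile-HMM engine

The engine (`ephscan.profilehmm`) is a match/insert/delete profile HMM with
the seven transition groups {M→M, M→I, M→D, I→M, I→I, D→M, D→D} plus begin
entries {B→M₁, B→D₁}; there is no insert state after the last match and no
multi-hit J state. Scoring is **glocal**: the model must be traversed
begin-to-end while the sequence flanks are free, which matches per-domain
envelope reporting; multiple domains per target are found by iterated
score-and-mask. Scores are log₂-odds against a fixed average amino-acid
composition (Swiss-Prot release statistics, embedded). Insert emissions
equal the background, so inserted residues are score-neutral — this
stabilises small-family profiles. All arithmetic is in log space; every
probability is floored at 1e-9 after smoothing and renormalised.

Construction: alignment columns with non-gap fraction ≥ 0.5 (default)
become match states; match emissions are observed counts plus
`pseudocount_weight` × background, normalised; transitions come from the
observed state paths with Laplace (+1) smoothing per group. `build_profile`
defaults to `pseudocount_weight = 1.0`. Viterbi and Forward use one
vectorised recursion per match state, with the insert self-loop solved as a
running max (or running log-sum) along the sequence, so scoring is
O(M·L) with O(L)-sized vector operations.

Viterbi and Forward were verified against exhaustive enumeration of all
legal paths on hundreds of randomly built models with ≤ 3 match states and
sequences of ≤ 5 residues (1e-9 relative agreement).

### E-values

Profiles are calibrated by scoring 200 i.i.d. background sequences of
length 400 (defaults; the seed is recorded in the profile) and fitting a
Gumbel law by the method of moments: λ = π/(σ√6), μ = mean − γ/λ. Then
E(s) = N·(1 − exp(−exp(−λ(s−μ)))) with N the number of target sequences in
the searched set (per-search convention, not per-residue). On 1000
background sequences the empirical counts of hits at E ≤ 1 and E ≤ 10 are
Poisson-consistent (checked in the test-suite).

## Iterative search

`ephscan.itersearch` mirrors the two-round iterative strategy: a seed
search (round 0), then rounds that (1) merge previously accepted hit
envelopes into the alignment — envelope subsequences only, deduplicated at
90% identity against rows already present — (2) rebuild and recalibrate the
profile, and (3) re-search the database at E ≤ 0.01. Rounds therefore
search with a profile that already contains the previous round's
discoveries, which is what extends reach into remote tiers.

Two design choices matter for sensitivity:

* **Depth-proportional pseudocounts.** Rebuilds inside the iteration use
  `pseudocount_weight = κ × (alignment rows)`. With plain Laplace-scale
  pseudocounts, a deep alignment keeps emissions so sharp that a
  25%-identity homolog scores below background mismatch penalties; scaling
  the pseudocount mass with depth softens emissions toward the background
  as divergent members accumulate (the same reasoning behind PSI-BLAST's
  depth-scaled pseudocounts). κ is exposed; the default was chosen on
  development panels separate from the validation panels.
* **Envelope-only merging** keeps domain profiles domain-sized even when
  hits sit inside multi-domain proteins.

Redundancy removal is greedy incremental clustering in the CD-HIT style:
sequences sorted longest-first, each joining the first representative at or
above the identity threshold (global alignment, match 1 / mismatch 0 /
linear gap −1; identity = matches / alignment length). The general default
threshold is 0.9; 0.4 reproduces the coarser clustering used for
fast-evolving surface-antigen superfamilies.

## Architecture grammar

Hits on one protein are resolved greedily by ascending E-value (ties:
higher bit score, then leftmost start); a hit is kept iff it overlaps every
kept hit by at most 10% of the shorter envelope. Classes:

* `EPH_FULL` — LBD is the most N-terminal domain (start before all others
  and within the first 35% of the protein) and a tyrosine-kinase domain
  starts C-terminal to every extracellular (LBD/fn3) domain. SAM/PDZ
  absence never blocks the call, since C-terminally truncated gene models
  are common.
* `PROTO_EPH_LIKE` — kinase + fn3 + TM, no LBD.
* `EPH_PARTIAL` — LBD without a correctly placed kinase.
* `EPHRIN` — ephrin-RBD domain, no kinase.
* `CUPREDOXIN` — cupredoxin-fold domain with a copper-competent site.
* `OTHER` — everything else (including copper-lost cupredoxins without an
  ephrin-RBD call, and decoys).

The CRD is the LBD→fn3 gap when it is at least 40 residues wide — the
shortest sushi+EGF region exceeds typical linkers, and the bound is a
documented constant, not an inference. Disulfide-bridge QC checks that
cysteines occupy annotated bridge columns of the profile-anchored
alignment.

## Membrane anchoring

TM consensus: five sub-predictors (Kyte–Doolittle windows 15–23, threshold
1.6), position-wise votes, consensus = runs of ≥ 15 positions with ≥ 3
votes. A helix is C-terminal when it ends within 40 residues of the
terminus (the quantitative boundary is a package choice; the qualitative
rule is standard). GPI anchoring requires BOTH of two independent
heuristics: an omega-site scan (small residue with two small successors in
the last 40 residues, followed within 25 residues by a window-11
hydrophobic stretch reaching the terminus) and a composition test (no
charged residue in the last 15, mean hydropathy of the last 12 ≥ 1.5, a
small-residue triplet in the last 40). When GPI is called, the stretch
C-terminal of the omega site is treated as the anchor propeptide — it is
removed on anchoring in vivo — so TM segments are truncated at the omega
position and kept only if a helix-length stretch remains; without this the
propeptide itself registers as a C-terminal TM and every GPI-only ephrin
would be typed DUAL. Subtypes: B ⇔ C-terminal TM ∧ ¬GPI; A ⇔ GPI ∧
¬C-terminal TM; DUAL ⇔ both; UNANCHORED ⇔ neither.

## Copper-site scanning

Azurin-numbered annotations (G45, H46, C112, H117, M121) on one reference
row of the cupredoxin seed alignment are mapped to match-state indices;
a hit is `COPPER_COMPETENT` iff H/C/H occupy the three required columns,
`COPPER_LOST` on any substitution there, `UNMAPPABLE` if a required column
is deleted. Only the invariant triad decides the verdict; the two
comparatively variable positions are recorded for inspection. Mapping goes
through the profile alignment rather than structure superposition — a
documented surrogate for structure-based alignment, adequate because the
generator and the QC tests hold the mapped columns fixed.

## Phylogenetics

Distances on profile-anchored rows: p = mismatches over co-ungapped
columns, d = −ln(1 − p − 0.2p²) (Kimura's protein correction), capped at
p = 0.85 (d ≈ 5.20) where the correction diverges. Trees are canonical
neighbor joining (Saitou–Nei Q-criterion; ties broken by the
lexicographically smallest id pair; negative branch lengths clamped to zero
with the deficit moved to the sibling). NJ recovers additive matrices
exactly (property-tested to 12 taxa, and cross-checked against scikit-bio's
implementation). Lineage-specific expansions are maximal bipartition sides
whose leaves share one lineage, with a minimum clade size (default 3);
`compare_domain_trees` tabulates per-lineage expansion counts of the LBD
tree against the kinase tree. NJ replaces ML/Bayesian inference
deliberately: it is deterministic, desk-scale, and sufficient for
clade-count contrasts on synthetic panels; no bootstrap support is
computed, so expansion detection is purely topological.

## Synthetic panels and what they do (not) show

The generator plants: families evolved from random background consensus
sequences (each site substituted with probability = divergence, always to a
different residue, so expected identity is exactly 1 − divergence; indels
at a per-site rate), architectures assembled with 15–60-residue linkers,
21-residue TM helices drawn from strong hydrophobics, 15-residue GPI
signals (omega + two small residues + hydrophobic tail, drawn from
uncharged candidates so planted signals satisfy both GPI heuristics),
copper-intact (H/C/H held fixed) or copper-lost (Q/S/Q planted) cupredoxin
domains, whole-domain N-/C-terminal truncation of a chosen fraction of
multi-domain proteins, and background decoys. Linkers avoid hydrophobic
runs longer than 8 and always carry a charged residue near their end, so
soluble termini never mimic TM helices or GPI tails — planted labels stay
re-detectable by construction. One master seed drives everything through
per-protein derived streams; identical specs give byte-identical panels.

What passing on these panels does **not** show: real proteomes have
composition biases, repeats, signal peptides, alternative isoforms and
assembly artifacts that the generator does not emulate; real domain
families have correlated (not i.i.d.) substitution patterns, which makes
remote homologs both harder (conserved blocks only) and easier (motif
anchors) than the uniform-divergence model used here. Accuracy numbers on
panels are a validation of the machinery, not a performance claim on real
data.

## Problem sizes

The validation suite uses: tiered-search panels with a 180-residue seed
family (8 members at divergence 0.1), 12 homologs per tier planted at
exactly 60/40/25% identity to the consensus (fixed substitution counts, so
each tier is homogeneous at its stated identity) embedded in 60-residue
flanks, and 200 decoys of 250–450 residues, over 10 replicate panels; classification panels of ~40 proteins
across three lineages; 1000 background sequences for calibration checks;
100 random additive matrices (≤ 12 taxa) for NJ. These sizes were chosen
as the smallest panels that still exercise every rule of each stage.

## Known limitations

* Uniform sequence weighting and single-component background pseudocounts
  (no Dirichlet mixtures); sensitivity below ~20–25% identity degrades
  accordingly.
* Glocal-only alignment: a profile cannot match a proper sub-range of its
  match states, so domains truncated mid-domain score poorly (whole-domain
  truncation is the generator default for exactly this reason).
* Method-of-moments Gumbel calibration is accurate to a few-fold in E
  around the 0.01 cutoff; it is not a substitute for exhaustive empirical
  calibration.
* The GPI and TM heuristics are surrogates for dedicated predictors and
  carry fixed, documented thresholds; they are tuned for the generator's
  signal model, not for proteome-scale screening.
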