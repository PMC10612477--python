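# Methods

## Model

All likelihood work is done on the 61 sense codons of the universal genetic
code. The instantaneous rate from codon i to codon j (i ≠ j) is

    q_ij = 0                      if i and j differ at more than one nucleotide
    q_ij = π_j                    synonymous transversion
    q_ij = κ π_j                  synonymous transition
    q_ij = ω π_j                  nonsynonymous transversion
    q_ij = ω κ π_j                nonsynonymous transition

with diagonal entries set so rows sum to zero. κ is the
transition/transversion rate ratio, ω = dN/dS, and π the equilibrium codon
frequencies. The chain is time-reversible (π_i q_ij = π_j q_ji), so
transition probabilities P(t) = exp(Qt) are computed through a symmetric
eigendecomposition of diag(√π) Q diag(1/√π), and tree likelihoods are
invariant to the placement of the (trifurcating) root.

**Scaling.** A single generator is scaled so −Σ π_i q_ii = 1 (branch lengths
in expected substitutions per codon). In mixture models every class shares
one common factor — the mixture-average rate of the background-branch
generators — so classes keep their correct relative speeds; per-class
scaling would erase the rate contrast between purifying and selected
classes. For branch/branch-site models the same background-mixture factor is
used; since branch lengths are free parameters re-optimized under every
model, the choice of factor only reparameterizes lengths and does not affect
maximized likelihoods.

**Site models.** ω varies over sites through finite mixtures: M0 (one
ratio); M1a (ω₀ ∈ (0,1) with proportion p₀, ω₁ = 1); M2a (adds ω₂ ≥ 1);
M3 with three free classes; M7 (beta-distributed ω, discretized into 10
equal-probability categories represented by their exact category means via
the incomplete beta function); M8 (beta plus a spike at ω_s ≥ 1); M8a
(the spike fixed at 1). Site likelihoods mix pruning likelihoods over
classes; pruning uses per-node rescaling in linear space with accumulated
log scalers, and site patterns are compressed before computation.

**Branch and branch-site models.** One terminal branch at a time is marked
foreground. The branch model (BR2) gives foreground and background separate
free ω; its null is M0 (df 1). The branch-site model is Model A — classes
(0) ω₀ on all branches, (1) ω = 1 on all branches, (2a/2b) background ω₀ or
1 with foreground ω₂ ≥ 1, proportions p₀, p₁, and (1−p₀−p₁) split
proportionally between 2a and 2b — tested against the same model with
ω₂ = 1 (df 1). These are the standard nested pairs; the df-1 χ² reference
for the two boundary tests (M8a-vs-M8, branch-site) is conservative, and a
50:50 χ²₀:χ²₁ mixture reference is available by flag.

**Test schedule and FDR.** Per cluster: M0 vs M3 (df 4), M1a vs M2a (df 2),
M7 vs M8 (df 2), M8a vs M8 (df 1); per foreground branch of gated clusters:
BR2 vs M0 and Model A vs its null (df 1 each). 2ΔlnL is clamped at 0
(a deficit below −0.01 triggers an optimizer-failure warning).
Benjamini–Hochberg is applied within each comparison family across clusters
(a pooled mode exists); the paper-facing "positive selection call" requires
both a significant M1a-vs-M2a or M7-vs-M8 test (q < 0.05) and a
positive-class ω̂ > 1, guarding against significance driven by non-selection
misfit. Clusters enter the branch/branch-site stage iff one of those two
site comparisons is significant after FDR.

**Site identification.** Naive empirical Bayes at the MLEs:
P(class k | site) ∝ p_k L(site | k), with the ω > 1 class(es) summed
(class 2 for M2a, the spike for M8, classes 2a+2b for Model A). Sites with
posterior ≥ 0.95 are reported, in original (pre-cleaning, 1-based codon)
alignment coordinates. Full Bayes empirical Bayes integration over
parameter uncertainty is not implemented in this version; requesting it
raises an explicit error. NEB posteriors at MLEs are anti-conservative for
small data sets; treat site lists on short alignments with caution.

## Upstream stages

**Input validation.** CDS and peptide FASTA per species must have identical
header sets (first whitespace-delimited token) — a hard error otherwise.
Terminal stop codons are stripped; records failing the 3×length rule,
containing internal stops, or not translating to their peptide (X matches
anything; N codons translate to X) are excluded per record with a logged
reason. N-containing codons are treated as missing data and removed with
gapped columns before likelihood work.

**Orthology.** All-vs-all cross-species Smith–Waterman (BLOSUM62, gap open
11 / extend 1, minimum score 50, minimum identity 25% — BLAST-like
conventions) feeds a reciprocal near-best-hit graph: for each (gene, target
species) the near-best set keeps hits scoring ≥ 0.95 of the best, and an
edge requires reciprocity. Near-best (rather than strict best) retention is
what lets a recent within-species duplicate join its family's component so
the one-to-one rule can reject the cluster; strict best-hits would silently
drop the paralog and mask the violation. Connected components become
clusters if they span ≥ 3 species with exactly one gene each;
paralog-bearing components are discarded, not trimmed. No spectral
re-partitioning is applied: rejected-if-paralogous makes further splitting
moot for emitted clusters. A precomputed tabular hit file can replace the
native search on large inputs.

**Alignment.** Peptides are aligned progressively: pairwise global
affine-gap alignments (BLOSUM62, −10/−0.5) give p-distances for an NJ guide
tree; profiles are merged by profile–profile dynamic programming with
average-of-pairs scores. The aligner is deterministic and does not attempt
phylogeny-aware gap placement; an externally produced protein alignment can
be imported instead. Back-translation threads each validated CDS through
its aligned row (residue → source codon, '-' → '---'), so degapping always
reproduces the CDS exactly. Codon columns containing any gap or N are then
removed (complete deletion, the default; configurable), keeping an index
map so reported sites refer to original coordinates; clusters with < 10
surviving codon columns are skipped with a logged reason.

**Gene trees.** Kimura-corrected protein distances
(d = −ln(1 − p − 0.2p²), capped at 5 when p ≥ 0.85) feed Saitou–Nei
neighbor joining with lowest-index tie-breaking and negative length
estimates clamped to 0; on additive matrices the generating tree is
recovered exactly. NJ lengths serve only as optimizer starting values —
every model re-estimates branch lengths. Trees are written as Newick
(".dnd", 6 significant digits, optional " #1" foreground mark) and as a
Nexus TREES block with a translate table; a user can replace the tree in a
cluster archive with a pruned species tree and re-fit (the subgroup
validation workflow).

## Optimization

Each fit maximizes lnL jointly over κ, the class parameters, and all branch
lengths with box-constrained L-BFGS-B on transformed coordinates (log scale
for κ, ω and beta shapes; stick-breaking in (0,1) for proportions; log
branch lengths in [1e-6, 50]). Bounds: κ ∈ [0.01, 100], free ω ∈ [1e-4, 50],
ω restricted to (0,1) where the model demands it, ω₂/ω_s ∈ [1, 50], beta
shapes ∈ [0.005, 99]. Convergence uses a relative-lnL tolerance of about
1e-11 with a gradient tolerance of 1e-7; default 2–3 seeded starts (the
first from defaults, later ones jittered). Alternatives in nested pairs are
warm-started from their null's optimum (with ~1e-8 of mixture mass or
ω − 1 perturbation where the null sits on the alternative's boundary), so
2ΔlnL ≥ 0 up to round-off by construction. Frequency parameters (default
F3x4 from the cleaned alignment, floored at 1e-6 and renormalized) are not
counted as free parameters, keeping LRT degrees of freedom at the standard
schedule; np = model free parameters + branch lengths.

## Pipeline mechanics

Clusters are independent work units processed from a queue (process pool;
`threads` workers). The per-cluster RNG seed is CRC32(global seed, cluster
id), so results do not depend on scheduling order, and result CSVs are
byte-identical across worker counts at a fixed seed. A cluster failure is
recorded in the run manifest and never aborts the run. Archives
(`Results/<id>.tar.gz`) hold alignments, trees, fit JSON, and a PAML-style
control file for manual cross-checks.

## Simulator

The bundled simulator draws root codons from the equilibrium frequencies,
assigns each site a mixture class, and evolves sequences branch-wise by
sampling from the exact transition matrices — matching the engine's
distributional assumptions rather than an event-level process. Alignments
are therefore gap-free; gap handling is exercised by synthetic gap
injection in the alignment tests, and real-data features such as
alignment error, indels, recombination, and compositional heterogeneity are
deliberately absent — passing simulation tests validates the inference
machinery, not robustness to those artifacts. Defaults chosen once as
realistic study conditions: a balanced 5-taxon tree with terminal branches
0.3 and internal branches 0.15 expected substitutions per codon (a
moderately divergent clade; 3/4/6-taxon variants scale the same shape),
κ = 2, purifying truth ω = 0.3 (M0) or p₀ = 0.7, ω₀ = 0.2 (M1a), and an
M2a condition with 20% of sites at ω₂ = 4. Gene families for pipeline
tests add per-species losses and within-species duplicates evolved along a
short 0.05-substitution branch — close enough to trigger near-best-hit
co-clustering and hence the one-to-one rejection rule deterministically.
The bundled 3-species example uses 300-codon families with one family under
ω₂ = 6 on half of a 50% selected+neutral mass so that the site-model gate
and branch scan are exercised end to end.

## Problem sizes in validation runs

The statistical checks run at sizes chosen to give stable estimates on a
single CPU: 20 replicates × 500 codons for M0 recovery; 100 replicates ×
100 codons for null calibration of M1a-vs-M2a; 50 replicates × 300 codons
for power and NEB detection; exhaustive-oracle comparisons on ≤ 4 taxa ×
≤ 5 codon sites (the brute-force sum over internal states grows as 61^k).
The acceptance script re-runs the same studies at reduced replicate counts
as a fast smoke-reproduction; its JSON records the sizes used.

## Known limitations

- NEB site posteriors ignore parameter uncertainty (no BEB); under
  moderate divergence and a 20% selected class, the average fraction of
  truly selected sites reaching posterior 0.95 plateaus well below one even
  at the true parameters — an information ceiling of the posterior itself.
- The progressive aligner is not phylogeny-aware; systematic alignment
  error propagates into selection tests, as with any fixed-alignment scan.
- One genetic code (universal); no within-site rate variation beyond the
  ω mixtures; no separate per-branch dN and dS decomposition.
- Connected-component clustering can chain distinct families through weak
  near-best links on very dense proteomes; the one-to-one filter rejects
  such chains rather than splitting them.
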