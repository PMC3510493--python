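# Methods

This note records the models, numerical choices and design decisions behind
`srnascreen`, and what the synthetic benchmark does and does not establish.

## Energy model

All thermodynamics run on a self-contained nearest-neighbour parameter set
(`src/srnascreen/data/default_energy.yaml`, version 1) rather than any
third-party table, so the pipeline's logic is reproducible from this
repository alone.  Its components, all in kcal/mol at 310.15 K
(RT = 0.0019872 × T ≈ 0.6163):

* a 6×6 stacking table over the canonical pairs, generated from a per-pair
  strength rule E(p₁,p₂) = −(s(p₁)+s(p₂))/2 with s(GC)=2.9, s(AU)=1.1,
  s(GU)=0.8 — symmetric under strand reversal by construction;
* affine loop penalties: hairpin 4.8 + 0.10·n (n ≥ 3), bulge 5.0 + 0.5·n,
  interior 4.6 + 0.5·(n₁+n₂), multiloop 3.8 + 0.4·branches + 0.1·unpaired;
* duplex initiation 4.1 for intermolecular helices;
* interior/bulge loops capped at 10 unpaired nt per side (larger loops get
  infinite energy), identically in folding and hybridization.

The loop interruption penalties are deliberately set so that breaking a
helix costs roughly what two to three average stacks gain.  With much
cheaper loops the *minimum-energy* duplex between two ~150-nt random
sequences degenerates into a chain of 2–3-bp micro-helices spanning the
whole region; with the shipped values optimal duplexes on random background
are compact (≈ 8–45 nt), matching the size of genuine regulatory sites.
Alternative tables with the same YAML schema can be supplied everywhere a
model is accepted.

## Folding engine

`thermo` implements the inside recursion over nested structures (canonical
pairs, minimum hairpin loop 3, lonely pairs allowed, no pseudoknots,
optional base-pair span limit defined as j−i ≤ max_span, forced-unpaired
constraints).  Z includes the open chain, so Z ≥ 1 always.

* Interval accessibility is the constrained-ensemble ratio
  Pu(I) = Z(I unpaired)/Z; the opening penalty is ED = −RT ln Pu.
  Pu(∅) = 1 by convention; Pu = 0 signals an unusable site (infinite ED).
* Pair probabilities are computed exactly as
  P(i,j) = (Z − Z with (i,j) forbidden)/Z, one inside recursion per queried
  pair, evaluated lazily.  The screen itself never needs them; they exist
  for diagnostics and for the enumeration cross-checks in the test suite.
* Arithmetic is plain float64.  With the default parameters the largest
  Boltzmann factor per stack is ≈ e^{2.9/0.616}, so Z for a ≤ 120-nt window
  stays far below float64 overflow; a guard raises with advice to fold
  locally if a global fold would overflow.
* The kernels (inside recursion and duplex DP) are numba-compiled; the pure
  Python enumeration oracles in `tests/oracles.py` are the independent
  check (agreement to 1e−9 relative on randomized sequences, including
  span limits and constraints).

### Local folding and window policy

The published procedure folds mRNA regions locally in a 100-nt window with
a 50-nt maximal pair span.  Two window policies are implemented:

* `local_accessibility_profile` — RNAplfold-style: Pu of each probe
  interval averaged over all windows containing it, windows sliding by
  1 nt, truncated (never padded) at sequence ends.
* the screen's ED/ΔPu terms default to a *single window centered on the
  queried interval* (`ScreenConfig.window_mode="single"`).

The averaged scheme systematically overestimates the accessibility of
long-range stems: windows that contain one arm but not its partner see the
position as unpaired.  Measured on the synthetic sRNA, a stem interval with
true Pu ≈ 10⁻²³ under the span-capped ensemble received window-averaged
Pu ≈ 0.16 — enough to defeat the accessibility veto entirely.  The centered
single window keeps every potential partner (≤ max_span away) of the
interval's midpoint in view and restores the veto.  Both modes and the
averaging grid (`window_step`, default 5 when averaging) are configurable.

## Interaction prediction

`hybridize` finds the minimum-E_hybrid antiparallel duplex that contains a
seed of ≥ 8 consecutive base pairs (GU allowed in the seed by default;
`SeedSpec(allow_gu=False)` excludes it).  The DP computes, for every pair
(i,j), the best duplex ending there and the best extension starting there;
anchoring a seed window between the two halves yields the optimum with a
guaranteed, structurally verified seed.  Ties break deterministically:
longer pairing, then smaller target start, then smaller sRNA start.
Reported sites must have E_hybrid < 0.

Accessibility is attached afterwards (E_total = E_hybrid + ED_sRNA +
ED_mRNA, an exact decomposition), and only sites with E_total < 0 count as
screening evidence: a duplex whose partner surface is buried in stable
intramolecular structure is not a credible interaction.  This veto is what
lets the negative controls reach zero calls without any tuned energy
cutoff.

The multi-site scan is greedy: discover the best remaining site, attach ED,
and if the site is vetoed, mask only those paired positions of the blocking
side whose own per-position Pu < 0.5, then rescan.  Masking the whole
interval would be wrong: the optimum duplex often chains an accessible
linker surface to adjacent stem segments, and the accessible sub-segment
must stay available.  Accepted sites claim their target interval; scanning
stops after `max_sites` acceptances or a bounded number of rescans.

## RBS location

The ribosome-binding site is located by hybridizing an anti-Shine–Dalgarno
probe (default CCUCCU, window −20‥−4 relative to the start codon, seed 4)
and taking the minimum duplex energy; calls at or below −3.5 kcal/mol are
flagged significant.  Whether the genome-wide RBS predictor this stage
stands in for used hybridization energies or a position-weight model is not
publicly described; the free-energy scan is this package's declared,
transparent choice, and probe, window and threshold are all configurable.

## Screening semantics

* Candidate selection: max(fold, 1/fold) ≥ 3 (boundary inclusive), plus the
  rank-1 ORF of any operon containing a selected gene.  Operon structure is
  a required input, never inferred.
* Search region: [TSS ‥ start+99] when the 5′-UTR is known, else
  [start−200 ‥ start+99]; truncated with a warning when the CDS is short.
* Repression: the site's target interval need only *overlap* −39‥+19
  (boundaries inclusive; positions are start-codon-relative with +1 the
  first codon nt and no position 0).  Masking any part of the ribosome
  footprint can block initiation; a `contained` toggle provides the
  stricter reading.
* Activation: "upstream of the RBS" is strict ordering (site 3′ end <
  RBS 5′ end), which keeps the two branches disjoint.  "After the
  interaction" is modelled as constrained folding with the site's target
  positions forced unpaired — a standard occupancy proxy, isolated in one
  operation (`rbs_accessibility_change`).  ΔPu is evaluated on the located
  RBS interval itself; `rbs_probe_extension` widens it toward the codon.
* Multiple sites: each branch uses the best (lowest E_total) site passing
  its positional test.  Direction comes from the expression table
  (mutant/wt; fold ≥ 1 counts as up).  No multiple-testing correction is
  applied — thresholds are pass/fail filters, matching the screen this
  package operationalizes.

## Synthetic data: what it emulates, and what it shows

`make_srna` builds a 191-nt sRNA: stem–loops SL1 (12 bp stem, 4-nt loop,
nt 1–28) and SL2 (13 bp/5 nt, 29–59), a 39-nt single-stranded linker
(60–98), SL3 (22 bp/5 nt, 99–147) and a 44-nt 3′ tail, with processing cut
sites annotated at 65/60/55.  Structural choices that make the generator
*verifiable*:

* the linker is purine-only ({A,G}, 30% G), so no canonical pair of any
  span can form within it; it carries a fixed AGGAGGAAG "activation word";
* stems are GC-biased random complementary arms; SL3's 5′ arm is drawn from
  {G,U} so its 3′ arm is G-free, and the tail is poly-C, which can pair
  only with G runs — neither the pyrimidine target sites nor a neutralized
  linker provide any;
* the generator checks its own contract with the folding engine (mean
  linker Pu ≥ 0.9, mean stem Pu ≤ 0.3 under the default span-capped
  ensemble) and deterministically resamples stems until it holds.

Planted targets are exact reverse complements of linker subsequences placed
at controlled start-codon-relative positions; the start codon is always
preserved, so straddling sites are planted as blocks around +1‥+3 and the
truth table records each block with its linker source.  Activation targets
place the reverse complement of the activation-word window in the 5′-UTR;
its 3′ end (CUUCCUCCU) sequesters a downstream planted RBS in a 9-bp
hairpin, so the release mechanism is physically realized: forcing the site
single-stranded raises Pu(RBS) from ~10⁻⁴ to near 1.

The default benchmark holds 50 genes: 5 repression targets (one as rank 2
of a bicistronic operon whose head gene is neutral), 3 activation targets,
10 down-stream/off-window decoy sites, 2 genes with unknown TSS (exercising
the 200-nt fallback) and neutral background; effects are 5-fold with
multiplicative lognormal noise (σ = 0.2 by default; the noise-free variant
is the canonical recovery condition).  All outputs are pure functions of
(spec, seed).

**Negative control.**  The linker-neutralized sRNA replaces the linker by
poly-U (`linker_mode="polyU"`), the analogue of replacing the targeting
domain by poly-T on the coding strand.  A compositional shuffle
(`"shuffled"`) is also available but is *not* a zero-interaction control: a
shuffled purine tract still pairs pyrimidine-rich sites (every U on the
mRNA side accepts either purine), a point worth remembering when designing
real scrambled-sequence controls.

**What passing means.**  The benchmark demonstrates that the pipeline's
logic — seed DP, accessibility veto, positional filters, RBS-release
computation, operon pull-in, scoring — is correct and self-consistent under
a known ground truth.  It does not demonstrate biological accuracy on real
transcriptomes: real sRNA sites are imperfect (planted ones are exact
complements), real 5′-UTR structure is not uniform-random background, the
energy model is not a fitted Turner set, and expression noise in real
microarrays is not purely multiplicative-lognormal.  Published interaction
energies from other tools are not comparable number-for-number, since they
depend on that tool's parameter tables.

A residual stochastic failure mode is documented rather than hidden: in a
minority of random backgrounds the planted RBS can be alternatively
sequestered by a chance complementary tract, in which case opening the
planted site barely changes Pu(RBS) and the activation gene is (correctly,
given the physics) not called.  The canonical benchmark seed is free of
this coincidence; across arbitrary seeds activation recall is ≈ 0.7–1.0
while repression recall and decoy specificity are stable at 1.0 and 0.

## Problem sizes and runtime

Test-suite and acceptance-script sizes are chosen for tight feedback:
enumeration cross-checks use ≤ 18-nt sequences (hundreds of cases),
duplex-oracle comparisons ≤ 15 nt per partner (hundreds of pairs), and
end-to-end runs use the 50-gene benchmark, where a full screen takes about
a second on one CPU.  The engines themselves handle the pipeline's native
sizes (191-nt sRNA, ≤ 300-nt search regions) directly.
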