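# Methods

## The model

`ferredup` analyses internal tandem duplication in small proteins, with the
2[4Fe-4S] ferredoxin of *Clostridium pasteurianum* (55 residues) as the
worked example. The molecule is treated as the concatenation of two halves
descended from a single ancestral peptide: the first half spans residues
1..⌊L/2⌋ (27 for L = 55) and the second the remainder (28). Evidence for
the duplication is accumulated along four routes:

1. **Coincidences.** The halves are aligned column-wise and the number of
   *coincidences* k — columns carrying the identical residue on both sides —
   is compared with a composition-preserving null. The worked example uses a
   prescribed pairing that anchors the four cysteines of each half on one
   another (a uniform offset of two positions); this register yields k = 12
   identities among 26 paired columns, drawn from 7 amino-acid types.
   Unknown residues ('X') never count as identities.
2. **Significance.** The default null freezes the column pairing and
   shuffles the second half's residues within the aligned columns, so
   composition is preserved exactly. The reported p-value is the add-one
   estimator (1 + #{k_perm ≥ k_obs})/(1 + B), which can never return 0. An
   analytic route computes E[k] = Σ_a n·p_a·q_a from the two halves' letter
   frequencies with a Poisson-binomial tail, and an exact route enumerates
   all distinct rearrangements for alignments of ≤ 10 paired columns. A
   stricter null that re-aligns (ungapped) after each shuffle is available
   behind the `realign_split` argument.
3. **Ancestral consensus.** One consensus position per alignment column:
   SHARED where the halves agree; RESCUE where a rescue residue (serine by
   default, configurable) occurs in either cell of a disagreeing column;
   UNDETERMINED otherwise, rendered as '-'. The ferredoxin example gives the
   27-position consensus `----ADSC-SCG-CAS-CPV-A-SQ--`. The consensus is
   mined for letters recurring at a fixed period and reduced against a short
   repeating motif (ADSG), partitioning determined positions into conforming
   and non-conforming sets.
4. **Spacing signatures.** For an anchor residue (cysteine by default) the
   ordered list of intervening-residue counts is extracted; a tandem
   duplication leaves the within-half gap lists identical. The ferredoxin
   signature CX2CX2CX3C X18 CX2CX2CX3C is symmetric under the 27/28 split.

The forward (predictive) counterpart replays an event script — DOUBLE,
MUTATE (validated against the current residue), SEGDUP, DELETE — from a seed
motif. The packaged scenario doubles ADSG into a 27-residue proto-repeat
whose motif frame restarts at position 15, mutates it into a
consensus-consistent pre-duplication ancestor, tandem-duplicates with a
one-residue junction duplication, and mutates into the extant 55-residue
molecule. The script is a synthetic reconstruction constrained by those
way-points, not a transcription of any published figure.

## Periodicity and the midpoint break

For each residue with at least `min_support` (default 3) determined
occurrences, every candidate period 2..L/2 is scored by the longest run of
consecutive occurrences spaced exactly that period apart; the largest run
wins and ties go to the smallest period (so a period-3 signal is never
reported as period 6). A *break* is a position where the progression's
phase shifts, reported as the position immediately after the last occurrence
of the interrupted run. In the worked example the cysteines occupy
consensus positions 8, 11, 14, 18: a period-3 progression broken at
position 15, immediately past the consensus midpoint.

## Chronology

Domain families carry SCOP concise classification strings
(class.fold.superfamily.family; superfamily-level prefixes allowed) and
relative ages as node distances nd ∈ [0, 1] (0 = origin of proteins, 1 =
present). The clock of folds is a piecewise-linear interpolation through
anchor points; the default two-anchor clock (nd 0 → 3.8 Gy, nd 1 → 0 Gy)
reproduces the published nd↔Gy pairs of the worked families to one decimal
(0.287 → 2.7 Gy, 0.515 → 1.8 Gy) and is overridable. Evolutionary phases
are right-open nd windows with admissible Venn groups (superkingdom/virus
sharing patterns), shipped as editable YAML; boundaries between the
published worked examples are interpolated. Loop prototypes inherit ages
from their mapped domain families: the default *first-transfer* rule takes
the second-smallest mapped nd (the age at which the loop first appears in a
second scaffold, which reproduces the published age 0.279 for the oldest
ferredoxin loop prototype); an *oldest* rule (smallest nd) is also
implemented. Residue intervals are assigned to the N- or C-terminal half
with the same ⌊L/2⌋ midpoint convention as the sequence split.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: an
ancestral half drawn i.i.d. from a 20-letter frequency vector (uniform by
default; the serine frequency can be overridden), tandem-duplicated, then
every site of each copy substituted independently with probability μ —
always to a *different* residue drawn from the renormalised frequencies, so
μ is the realised per-site change probability and truth bookkeeping is
exact. Closed form under this model:

E[k]/L = Σ_a q_a [ (1-μ)² + μ² Σ_{b≠a} (q_b/(1-q_a))² ]

(1/19 collision term for uniform frequencies at μ = 1). Randomness flows
from one seed through spawned per-replicate streams, so each replicate is
individually reproducible. The generator has no indels, no rate
heterogeneity across sites and no phylogenetic structure; passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to alignment error or heterotachy in
real families.

## Numerical and design choices

- **Split point**: ⌊L/2⌋, first half shorter on odd lengths — this is what
  makes the ancestral consensus 27 residues long for L = 55.
- **Ungapped aligner ties**: smallest offset wins (determinism); property
  tests check equality with the exhaustive offset scan.
- **Permutation seed**: default 1966, a mnemonic only.
- **Type-I calibration**: the null rejection rate of the permutation test is
  checked at α = 0.05 over 2000 replicates of shuffled-half nulls with
  half length 1000 and B = 199 shuffles. The alignment length matters: the
  add-one estimator is conservative on a coarse k-lattice, and shorter
  alignments push the null rejection rate visibly below α; at length 1000
  the lattice is fine enough that the rate sits within 3 Monte-Carlo
  standard errors of α. Power analyses use smaller halves where the effect
  is the object of interest rather than calibration.
- **Degenerate inputs**: empty halves, empty motifs, all-undetermined
  consensi, single-mapping loop prototypes and non-covering phase configs
  all raise or warn explicitly rather than returning silent defaults.

## Known limitations

- The historical half pairing and event script are figure-only in the
  sources that describe them; the packaged fixtures are reconstructions
  pinned by the printed constraints they satisfy (cysteine anchoring, k = 12
  / 7 types, the 27-residue consensus, the extant end-point of the replay).
  Two printed figure-derived counts — 13 ADSG-conforming ancestor positions
  and an alanine cycle of four in the ancestor — are not reproducible from
  the printed sequence under the stated reconstruction rules; the package
  reports what the rules actually yield (4 conforming; no period-4 alanine
  progression in the consensus, though the forward proto-repeat does carry
  alanines in exact cycles of four around the frame restart).
- The analytic p-value treats columns as independent Bernoulli draws, which
  is an approximation to the permutation (fixed-composition) null; it is
  exposed for expectation checks, and the permutation route is authoritative.
- Phase windows between published example nds are interpolations; the clock
  is linear by default and should be re-anchored for serious absolute-age
  work.
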