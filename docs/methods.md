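# Methods

## Setting

The package analyses site-saturation mutagenesis carried out in parallel
across protein homologs.  The motivating system is the LacI/GalR family of
bacterial transcription repressors: a panel of chimeric homologs sharing the
LacI DNA-binding domain is mutated at the nonconserved linker positions
(45–62 in LacI numbering), and each variant's repression of the *lac* operon
is measured as β-galactosidase activity in Miller units.  Lower activity
means tighter repression; the "DEL" control (no repressor present) is the
weakest possible value any variant can reach (MIN), and 13 Miller units is
the growth threshold below which changes in repression alter growth on
lactose minimal medium.  Repression is read out in the effector condition in
which the parent represses: without effector for inducible repressors, with
effector for co-repressible (PurR-based) chimeras.

## Distinguishability and normalization

All classification rests on one distinguishability rule.  Two measurements
(mean ± sd over independent colonies) **change** when the means differ
strictly more than 2-fold AND their mean ± sd intervals are disjoint.  The
rule is symmetric and reflexively false.  A variant is **at MIN** when it is
not changed relative to the DEL control (treated as exact, sd 0).  Variant
effects are expressed as fold change = parent mean / variant mean, so values
above 1 are enhanced repression.  Activities of exactly zero are clamped to
half the smallest positive value in the profile before forming ratios (the
assay bottoms out; ratios must exist).  Repeat clones of the same variant
are merged by geometric mean of means and pooled sd; pairs differing more
than 2-fold are flagged in the warnings stream but still merged.

## The position classifier

For one (homolog, position) with n scored substitutions the gates run in a
fixed order; the first that fires assigns the code.

1. **`#`** — n < `min_substitutions` (default 5; typical yield in this kind
   of screen is 8–12 substitutions per position, so 5 is a conservative
   floor).
2. **`x`** — every substitution at MIN.
3. **`N`** — every fold change in [0.5, 2]; **`n`** — every fold change in
   [0.2, 5] but not all in [0.5, 2].  The 2-fold band is the assay's
   equivalence band; ~5-fold is the conventional outer edge of "small".
4. **Clusters** — sorted log10 activities are split at gaps ≥ `cluster_gap`
   (0.7, i.e. 5-fold, the same scale as the `n` band edge).  Exactly two
   clusters with the tighter one inside the parent's 2-fold band and the
   weaker one entirely at MIN → **`T`**.  Exactly three clusters, each
   internally tight (span ≤ 0.3 log10) → **`3`**.  The internal-tightness
   requirement separates genuinely discrete states from a sparsely sampled
   continuum.
5. **MIN-subset hybrids** — when ≥ 3 substitutions sit at MIN, those values
   are censored at the assay floor and are removed before measuring the
   span of the remainder: remainder span > 2 decades and progressive →
   **`R+T`**; span > 0.7 → **`r+T`**.
6. **`R`** — full span log10(max/min) > 2 and progressive.  Progressivity
   requires the largest adjacent gap to be ≤ `gap_fraction` (0.62) of the
   span, so no single break dominates the ladder.
7. **`N+R` / `N+r`** — at least half the substitutions neutral, the rest
   reaching beyond the 5-fold band (span > 2 → `N+R`).
8. **`n/r`** — span in (0.7, 0.95]: between neutral and rheostat (a ~5–9
   fold range).
9. **`r`** — span in (0.7, 2].
10. Fallbacks for cells the rules above leave open: span ≤ 0.7 (tight but
    straddling a strict band edge) → `n`; span > 2 but non-progressive with
    no hybrid structure → `R`.

The call is invariant under re-ordering of the input measurements and under
common rescaling of all activities (parent, DEL and variants) by a positive
factor, because every gate works on ratios and log-differences.

Enhancement statistics count, per position across homologs, substitutions
whose fold change exceeds 10; the percentage is
enhanced / (total variants − parents mutated), rounded half-up, with each
mutated parent counted once among the total.  This reproduces all twelve
published percentage values from their printed numerators and denominators.

### Allosteric response

A variant matches its parent's allosteric behavior when, in the inactive
condition, it either (i) induces to the DEL level (indistinguishable from
DEL) or (ii) maintains the parent's response ratio ρ = inactive/active
(its inactive value is indistinguishable from active·ρ, sd scaled by ρ).
A substitution is flagged as allostery-altering only when neither holds;
missing conditions yield an undetermined flag, never a false.  By default
parents are taken to induce fully to DEL; a measured parent inactive state
can be supplied per homolog.

## Sequence entropy and tiering

Column conservation is the gap-inclusive Shannon entropy
H = −Σᵢ₌₁²¹ fᵢ ln fᵢ in nats over the 20 amino acids plus one gap symbol;
ambiguity codes are counted as gap after a logged warning.  H ranges from 0
(perfect conservation) to ln 21 ≈ 3.04.  Sequences are unweighted.  Motif
subsetting (e.g. the YPAL residues Y47/P49/A53/L56) keeps exactly the
sequences carrying every required residue — matching is exact-letter and
case-insensitive, and a gap at a motif position is a mismatch.  Columns are
positional: membership changes never renumber the column map, so positions
stay comparable across nested sets even when the reference sequence itself
is dropped.  Tier labels on the motif-subset entropies use H < 0.1 for
toggle candidates and H ≥ 0.6 for rheostat candidates (ties follow the
inequality directions; a position printing exactly 0.60 is a rheostat
candidate), anything between is intermediate.

## Outcome cross-tabulation

Per (position, amino acid) across homologs, against the motif-subset MSA
frequencies: `A` requires frequency exactly 0 and fold change ≥ 0.5 ("near
or better than parent", i.e. within the 2-fold band or enhanced) in ≥ 2
homologs; `P1`/`P2` require frequency > 0 and, in at least one homolog whose
parent represses below the 13-Miller growth threshold, a variant above that
threshold (`P1`) or at MIN (`P2`); `D` fires when fold changes across
homologs span ≥ 2 decades or the substitution is enhancing (> 2-fold,
changed) in one homolog while at MIN in another; `L` requires frequency 0,
tolerance in the designated reference homolog (by default the dataset's
first) and intolerance everywhere else with data; cells carried by fewer
than two homologs are marked insufficient.  Codes are reported as full sets
(`P2D` etc.); no precedence is imposed beyond the inherent exclusivity of
absence (`A`, `L`) versus presence (`P1`, `P2`).

The physico-chemical screen reports Spearman's tie-corrected rank
correlation between a scale (e.g. Kyte–Doolittle hydropathy, shipped
built-in; any scale loadable from CSV) and log10 activity per (homolog,
position), undefined below 4 substitutions or for constant scales, plus the
family-wide fraction of cells with |ρ| ≥ 0.8.

## Synthetic data generator

The generator emulates the study conditions so that every stage is testable
without the original measurements.  Defaults: 14 homologs with the panel's
published parent repression values (0.06–58 Miller units; weak parents for
which changes would be undetectable are represented by their tighter
point-mutant versions, as in the study design), DEL control 4000 Miller
units (no-repressor reporter activity is of order 10³; the study prints no
numeric DEL value), 12 positions × 10 substitutions (the screen's typical
8–12 yield), 4 replicates with lognormal noise at cv 0.2 (clone agreement
within 2-fold), ~30 planted allostery-altering variants and ~10 excluded
(no pull-down activity) rows among the ~1700 variants.

Class-conditional true values: rheostats are *stratified* log-uniform over
[parent·10^(−s/2), parent·10^(s/2)] with planted span s (default 3) — one
draw per equal stratum, shuffled — which is marginally log-uniform but
guarantees a progressive ladder for every seed, matching the rheostat
archetype the classifier is meant to recover; toggles place a fixed count
round(f·n) of substitutions at DEL and the rest at the parent level;
three-state cells use parent, the geometric midpoint, and DEL; neutral
effects are lognormal (σ = 0.1 log10) truncated to the 2-fold band;
`x` cells sit entirely at DEL.  Measured means and sds come from simulating
the replicates themselves, so cv = 0 reproduces the true values exactly.
Substituted amino acids are drawn without replacement from the 19 non-parent
letters, with an optional bias against methionine (off by default).

The alignment generator plants a conserved motif in a configurable fraction
of sequences (default 0.6) and a low-diversity subfamily (default 0.15,
Dirichlet concentration 0.05) inside the motif carriers; remaining columns
draw from per-column Dirichlet-categorical distributions (concentration 0.5
over the 21-symbol alphabet, giving nonconserved-column entropies around
2.2–2.6).  The gapless reference sequence is a motif-carrying subfamily
consensus.

What the generator does **not** emulate: real amino-acid-specific effects
(outcomes are independent of residue identity, so scale screens are null by
construction), phylogenetic correlation between sequences, codon-level
mutagenesis bias beyond the optional Met toggle, position-to-position
epistasis within a homolog, and homolog-specific behavior switching at a
position (the planted class is shared across homologs).  Passing recovery
tests therefore shows the classifier is correct and robust to measurement
noise under the planted archetypes — not that real proteins obey them.

## Benchmark sizes and pinned figures

The regression benchmark is 168 cells (14 homologs × 12 positions; 6 R, 2 T,
3 N, 1 x per homolog).  At cv 0 recovery is exactly 1.0 by construction of
the generator/classifier pair.  At cv 0.2, Monte-Carlo over 20 seeds gave
accuracies 0.964–1.0 (mean 0.984); the residual errors are borderline
neutral cells drifting into `n` when a true effect near the 2-fold edge is
pushed outside by noise.  The pinned regression gate is ≥ 0.95.  Planted
allosteric variants are recovered 30/30 with zero false positives at both
noise levels, because eligibility for planting requires the active-condition
value to sit at least 4-fold below the DEL level, a margin the change
criterion cannot lose at cv 0.2.

## Numerical choices and degenerate inputs

Natural logarithms throughout the entropy code (the printed maximum 3.04 is
ln 21); 0·ln 0 = 0.  Percentages round half-up.  Zero activities are clamped
(half the smallest positive value of the profile) rather than rejected;
profiles that are entirely zero raise.  An empty motif subset is returned as
an empty alignment with a warning, not an exception.  Behavior calls never
raise on thin data — they return `#`.  Pipeline outputs are written with a
fixed float format and no timestamps, so identical seed and configuration
reproduce byte-identical files (the manifest records the config hash and
output checksums).

## Known limitations

* Thresholds carry the field's conventions (2-fold, 5-fold, 2 decades,
  0.1/0.6 entropy cuts) but the cluster gap (0.7), progressivity fraction
  (0.62), three-state width (0.3) and minimum substitution count (5) are
  package choices on a continuum the source material describes only
  qualitatively; all are exposed in `ClassifierConfig`.
* Hybrid and three-state calls are the least constrained part of the rule
  set and should be reviewed against the per-position evidence columns
  (`n_at_min`, `n_clusters`, `largest_gap_log10`) rather than trusted
  blindly.
* The entropy tiering takes alignments as given; no redundancy weighting,
  alignment construction or subfamily discovery is performed.
* Insertion-coded positions (e.g. "61a") are carried as opaque ordered
  labels; classification never does arithmetic on them.
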