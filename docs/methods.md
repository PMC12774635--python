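# Methods

## Scientific setting

A noncoding single-nucleotide variant (SNV) can strengthen or weaken the
binding of a transcription factor (TF) to its DNA site. Given a *pair* of
predicted TF–DNA complex structures — one built on the reference-allele
oligonucleotide, one on the alternative — together with the predictor's
interface confidence (ipTM) and force-field mutation energies
(FoldX-style ΔΔG and interface interaction energies), `structbind`
derives scalar allele-preference scores and evaluates them against
SNP-SELEX-style experimental preferential binding scores (PBS).

All metrics are oriented at computation time to the PBS convention:
**positive = reference-allele preference**. Downstream code never
re-flips signs.

## Allele-preference metrics

For a pair with forward (ref→alt, scored on the reference model) and
reverse (alt→ref, on the alternative model) mutation energies, interface
energies, and per-model ipTM values:

* **ΔΔG_sym** = (ΔΔG_fwd − ΔΔG_rev) / 2, kcal/mol. Antisymmetric under
  allele relabelling: if the reference binds better, mutating away from
  it is destabilising (+) and mutating toward it stabilising (−), so both
  halves push the score positive.
* **ΔInterface** = Interface_alt − Interface_ref, kcal/mol. Interaction
  energies are more negative when stronger, so a positive difference
  means the alternative interface is weaker.
* **ΔipTM** = ipTM_ref − ipTM_alt, in [−1, 1].
* **ΔΔG_max(ipTM)** — the ΔΔG of whichever model of the pair carries the
  higher ipTM (forward branch if the reference model wins, reverse if the
  alternative does). The defining rule is piecewise and silent on ties;
  an exact tie takes the mean of both branches, the unique choice that
  preserves allele-swap antisymmetry. Note that by construction this
  score tends toward *positive* values for any true effect in either
  direction (the more confident model "sees" the better-bound allele), so
  it discriminates differential binding but not its direction — the
  benchmark uses it raw in the differential-binding task and reports, but
  does not expect signal from, its direction-task rows.

### Consensus call

A qualitative call over the three core metrics (ΔΔG_sym, ΔInterface,
ΔipTM): if all available metrics clear their magnitude floors with one
common sign the pair is called `ref_pref`/`alt_pref`; if all sit inside
their floors, `no_preference`; anything else `ambiguous`; fewer than two
available metrics, no call. The floors are deliberate, user-visible
configuration (defaults 0.5 kcal/mol for the energies, 0.02 for ΔipTM)
because no published magnitude thresholds exist for this kind of call;
the defaults sit near the upper edge of the non-preferential score
distributions the generator produces at its default noise level, and
users with calibration data should override them.

### ipSAE (optional)

A PAE-derived interface confidence. For an ordered chain pair (A→B) and
each aligned residue i in A, cross-chain PAE entries below the cutoff
(10 or 15 Å) contribute `1 / (1 + (PAE/d0)²)`, averaged per residue with
the TM-score distance scale `d0(n) = max(1.0, 1.24·(max(n,19)−15)^⅓ −
1.8)` set from that residue's own count n of contributing partners; the
pair score is the best per-residue value. The mean score averages the
larger direction over all three chain pairs of a monomeric-TF/duplex
model; the max score takes only protein↔DNA pairs. An independently
transcribed re-derivation of the formula guards the implementation in
the test suite.

## SASA and binding-site shift detection

Solvent-accessible surface area is computed with an internal
Shrake–Rupley implementation:

* **Point set.** A deterministic Fibonacci (golden-spiral) lattice,
  default 200 points per atom — fixed rather than random so results are
  reproducible bit for bit.
* **Canonical frame.** Because a space-fixed lattice makes quadrature
  results orientation-dependent, coordinates are first mapped to a
  canonical body frame (centroid at origin, principal axes of the atom
  cloud, signs fixed by third moments, right-handed). SASA is then
  invariant under rigid motion of the input up to floating-point error.
  Structures with an exactly degenerate inertia spectrum keep a
  deterministic but arbitrary in-plane orientation.
* **Radii.** A NACCESS-style table keyed by (residue, atom name) with an
  element-keyed fallback (C 1.80, N 1.55, O 1.40, P 1.90, S 2.00,
  H 1.00 Å); atoms with no radius are an error, never a guessed default.
  A uniform-radius set is available for validation against closed forms.
  Probe radius defaults to 1.4 Å (water).
* **Neighbour search.** A uniform spatial grid with cell size
  2·(max inflated radius); the 3×3×3 cell neighbourhood provably covers
  every overlapping pair, and the test suite asserts bit-identical
  results against an all-pairs search.
* **Hetero atoms.** Residues outside the protein/DNA vocabularies count
  as hetero; by default they occlude and are scored like any other atom.

The per-nucleotide SASA vector over both duplex strands (chain 1 then
chain 2, positions ascending; 80 elements for a 40-bp duplex) is a
footprint of where the protein sits. Spearman correlation between the
reference- and alternative-model vectors (`DNA SASA cor.`) detects
binding-site shifts: a pair is flagged *shifted* when the correlation is
strictly below the threshold, default 0.8 — the published separation
point of the bimodal correlation distribution; the boundary side is not
specified there, and strictness below was chosen so that a pair sitting
exactly at the threshold keeps the conservative "matching site" call.
Constant vectors make the correlation undefined; the result is flagged
degenerate rather than silently assigned.

## Oligo windows

Coordinates are 1-based inclusive throughout. Three window modes around
a SNV at genomic position p: `selex40` (40 bp, variant at the 21st base:
20 nt upstream, 19 down — the split is forced by the 21st-position
constraint), `clinical41` (41 bp, 20 nt either side), `clinical81`
(81 bp, 40 nt either side). Only the forward strand is extracted; the
duplex second strand is generated by reverse complement. Soft-masked
bases are uppercased; ambiguity codes and truncated windows are errors,
as is a genome base disagreeing with the stated reference allele.

## Benchmark statistics

* **Labels.** PBS p < .01 with positive/negative PBS → `ref_pref` /
  `alt_pref` (jointly: pbSNPs); p > .5 → `non_pb`; the intermediate band
  stays `unclassified`. A significant pair with PBS exactly 0 is
  contradictory input and an error.
* **Tasks.** (1) pbSNP vs non-pbSNP, using |ΔΔG_sym|, |ΔInterface|,
  |ΔipTM|, raw ΔΔG_max(ipTM) and negated DNA SASA cor. (higher = shifted
  = more likely differentially bound); (2) preference direction within
  pbSNPs, using the raw signed metrics with reference preference as the
  positive class. Spearman correlations against PBS use the full dataset
  including unclassified pairs.
* **ROC AUC** is the rank-based Mann–Whitney concordance (ties count ½),
  exact against exhaustive pair counting.
* **PR AUC** uses Davis–Goadrich interpolation — false positives grow
  linearly in true positives between operating points, giving hyperbolic
  precision — with each segment integrated in closed form; PR analysis
  runs twice, once per class as positive. This is a documented dialect
  choice among PR conventions.
* **Bootstrap CIs** are percentile intervals over case-resampled
  replicates (default 1000); single-class resamples are redrawn, and a
  statistic undefined on more than half the replicates is an error. A
  group too small to resample (n < 10) reports its point estimate with a
  missing interval. AUC rows require at least `min_class_n` (default 5)
  cases per class: a rank AUC over fewer cases takes so few discrete
  values that reporting it would be noise.
* **Weighted MCC** accumulates |PBS| weight instead of counts in the 2×2
  sign-agreement table, so strong experimental effects dominate; a zero
  margin leaves it undefined (null).
* **Group tests.** Dunn's pairwise z from pooled average ranks with the
  tie-corrected Kruskal–Wallis variance, Holm-adjusted, across the three
  preference groups; two-sided Mann–Whitney U per TF (tie- and
  continuity-corrected normal approximation, matching R's default; an
  exact small-sample option exists), Benjamini–Hochberg-adjusted across
  the TF family, with empty groups excluded from the family.
* **Determinism.** Every stochastic step takes a seed; per-row bootstrap
  seeds are derived from the config seed via CRC32 of the row identity,
  so reports are byte-identical across reruns.

## Synthetic cohorts

The generator emulates the statistical structure of a SNP-SELEX
benchmark cohort. A latent per-pair effect δ is 0 with probability
`null_fraction`, else ±`effect_magnitude`. Channels are coherently
coupled with independent Gaussian noise:

    ipTM_ref − ipTM_alt       = c_iptm·δ + ε      (each ipTM clipped to [0,1])
    ΔΔG_fwd                   =  c_ddg·δ + ε
    ΔΔG_rev                   = −c_ddg·δ + ε
    Interface_alt − Interface_ref = c_interface·δ + ε
    PBS                       = c_pbs·δ + ε

PBS p-values are two-sided normal tails under the known null sd, so
planted significance is exact by construction. Defaults — 400 pairs,
50% null, unit effect and couplings, noise sd 0.1 per channel, ipTM
baseline 0.5, interface baseline −10 kcal/mol — define the standard
conditions the recovery tests run under. True-effect pairs receive a
displaced TF blob in the alternative model with probability
`shift_prob` (default 0.5), displaced by `shift_bp` (default 10 bp).

Structures are toy-scale: four pseudo-atoms per nucleotide on an
idealized helix (3.4 Å rise, 36° twist, second strand antiparallel at a
140° angular offset), one CA pseudo-atom per protein residue, the blob
a 10-bp two-strand cuff at 12 Å radius. This suffices for
non-degenerate SASA footprints and plantable shifts; it does not model
sequence-dependent DNA shape, realistic sterics, or PAE realism.
Passing recovery tests therefore demonstrate that the *pipeline*
recovers planted effects through the exact file dialects it parses —
not that any structure predictor achieves such accuracy on real TFs.

## Problem sizes and numerical choices

The recovery suite uses 400-pair cohorts without structure files (the
channel metrics do not need them); the acceptance script's null cohort
uses 1200 pairs so that chance-level pbSNPs are numerous enough for
estimable AUCs at any seed. SASA validation uses 100–200 lattice points
for speed and 960–8000 points where convergence itself is under test.
FoldX `Dif_` files with multiple runs are averaged (matching the tool's
own `Average_` output semantics); fxout parsing skips all lines until
the first row whose leading field ends in `.pdb`, absorbing header drift
across tool versions. Confidence JSONs accept both `iptm` and `ipTM`
spellings, flat or nested under `summary_confidences`; agreeing
duplicates pass, conflicting values are an error, and a missing ipTM is
an error rather than a default.

## Known limitations

* The package consumes predicted structures, confidences and energies;
  it does not run a structure predictor or force field, and `RepairPDB`
  is an upstream precondition for real FoldX outputs.
* Single-model inputs only: no multi-model mmCIF ensembles, no
  multi-seed prediction variability.
* SNVs only — no indels or multi-nucleotide variants; no strand-flip
  handling for variants reported on the reverse strand.
* The FoldX total-energy difference is taken as the ΔΔG, and the
  `Interaction Energy` column as the interface strength; per-term
  decompositions are not parsed.
* Water-mediated contacts, chromatin context and cooperative TF
  assemblies are outside the model; conclusions transfer to real data
  only to the extent the inputs capture them.
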