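# Methods

This note documents the models, parameter choices and numerical
decisions behind `metaseed`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Scope and assumptions

The pipeline starts from a detected-peak table (any upstream peak
picker) and assumes negative-mode electrospray, singly charged,
deprotonated species: neutral mass M = m/z + 1.00727646 Da. Charge-state
deconvolution, positive-mode rules, RT alignment across runs and MS²
interpretation are out of scope. Nuclide masses and abundances are
hard-coded IUPAC/NIST values (CIAAW abundances, AME nuclide masses) to
at least six decimals.

## Deconvolution cascade

Statuses are assigned by the first failing stage in a fixed order —
retention-time validity, artifact (adduct/multimer), mass defect,
isotopologue — so the category counts are exclusive and the accounting
identity `total = retained + Σ eliminated` holds by construction.

**Retention-time window.** The default valid window is the closed
interval [120, 2030] s. This excludes the void volume and the column
wash; boundary values are kept. Peaks outside are `invalid_rt`.

**Adducts and multimers.** A peak is an artifact when a co-eluting peak
(|ΔRT| ≤ 60 s) explains it by a rule offset within the 2 ppm grouping
tolerance (ppm computed on the lighter peak's m/z). The default
negative-mode rule set (offsets in m/z relative to the [M−H]⁻ anchor):
[M+Cl]⁻ +35.976129, [M+HCOO]⁻ +46.005480, [M+CH3COO]⁻ +60.021130,
[M+Na−2H]⁻ +21.981944, [M−H2O−H]⁻ −18.010565, and the dimer relation
m/z([2M−H]⁻) = 2·m/z + 1.007276. The anchor of an accepted match is
never itself flagged: positive-offset and dimer rules are resolved
lightest-first and the water-loss rule heaviest-first, so every anchor's
status is final when it is used. This keeps artifact chains (an adduct
of an adduct) from deleting their own evidence.

**Mass-defect filter.** Biological elemental compositions confine the
fractional part of the monoisotopic mass to narrow mass-dependent bands.
The model is a 2-D occupancy histogram over the reference database:
10-Da pooling slabs along the integer axis × 0.01-wide bins along the
fractional axis, over 100–1000 Da. A query mass is plausible when its
bin is occupied or within one bin (dilation margin 1) along the
fractional axis; the fractional axis wraps modulo 1 so the occupied band
can straddle the 0/1 seam at high mass. The bin sizes and the
occupancy>0 rule are this package's own calibration: they densify sparse
reference databases while preserving the visibly empty region. Masses
outside 100–1000 Da are rejected with a distinct out-of-range code.

**Isotopologue grouping.** A co-eluting, less intense peak whose Δm/z
matches +1.0033548 (¹³C), +0.9970349 (¹⁵N), +2.0042464 (¹⁸O) or
+1.9957959 (³⁴S) within 2 ppm (on the parent m/z) is folded into the
parent's isotope pattern and removed from the list. Each partner is
assigned to at most one parent — smallest |ppm error| first, then
closest RT — and a peak already claimed as a partner cannot itself be a
parent, which prevents chains. A pattern is "visible" when at least one
partner has relative intensity ≥ 1 % of the parent (the floor is this
package's choice; the tier definitions need a concrete threshold).

## Differential statistics and tiers

Per feature, at the matched timepoint: percent change =
(mean_treat − mean_ctrl)/mean_ctrl × 100; signed fold change reports the
ratio r as +r (r ≥ 1) or −1/r (r < 1), so up- and down-regulation are
symmetric in magnitude. The p-value is a Welch two-sample t-test on
log10(intensity + 1) — the log stabilizes the multiplicative error of
ESI intensities, and the +1 guards zero cells. No normalization is
applied by default. A zero control mean yields an undefined percent
change and a +∞ fold sentinel, treated as "changed beyond any threshold"
by the tier rules. Tiers: primary = visible pattern and |Δ%| > 20;
secondary = pattern, |Δ%| ≤ 20; tertiary = no pattern.

## Formula inference

**Decomposition.** All formulas within the element bounds whose
monoisotopic mass lies within the ppm window. Default CHNOPS caps are
mass-dependent (≤500 Da: C39 H72 N20 O20 P9 S10; ≤1000 Da: C78 H126 N25
O27 P9 S14). The implementation enumerates the non-hydrogen count grid
vectorized, pruning each element by the window still reachable given the
remaining caps, and closes hydrogen by direct solution of the residual
mass — a complete enumeration (no integer-scaling round-off) that is
fast enough to run over full 100–1000 Da feature lists. Tests pin the
output set against an independent brute-force nested-loop oracle.

**Golden-rules filtering.** Hard filters: RDBE = C − H/2 + (N+P)/2 + 1
must be a non-negative integer (neutral, even-electron molecule; the
observed ion is [M−H]⁻ but formulas are for neutral M); H/C within
[0.1, 6]; N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8 (only when C > 0,
so carbon-free molecules like water pass); multi-element NOPS
plausibility caps. Soft flag (candidate kept): H/C outside [0.2, 3.1].

**Isotope patterns.** The theoretical pattern is the exact
nominal-mass-aggregated isotopologue distribution: per-element
single-atom distributions over mass offsets are raised to the atom count
by exponentiation-by-squaring with convolutions truncated at depth
(default M+0…M+3) — truncation is exact for the retained entries because
heavier isotopologues never feed back into lighter ones. Fine structure
within a nominal offset is not resolved; the experimental M+1 entries
(¹³C and ¹⁵N partners) are summed per offset before comparison.

**Scoring.** log L = log N(ppm error; 0, σ_mass = 2 ppm) + Σ over
observed offsets log N(obs − theo relative intensity; 0, σ_int = 0.05).
Offsets with no observed partner contribute nothing — below detection is
not evidence of absence, and a zero-intensity term would punish shallow
patterns. Posteriors use a uniform prior over golden-rule survivors and
normalize over the full candidate set; the top 3 are kept. The Gaussian
form and σ defaults are this package's design; σ_mass matches the
grouping tolerance.

## Annotation and set build-up

Primary features are searched by neutral mass (5 ppm, binary search on
the sorted index) and by exact Hill-string match of their top-3 formulas
(a formula match must also satisfy the mass tolerance and is recorded as
`formula+mass`). Features with hits become seeds; their pathways form
the implicated set; hitless primaries go to the unannotated queue.
Secondary features require a formula+mass match and tertiary features a
mass-only match, both restricted to implicated pathways. A feature
hitting several compounds joins every corresponding set. Sets with fewer
than 2 members are dropped: a running-sum statistic on a singleton is
uninformative. HRPP = total hits / peaks with ≥1 hit (≥ 1 when defined,
NA when no peak hits). Note that HRPP is a ratio of sums: restricting
the search space removes hits pointwise but can still raise the ratio on
a single small dataset when a one-hit peak loses its only hit; the
monotone statement holds pooled over many searches, and that is the form
the tests assert.

## Enrichment (MSEA)

The reference metabolome is all retained features, ranked by signed
percent change (descending; ties by feature id; a t-statistic ranking is
available). For a set of H members in a ranking of N, the running sum
gains 1/H at members and loses 1/(N−H) elsewhere; ES is the signed
maximal excursion, computed from the sorted member positions (the walk's
extrema occur only immediately before/after members). ES ∈ [−1, 1], with
+1 iff the members fill a prefix. On an exactly tied ± excursion the
positive value is reported.

The null places H members uniformly at random among N ranks. When
C(N,H) ≤ 10,000 the null is enumerated exhaustively (exact p);
otherwise Monte Carlo with p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm)
(default n_perm = 10,000; the pseudo-count avoids zero p-values). Each
pathway's permutation stream is seeded by crc32(pathway id) XOR the run
seed, so results are independent of set iteration order. BH adjustment
runs across sets; "active" means q ≤ 0.05 by default (switchable to raw
p).

## Synthetic data: what it emulates and what it does not

The generator emulates the data layer of a feeding experiment: random
golden-rule-clean CHNOPS formulas (masses 100–1000 Da, ≥25 ppm apart so
annotation ground truth is unambiguous, and away from the upper edge of
their 10-Da pooling slab so a compound and its M+1/M+2 isotopologues
share a slab), pathways partitioning the compounds, [M−H]⁻ peaks at
uniform RT with log-normal intensities (multiplicative noise is the
standard ESI error model; default CV 10 %, 3 replicates per condition),
one planted pathway multiplied by 1 + effect/100 (default +150 %) in
treatment, ¹³C partners at the theoretical M+1 ratio (probability 0.8),
adduct/dimer decorations co-eluting within 5 s (≪ the 60 s tolerance, so
grouping is unambiguous), and noise peaks rejection-sampled inside or
outside the mass-defect allowed region.

It does **not** simulate chromatographic peak shapes, RT drift, matrix
effects, detector saturation, missing values, or database
incompleteness (every emitted compound is in the database). Passing the
recovery tests therefore demonstrates the internal consistency of the
pipeline — each stage inverts what the generator planted — not
performance on real spectra, where annotation coverage and intensity
error structure are far less favorable.

## Problem sizes and numerical tolerances

Default test/acceptance sizes: decomposition completeness on 200 random
masses (50–400 Da, 5 ppm) against the brute-force oracle;
isotope-simulator exactness to 1e−9 per entry against an exact
rational-arithmetic convolution; Monte-Carlo vs exhaustive permutation p
within 3 standard errors for all N ≤ 8, H ≤ 4 at 50,000 permutations;
type-I calibration over 1,000 random-ranking replicates (N = 200,
H = 8, 499 permutations each) against the 95 % binomial interval around
0.05; end-to-end recovery over 20 seeded runs at the generator defaults
with 2,000 permutations per set. Percentages in the accounting report
are rounded (round-half-away) to 1 decimal. Mass comparisons use
1e−5 Da for formula/mass consistency checks and ppm windows everywhere
else. All randomness flows from explicit seeds; identical seeds give
byte-identical outputs.

## Known limitations

- Mass-defect model quality degrades with very sparse reference
  databases (few compounds per 10-Da slab); the 1-bin dilation is a
  compromise between false rejections and filter power.
- Experimental isotope patterns aggregate to nominal offsets; isobaric
  fine structure is not used as evidence.
- The unweighted KS statistic treats all ranks equally (no weighting by
  the ranking metric); strongly bimodal rankings can dilute power.
- HRPP counts multiple hits per peak; it measures annotation ambiguity,
  not correctness.
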