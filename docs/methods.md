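# Methods

This note documents the models, estimators, and numerical choices behind
the package, the assumptions they rest on, and what the synthetic-data
generator does and does not emulate.

## Absolute quantification (AQUA ratio method)

Each peptide measurement pairs an endogenous intensity with the intensity
of a stable-isotope-labeled reference peptide of known spike amount *s*
(amol). The amount estimate is (endogenous/reference) × *s*. The method is
absolute because any peptide-intrinsic response factor (ionization
efficiency, digestion recovery, transmission) multiplies both channels and
cancels in the ratio. Assumptions: the reference is spiked at a known point
in sample processing, both channels are within the instrument's linear
range, and the endogenous and reference peptide are chemically identical.

Aggregation to the protein level is the arithmetic mean of per-peptide
amounts ("average ratio" reading): charge states of one peptide are
averaged first so multiply-observed peptides are not over-weighted, then
peptides are averaged. The reported CV is the sample standard deviation
(n−1) over the mean. A median option exists for peptide sets with known
biases (reference-peptide digestion artifacts can inflate individual
peptides several-fold). Rows with a zero reference channel carry no ratio
and are dropped with a warning; zero endogenous intensity is a valid
amount of 0.

iBAQ divides a protein's summed intensity by its number of observable
peptides: distinct fully tryptic peptides (cleavage C-terminal to K/R
except before P, zero missed cleavages, implemented via
`pyteomics.parser.cleave` with an explicit rule) with length in [7, 30].
These bounds are this package's fixed convention; other tools use slightly
different windows, which shifts iBAQ values by a protein-specific constant.

Dilution linearity is ordinary least squares of log10 intensity on log10
amount over a ladder (the assessment design spans 0.4–40,000 amol);
zero-intensity points cannot enter log space and are excluded and counted.
A slope of 1 with r² near 1 indicates ratio-faithful response.

## Copies per cell and the receptor ruler

Amounts (amol) convert to molecules with the exact SI Avogadro constant
(6.02214076e23/mol) and to copies per cell by dividing by the cell
equivalents the sample represents *at the spike point*. This spike-point
convention is carried explicitly in the sample metadata because the two
designs differ: lysate rulers are spiked right after lysis (cell
equivalents of the digested material, 100 µg at ~230 pg/cell ≈ 435,000
cells), while affinity-purification samples are spiked into the final
peptide matrix (cell equivalents = processed cells, e.g. 2% of 1.2e8 =
2,400,000). Every amount-to-copies conversion divides by that one number,
which keeps both conventions consistent and makes the calibrant
translation an exact identity: translating the calibrant through itself
reproduces the direct division to round-off.

Other proteins are placed on the copies-per-cell scale by the ruler
relation c_p = c_cal × A_p / A_cal within the same sample, then averaged
across samples. With the same-sample formulation the calibrant's own noise
cancels between numerator and denominator of its direct estimate, so the
translation adds no extra variance beyond the two amount estimates.

## Stoichiometry

Relative stoichiometry is the ratio of each member's amount to a reference
member — by default the most abundant member (ties broken by member order
in the complex definition), optionally a fixed member. The reference is
selected from the amounts supplied to the call; when a stable reference
over a time course is wanted, pass time-averaged amounts.

Integer models are found by exhaustive enumeration: base vectors with each
multiplicity in 1..4 and gcd 1, optionally extended by a single additive
excess vector (entries 0..4, not all zero) representing surplus subunits
riding on a core isostoichiometric complex (partial-complex isoforms). The
predicted ratio vector is (base + excess) normalized to its maximum, and
the fit error is the RMS difference in log2 space — chosen so that a 2×
and a 0.5× discrepancy weigh equally, appropriate for multiplicative
ratio data. Ranking is fit error, then total copy number (parsimony), then
lexicographic order of (base, excess): fully deterministic. The bound of 4
copies covers trimers, dimers, 2:2:1 and (1:1:1)+(1) patterns while
keeping enumeration exhaustive and independently checkable by brute force.
Note that distinct decompositions can predict identical ratios (base (2,1)
equals base (1,1) plus excess (1,0)); model comparisons should therefore
compare predicted ratio vectors, which the tie-break makes canonical.
Known homo-oligomer states (trimeric receptor, dimeric kinase/DUB
subunits) enter as fixed multipliers from the complex definition, never
inferred from the data.

Occupancy (interactor amount / multiplicity / bait amount) may exceed 1 —
polymeric cargo such as conjugated ubiquitin is genuinely
super-stoichiometric — so values above 1 are returned as-is, and the
complex-level bound fraction carries an over-unity flag instead of being
clamped.

Recruitment time courses divide each analyte's amount by the receptor's at
the same timepoint (removing capture-efficiency variation) and then by the
series maximum. Profiles are grouped by agglomerative hierarchical
clustering with distance 1 − Pearson correlation and average linkage, cut
to k clusters (default 3); zero-variance profiles have no defined
correlation and are placed in singleton clusters with a warning.

## Resource allocation

Complete complexes per cell is the min over members of copies/multiplicity.
The copies required for isostoichiometry of a member with multiplicity m,
given R receptor copies per cell and receptor oligomer n (3), is m × R/n —
one complete complex per oligomeric receptor unit. A member is limiting
iff available < required (strict; equality is exactly sufficient). This
model deliberately ignores competitive binding and paralog compensation;
it provides a supply-side bound, not a kinetic model.

Signalosome mass at a timepoint expresses molecules bound per oligomeric
receptor unit (default) or per monomer, times monomer molecular weights,
receptor included. When a single protein exceeds half the total mass it is
flagged as the majority contributor (in practice ubiquitin).

## Native-gel (BNPAGE) profile analysis

Profiles are per-fraction intensity vectors over 65–75 one-millimeter gel
slices, 1-based. Two normalizations are provided (to the maximum; to an
anchor fraction). The first relative minimum — the anchor used to separate
well-trapped from resolved signal — is operationalized as: smooth with a
centered moving average (window 3, shrinking at the edges), return the
smallest interior index that is strictly below its left neighbor and not
above its right neighbor; plateaus resolve to their earliest index;
monotone profiles raise an explicit no-minimum error.

The disassembly shift statistic is each protein's early-fraction share
(signal in fractions 1..5 over total, cutoff configurable) in both
conditions; the paired one-sided Wilcoxon signed-rank test (exact null)
tests whether untreated shares exceed deubiquitinase-treated shares.
Proteins quantified in only one condition are excluded from the test;
fewer than 5 matched proteins skips the test with a warning; identical
shares yield p = 1 by convention. Peaks are local maxima with prominence
≥10% of the profile maximum (suppresses noise-floor maxima at
low-attomole signal levels while keeping ladder peaks), optionally
excluding the well region; spacing mean/CV and successive height ratios
quantify periodicity. Comigration is plain Pearson correlation on matched
fraction grids, with zero-variance profiles reported as undefined.

## Synthetic-data generator

The generator defines a ground-truth cellular state and simulates the
three measurement designs from it.

*State.* Defaults emulate an adenocarcinoma-like cell line signaling
state: trimeric receptor at 25,000 copies/cell; complex members between
1e3 and 1e6 copies/cell (log-uniform when sampled); the CYLD-SPATA2
deubiquitinase module held below its isostoichiometry requirement (12,000
and 6,000 copies against a ~16,700 requirement), making it the limiting
module; four substoichiometric accessory factors (a few percent of core
occupancy); conjugated ubiquitin at 550 copies per receptor trimer at
peak, which puts the peak assembly mass near 6 MDa with ubiquitin the
majority mass contributor; and DUB-module occupancy (0.11) about a fifth
of LUBAC occupancy (0.5), i.e. roughly 20–25% of ligase complexes carry a
DUB module.

*Kinetics.* Recruitment per complex is a saturating exponential with lag,
normalized to reach its plateau at 10 min, with slow exponential decay
after; all non-receptor binding is zero at t = 0. Ubiquitin accumulates
more slowly (rate 0.25/min) than the core, reflecting continued chain
elongation — this keeps the mass peak unambiguously at 10 min.

*Noise model.* Intensities are multiplicative lognormal. Each peptide has
a shared response factor (lognormal across peptides, sigma 1.0) applied to
both channels, making the ratio-based cancellation literal. Per-channel
log-noise sigma is set to sqrt(ln(1 + cv²)/2), so the CV of the
endogenous/reference ratio is exactly `noise_cv` (default 0.2, a
deliberate artifact choice: replicate-level CVs are not published for this
kind of design). Spike levels form a geometric ladder over 16–160,000 amol
(5 levels for lysates, 4 for APs) with each peptide assigned the level
nearest its true amount in log space. True amounts below the detection
limit (default 0.01 amol, i.e. 10 zmol — targeted acquisition is sensitive
to the zeptomole range) are censored: the row is omitted, not zero-filled.

*Gel profiles.* Untreated condition: all signal in the first
`well_fractions` fractions (geometrically decaying) plus a uniform noise
floor — the intact assembly exceeds the gel's resolving power and stays in
the well. Treated condition: Gaussian peaks at multiples of the period
with geometrically decaying heights (constant successive ratios) plus the
same noise floor.

*What it does not emulate:* chromatographic interference, isotope-pattern
overlap, retention-time drift, missing-value mechanisms beyond the simple
LOD, digestion-kinetics differences between proteins, inter-complex
competition, and gel-migration anomalies. Passing the closure and recovery
tests therefore demonstrates correctness of the estimators under the
stated noise model, not robustness to every artifact of real acquisitions.

## Problem sizes and determinism

The default simulated designs mirror the measurement layout: 12 lysates
(3 replicates × 4 timepoints, 0/5/10/15 min), 12 AP samples, 3 peptides
per protein, 23 proteins, 70 gel fractions. The stochastic recovery check
runs 100 seeded simulations of the lysate design (~2 s); the exhaustive
integer-model self-fit covers the full 3-member candidate space (6,875
models, ~15 s). Every random draw flows from a single
`numpy.random.default_rng(seed)`; identical configuration and seed
reproduce every output byte for byte (floats are serialized via `repr`,
which round-trips exactly).

## Known limitations

- One excess vector only: mixtures of more than two complex isoforms
  (e.g. two coexisting kinase-complex variants) are outside the search
  space; the enumeration is structured so a two-isoform extension can be
  added without changing the ranking contract.
- The allocation model treats copy numbers as a static supply; it says
  which proteins *can* be limiting, not which are kinetically engaged.
- Gel-fraction indices are not calibrated to molecular weight; the
  analysis is purely positional (periodicity, shift, comigration).
- The AQUA estimator trusts the spike amounts; systematic spike errors
  propagate 1:1 into amounts and copies.
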