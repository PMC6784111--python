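# Methods

This package implements a germline-guided antibody light-chain framework
optimization workflow and the downstream assay analyses used to characterize
the resulting variant panel. It is organized as a library (`abframe`) with
numbered analysis drivers under `analysis/`; every computation the drivers
report lives in the library and is unit-tested.

## Kabat numbering (`abframe.kabat`)

V-domain sequences are numbered by global alignment (BLOSUM62, affine gaps,
free end gaps) against a per-chain consensus template, followed by
region-wise renumbering: the alignment fixes how many query residues fall in
each framework/CDR segment, and each segment is then mapped onto its
canonical Kabat span. Length excess in a segment becomes lettered insertions
at that segment's canonical site (L: 27a-f, 95a-f, 106a; H: 35a-b, 52a-c,
82a-c, 100a-k); length deficits leave positions absent — omitted just after
the canonical site for internal deletions, and at the far end for terminal
truncations (so a kappa V gene covering positions 1-95 numbers cleanly).
Queries under 40% identity to the template are rejected rather than
numbered unreliably. The templates are synthetic, insertion-free
consensus-like sequences (kappa-I flavoured VL of 107 positions, VH3
flavoured VH of 113), so the canonical spans — in particular the 70-position
kappa FR1-FR3 framework — hold exactly. Real germline genes (e.g. IGKV3-20
with its 12-residue CDR-L1) deviate from these templates; the bundled
germline set is therefore an explicitly synthetic toy reference, adequate
for exercising the scan/design machinery but not a substitute for a curated
database.

Insertion placement when a segment has no canonical site is an error, not a
guess. Ties in gap placement never arise because renumbering is count-based
rather than alignment-column-based; this also makes numbering idempotent.

## Germline scan and variant design (`abframe.germline`)

Framework identity is 100 x matches / shared positions over Kabat FR1-FR3
only (germline V genes do not encode FR4); for an insertion-free kappa chain
the denominator is 70, so five mismatches give 65/70 = 92.86%. Total
V-region identity uses every position the germline covers (kappa V genes end
within CDR3, around Kabat 95). X counts in the denominator but never as a
match. Ties on framework identity break by total identity, then gene name.

Mismatches whose Kabat numbers differ by at most 2 merge into one mutation
region — this lets a single conserved position sit inside a region, as in
the 1-4 stretch where position 2 matches germline while 1, 3 and 4 do not.
Variant enumeration takes all 2^k parental/germline region combinations,
ordered by the number of germlined regions and then by region order, names
each variant by concatenating the residues at the signature positions (a
4-position region contributes four letters), and optionally inserts a
"-K" duplicate of the parental carrying the heavy-chain C-terminal lysine
(a panel-level flag; no constant domain is modelled). Panels are capped at
k = 12 regions (4096 combinations).

Positional residue frequencies come from a `FrequencyProfile` built over any
reference set of numbered sequences. The public databases behind the
literature's frequency anchors are not bundled; tests plant known counts.

## Binding kinetics (`abframe.spr`)

Sensorgrams follow the pseudo-first-order 1:1 model: association
R(t) = Req (1 - e^(-(ka C + kd) t)) with Req = Rmax C ka / (C ka + kd), and
dissociation by e^(-kd (t - t_stop)) from the response at injection stop.
Fitting is global — one (ka, kd, Rmax) triple across all analyte
concentrations — by Levenberg-Marquardt on log-parameters, initialized from
a pooled dissociation-phase log-linear regression (kd) and an
equilibrium-isotherm scan (KD, Rmax). Mass-transport limitation, baseline
drift and reference-channel subtraction are out of scope. Default simulated
design: five concentrations spanning 3-25 nM, 300 s association, 1200 s
dissociation, Rmax 40 RU, Gaussian noise 0.5 RU.

## Thermal stability (`abframe.dsf`)

Melt curves are two-state sigmoids between linear pre- and post-transition
baselines; the slope parameter (default 1.5 degC) sets transition width.
The default midpoint estimator is the first qualifying maximum of the
Savitzky-Golay-smoothed derivative dF/dT, refined by a parabola fitted over
about +/-2 degC around the peak; a two-state sigmoid fit restricted to the
first-transition window is available as an alternative. A peak qualifies if
its height exceeds 10% of the global derivative maximum, it is at least
2 degC wide (narrow spikes are noise, genuine unfolding transitions are
broad), and the smoothed fluorescence jump across it exceeds 5% of the
curve's full range. Flat or transition-free curves raise a no-transition
error. At 1% -of-amplitude noise on a 0.5 degC grid the estimator's bias is
under 0.03 degC with an SD near 0.1 degC; panel shifts are therefore
reported from replicate means in the tests. Tm shifts are invariant to
shared affine rescaling of fluorescence because all thresholds are relative.

## Aggregation by SE-HPLC (`abframe.sec`)

Species (HMW aggregate, dimer, monomer, fragment, in that elution order) are
quantified by baseline-subtracted trapezoidal integration over fixed
retention-time windows and normalized to fractions — the routine purity
reporting practice; no peak deconvolution is attempted, so heavily
overlapping peaks are apportioned by the window boundary. The baseline is a
linear fit over blank regions flanking the windows. Simulated traces are
Gaussian peaks on a linear baseline with the integrated truth returned
alongside. Stability time-courses summarize monomer percentage per week,
its minimum, and the total change.

## Pharmacokinetics (`abframe.pk`)

Plasma decay after an intravenous bolus is fitted by unweighted least
squares on the linear concentration scale (log-scale residuals available by
option, appropriate for constant-CV error) to a mono-exponential
C0 e^(-kt) or a bi-exponential C0a e^(-at) + C0b e^(-bt) with a > b > 0
enforced by parameterization. The bi-exponential objective is optimized by
variable projection — amplitudes solved linearly at each step — from a
curve-peeling start plus a small grid of rate-pair starts, because near the
one-compartment limit the surface is degenerate and a single local search
understates the achievable sum-of-squares reduction. Amplitudes are
deliberately left unconstrained in sign: constraining them places the
mono-exponential null on the parameter boundary and makes the extra
sum-of-squares F-test reject at roughly half its nominal rate. The model
chooser (`select_decay_model`) restores physicality: a statistically
preferred but negative-amplitude fit falls back to the one-compartment
model, as does any arm with fewer than five uncensored points (the
below-LOQ regime).

Model choice uses F = ((SS_mono - SS_bi)/2) / (SS_bi/(n-4)) with p from
F(2, n-4), two-compartment iff p < 0.05. Under a mono-exponential truth
with additive Gaussian noise this selects the richer model in ~5% of
simulated datasets.

NCA follows the stated definitions: AUC(0-144 h) by the trapezoidal rule
over observed group-mean points, anchored at t = 0 by the fitted model value
(no t = 0 sample exists); CL = dose/AUC scaled to mL/h/kg at 30 g body
weight; t1/2,beta = ln2/beta; MRT model-based by default,
(C0a/a^2 + C0b/b^2)/(C0a/a + C0b/b), with a trapezoid-moment alternative.
Model-based MRT corresponds to 0-infinity moments while AUC is truncated at
144 h, so V_D,ss = CL x MRT mixes horizons exactly as the source analysis
does; the stored identities CL x AUC = dose and V_D,ss = CL x MRT hold to
1e-9 relative. Concentrations below the LOQ are censored out of fitting; a
time point is dropped only when every animal is censored. Group-mean
fitting over n = 4 animals is the default presentation.

## Cross-variant statistics (`abframe.stats`)

Spearman's rank correlation between Tm and mean expression titer uses
average ranks and, for n <= 10, an exact permutation p-value over all n!
orderings (the permutation leaves one rank vector's centered sum of squares
fixed, so only cross-products are re-evaluated, in vectorized chunks);
larger panels use the t-approximation. The default alternative is one-sided
positive — the working hypothesis is that stability helps expression — with
two-sided available. Group comparisons run a per-group Kolmogorov-Smirnov
normality screen (reported, not enforced), one-way ANOVA, and Tukey's HSD
(Tukey-Kramer under unequal n, via the studentized range). Fold checks
report max(v/ref, ref/v) per variant with an inclusive bound, invariant to
global rescaling.

## Synthetic data (`abframe.simulate`)

The generators define the study conditions and emit their truth tables, so
every recovery test compares against a known truth:

* kinetics truths are the reported per-variant (ka, kd) pairs
  (1.1-3.1 x 10^5 /M/s, 2.9-6.4 x 10^-4 /s), all KD within two-fold of
  parental;
* Tm offsets are keyed to region content — ~+0.5 degC for the 1-4 or 66
  single regions, ~+2 degC for anything carrying Q79E, and >+4 degC for the
  synergistic 1-4 x A66G combinations — on a 70 degC parental baseline (an
  assumed typical IgG first transition; absolute values were never
  published, only shifts);
* titer fold-effects are 3-10x for A66G-containing variants and ~1.2-1.4x
  otherwise, with lognormal replicates at 20% CV over five expression runs;
* monomer fractions decline linearly 97.4 -> 95.6% (optimized) and
  89 -> 85% (parental) over 12 weeks;
* PK arms are two-compartment curves with the reported C0a/C0b/t1/2,beta per
  antibody x dose, a 5 h distribution half-life (never published;
  configurable), n = 4 animals, 20% CV multiplicative lognormal noise, and
  an LOQ of 0.4 mg/L that censors the parental 5 mg/kg tail beyond 48 h (the
  parental 5 mg/kg truth is dose-scaled from its 15 mg/kg fit, since that
  arm's estimates were never obtainable). Sampling times default to
  {0.5, 1, 2, 4, 8, 24, 48, 72, 96, 120, 144} h, a conventional schedule
  (the exact schedule was not published).

What the generators do not emulate: inter-animal random effects (noise is
iid per observation), instrument drift and reference-channel artifacts in
SPR, DSF waterfall baselines, SEC column aging, or assay-plate effects in
titers. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated error models, not robustness to every artifact
of real instrument data.

## Reproducibility and problem sizes

All randomness flows from a single integer seed through named
`numpy.random.Generator` streams; identical seeds give byte-identical
outputs. The test suite uses deliberately small designs — 5-curve SPR
panels, 141-point melt grids, 10-11-point PK schedules, 50-seed Tm and
20-seed rate-recovery studies, 1000-replicate F-test calibration — chosen to
estimate each property tightly while keeping a full run in tens of seconds.
The pipeline (`abframe.pipeline.run_pipeline`, CLI `abframe run`) executes
design -> assays -> PK -> statistics end to end, logs a config hash, and is
deterministic given the seed.

## Known limitations

* The numbering templates are synthetic consensus sequences; sequences far
  from a canonical kappa/VH3 V domain (lambda chains, heavily engineered
  frameworks) may fail the 40% identity screen or place deletions at
  positions a curated numbering tool would choose differently.
* Species assignment in SEC is window-based; strongly shifted retention
  times require re-configuring the windows.
* The F-test is exactly calibrated for additive iid Gaussian error; under
  multiplicative noise fitted unweighted it is approximate (use the
  log-scale option in that regime).
* Exact permutation p-values are limited to n <= 10 (10! orderings); beyond
  that the t-approximation is used.
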