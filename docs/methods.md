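# Methods

## Curve model and preprocessing

A retraction trace is treated as a 2-D parametric curve
c(x) = [dist(x), force(x)] over the acquisition timeline x. Samples stay
in file order; monotonicity of the distance channel is never enforced on
raw input, since noise can reverse it locally. Units are nm and pN
throughout (SI input is converted on read; a flag flips inverted force
signs).

Both channels are denoised independently with robust locally weighted
linear regression (RLOWESS, tricube weights, five bisquare reweighting
iterations) over a span of `window` raw samples — default 51 on a
~1,600-sample curve, the span at which a bR curve shows its expected
three main events; 11 over-segments and 101 over-smooths, and the test
suite asserts that monotone trend. The smoothed channels are then
linearly interpolated on the timeline to 50,000 points, jointly, so they
remain paired.

**Noise floor.** The denoising residuals give a robust raw-noise scale
σ_raw = 1.4826·MAD; the floor used everywhere downstream is
3·σ_raw·√(1.2/window), the standard deviation expected of the *smoothed*
noise (1.2 is the variance factor of locally weighted linear smoothing).
A trailing-baseline estimate (3 × std of the final 5% of samples) is the
fallback for curves lacking residual metadata, but it is far noisier:
after a 51-point smooth the tail of a 1,600-sample curve holds only a
couple of independent values.

**Overall length and filtering.** A curve's overall unfolded length is
the largest tip-sample separation at which force exceeds the noise floor
for at least half a smoothing span (shorter excursions are correlated
noise, not signal), divided by 0.36 nm/aa. Datasets are filtered to
180–220 aa (inclusive), which for bR selects molecules tethered by the
C-terminus. The 0.36 nm/aa conversion is configurable everywhere; 0.36
is the default because the three worked examples it is paired with
(148 aa ↔ 53 nm, 105 aa ↔ 38 nm, 94 aa ↔ 34 nm) are self-consistent
with it, whereas some coarser printed approximations imply ~0.33.

## Derivative encoding

Both axes are min-max normalised to [0, 1] and the curve is resampled at
unit speed in arc length, which bounds the tangent components
(dist′, force′) to [−1, 1] and makes the representation translation
invariant by construction (normalisation removes the offset exactly; the
derivative-space argument then holds trivially). The tangent at each
sample is a secant over ±0.2% of the sample count — wide enough to damp
residual smoothing noise, narrow enough not to blur transitions.

Each tangent pair is binned on a uniform 1,000-bin grid per axis
(index = ⌊(d+1)/2 · n_bins⌋, clamped); a maximal run of samples sharing
a bin pair is one *derivative cell*, annotated with the arc length it
covers. A perfectly linear curve yields exactly one cell.
`prune_small_cells` implements the classical cell-level pruning (cells
below a fraction `t_small` of the total arc length merge into the
preceding retained cell, the first cell is never pruned, and an
all-below-threshold sequence is an error).

**Banding and fragments.** For fragment classification the cells are
banded by their force-derivative bin into rising / constant / falling.
The constant band half-width defaults to 445 bins, i.e. "constant" means
|force′| ≤ 0.89, a normalised slope of about 2. This is deliberately
wide: on a sawtooth curve the limb just below a rupture and the drop
after it are far steeper than the overall force/extension scale, while
baselines and constant-force cliffs are far flatter, so the band
separates the two slope populations with maximal margin; the residual
derivative noise of a smoothed 8-pN-noise curve (± ~0.4 normalised)
falls safely inside it. Low-force limb portions also land in the
constant band; they coalesce with the baseline and do not affect peak
positions, because WLC fits are force-trimmed (below).

Band runs are cleaned in two passes that share the single `t_small`
scalar (default 0.005 of total arc length): first, rising/falling runs
whose net force change stays below twice the noise floor are relabelled
constant (noise cannot sustain a real limb or rupture), letting a
noise-chopped plateau coalesce into one constant run; second, runs
covering less arc than the threshold are merged into their neighbours,
smallest first. Cell-level pruning is not used in this chain because on
noisy data nearly every cell in a baseline or plateau is individually
sub-threshold, and merging them into the *preceding* cell erases whole
regions; the run-level formulation applies the same arc criterion
without destroying band identity.

The cleaned runs reduce to fragments:

| structure                  | emits | meaning                          |
|----------------------------|-------|----------------------------------|
| rise → fall                | A     | rupture peak                     |
| fall → rise                | B     | valley between events            |
| rise · const · rise        | C     | cliff in a rising stretch        |
| fall · const · fall        | C     | cliff in the drop                |
| fall · const · rise        | B     | flat valley floor                |
| rise · const · fall        | C, A  | cliff ending at the rupture      |
| leading/trailing runs      | —     | baseline, no fragment            |

A constant run flanked fall→rise is a valley, not a cliff: after
smoothing, *every* baseline between sawtooth peaks is such a run, and
calling it C would fabricate a side peak per valley. Conversely a
constant run between rise and fall that is wide enough to survive arc
smoothing cannot be a rounded peak top (that crossing covers a tiny
arc); it is a cliff whose end coincides with the rupture, hence C
followed by A at the cliff end. A-peak positions are the maximum-force
sample of the transition; B valleys the minimum.

## Events and WLC fits

One event is parsed per A fragment, left to right: a span-adjacent C
directly before the A makes it type II (the C is consumed), otherwise an
immediately following unconsumed C makes it type III; a trailing A
without a closing B still closes the final event (the last rupture may
end at detachment), and unconsumed C fragments are logged as orphans.

Every limb is fitted with the WLC interpolation formula with persistence
length p = 0.4 nm and k_B T = 4.114 pN·nm (room temperature) held fixed
— the community defaults for polypeptide SMFS, both configurable — so
the only free parameter is the contour length L, optimised by bounded
1-D least squares on u = x_max/L ∈ (0, 1). Limbs are trimmed to forces
above the noise floor and above 80% of the limb's own top force: the
WLC's approach to its asymptote pins L from the high-force samples, and
the relative trim shields the fit from earlier branches or undetected
plateaus lower on the limb. The type II side fit (limb before the
cliff) additionally stops half a smoothing span short of the cliff,
where corner rounding biases L upward; the type III side fit uses the
trailing stretch of the cliff, referencing the side to the cliff exit.
When the limb between a cliff and its rupture is shorter than the
smoothing span — common when the intermediate gives way close to the
main barrier — the main fit falls back to the trailing stretch of the
cliff, which lies on the main branch.

Two sanity rules remove noise artefacts: events closer than 5 aa within
one curve merge (noise can split one rupture into near-identical
fragments; the stronger peak wins), and a type II side whose contour
length is not below the main's is discarded, with the main refitted on
the whole limb (a real intermediate always precedes its rupture).

## Alignment

Event positions are the fitted contour lengths in aa (main and side
positions participate equally). Because the cantilever grabs the protein
somewhere within a terminal stretch, all events of one curve share an
unknown offset; alignment searches one shift S per curve over
[−30, +30] aa in 1-aa steps. For each S an order-preserving matching (no
crossings — unfolding follows the amino-acid sequence) maximises the
number of pairs closer than the strict 5-aa window, ties broken by the
smaller total absolute discrepancy. Shift selection ranks by score, then
total discrepancy, then smaller |S|: with unit match scores many shifts
tie on the count, and the discrepancy is what actually pins the
alignment — preferring small |S| first would bias every curve toward
zero by up to the match window.

Curves are aligned progressively in descending event-count order (richer
curves seed a more complete consensus); matched consensus positions
track the running mean of their supporting shifted positions and
unmatched events open new columns. Two closing steps make the consensus
well-defined: columns closer than the match window merge (two events of
one curve are never that close, by the dedup rule), and all positions
are re-referenced by subtracting the maximum per-curve shift. The
re-referencing rests on the one-sided attachment model — tethering can
only *add* contour length — so the curve with the largest positive shift
is the least-offset one and is pinned at zero; it also makes consensus
positions independent of which curve happened to seed the alignment
(they are stable to ~1 aa under input reordering).

## Statistics

Consensus events supported by at least half the curves (inclusive) are
main peaks, the rest side peaks; 0.5 cleanly separates the bR
frequencies (mains ≥ 15/26, sides ≤ 10/26). Events are assigned to
contour-length regions — defaults [30, 110), [110, 180), [180, 240] aa,
covering the helix pairs E–D and B–C and helix A — and each curve's 0/1
signs concatenate per region (main peak first, then side peaks by
position) into a pathway string. Co-occurrence counts are exact row
scans of the binary matrix. TP/FP evaluation matches aligned detections
to annotations per curve with the same order-preserving matcher and the
same strict window.

## Synthetic data generator

The generator renders the study conditions: 26 curves of ~1,600 samples,
main events at 80/143/215 aa with occurrence probabilities 15/26, 24/26,
26/26 and side events at 39/97/167/201 aa with 9/26, 4/26, 10/26, 4/26;
Gaussian force noise of 8 pN; and a per-curve attachment offset drawn
uniformly from [0, 30] aa that lengthens every contour (one-sided, as
terminal tethering only adds residues). Each included event contributes
a WLC branch with contour (position + offset)·0.36 nm that rises until
its rupture force — drawn uniformly from 100–200 pN — then the trace
drops onto the next branch; beyond the last rupture the force is
baseline. Noiseless branches satisfy the closed form to 10⁻⁶ pN.

Side events render as constant-force cliffs where geometry permits: a
plateau welded into the next main's limb (CAB, type II) when that main
is included and within 60 aa, or into the previous main's drop (ACB,
type III), otherwise as a standalone peak. Cliff forces are drawn
uniformly from 0.45–0.70 of the flanking rupture force: unfolding
intermediates give way well below the main barrier, and a cliff too
close to the rupture force would leave a post-cliff limb shorter than
the smoothing span — a morphology whose main peak no smoothing-based
detector can see. The annotation records every included event at its
offset-free position, its kind, its rendering, and its force.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: distance-channel noise and drift, baseline
tilt, adhesion peaks near contact, pulling-speed (Bell–Evans) force
dependence, correlated instrument noise, and multi-molecule tethers.
Detection rates on real curves will be lower at equal noise settings.

## Problem sizes and numerics

The default test run simulates a 26-curve dataset once (seed 7) and
reuses it across tests; the acceptance script re-simulates 26 curves at
the caller's seed and fits ~100 noiseless limbs — a few seconds each on
one core. WLC fits subsample limbs to ≤ 500 points and solve a bounded
scalar minimisation (xatol 10⁻¹⁰); an optimum at the long-contour bound
is reported as a fit failure rather than a number. Degenerate inputs
fail loudly: even smoothing windows, zero-extent axes, all-sub-threshold
pruning, extensions at or beyond L. Curves whose events cannot be fitted
are kept with empty event lists, so one bad curve never aborts a
dataset; byte-identical outputs under identical seeds are a tested
contract.
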