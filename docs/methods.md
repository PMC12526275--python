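# Methods

## Scope and data model

The package analyzes *summary* electrophysiology data, not raw current
traces: per-concentration mean fractional inhibition of the hERG tail
current (single drugs and fixed-ratio mixtures), and gating curves
(normalized current vs voltage, or vs depolarization duration). Doses
are μM throughout; readers reject any other unit annotation rather than
convert silently.

## Median-effect analysis

The median-effect equation fa/fu = (D/Dm)^m is fitted by unweighted
ordinary least squares on the base-10 linearization
(log10 D, log10(fa/(1−fa))). m is the slope, Dm = 10^(−intercept/m),
and r the Pearson correlation of the linearized points. Base 10 and
unweighted OLS reproduce the published CompuSyn parameter triples for
all three single drugs and all four mixtures to better than 0.01%, so
no other weighting was considered. Points with fa exactly 0 or 1 have
undefined log-odds; they are excluded from the fit and recorded with a
reason rather than clamped — boundary values carry no usable effect
information on this scale. A fit needs at least two usable points; a
non-positive slope (effect decreasing with dose) is returned but
flagged `non-monotone` instead of raised, so screening runs continue.

Internal consistency is structural: Dm is *stored* as the anti-log of
−intercept/m, so the (m, intercept, Dm) triple can never drift apart.

## Combination index

CI at an observed mixture level uses that level's measured combined fa
and the single-drug fits: CI = Σ Di/Dxi with
Dx = Dm·[fa/(1−fa)]^(1/m). CI at effect levels (ED50…ED95) instead
takes the total dose from the mixture's own median-effect fit (the
mixture fitted as one agent on total dose — valid precisely because the
design is fixed-ratio) and splits it by the design weights. These two
constructions reproduce, respectively, the published per-level CI
values and the published effect-level orderings.

Classification uses the conventional bands: CI < 0.90 synergistic,
0.90 ≤ CI ≤ 1.10 additive (closed on both sides), CI > 1.10
antagonistic. The thresholds are configurable in the pipeline but the
defaults are the conventional ones.

A mixture level with fa exactly 0 or 1 has no finite equivalent
single-drug dose; its CI is recorded as undefined with a reason and the
remaining levels are still computed.

## Hill fitting

The Hill model B(%) = 100/[1 + (IC50/[D])^n] is fitted by least squares
on the percent-blockade scale (the scale on which the model is stated),
unweighted. The optimizer works in log-parameter coordinates centered
on the geometric-mean dose, with bounds IC50 ∈ [min dose/10³,
max dose·10³] and n ∈ [0.05, 10], IC50 initialized at the dose whose fa
is nearest 0.5 and n at 1 — robust for the shallow slopes (0.4–1)
typical of these blockers. A Gauss–Newton polish after the bounded
solve drives the gradient to machine precision, which makes the
advertised scale equivariance (doses ×c ⇒ IC50 ×c, n unchanged) hold to
~1e-12 rather than the ~1e-9 a bounded trust-region stop leaves behind.
An IC50 above the top tested dose (the sipeimine case, where solubility
capped testing at 30 μM and 43.6% blockade) is reported but flagged
`extrapolated`.

Note the Hill curve with (IC50, n) and the median-effect curve with
(Dm = IC50, m = n) are the same function; the two fits differ only in
objective (percent-scale nonlinear LSQ vs log-odds-scale OLS), which is
why refitting the published mean fa columns gives IC50 estimates near,
but not equal to, the published per-cell values.

## Gating fits

Boltzmann: I/Imax = 1/{1 + exp[(V½ − V)/k]} with k constrained
positive. Activation rises with voltage; steady-state inactivation
falls, yet the same formula and positive k are conventionally quoted
for both. Both orientations (rising, and falling = 1 − rising) are
fitted and the lower-residual one kept, so callers never guess a sign
convention. Data whose y-range is below 0.05 are rejected as
unidentifiable. Voltages are centered before fitting, making the fit
shift-equivariant to machine precision.

Exponentials: A·(1−exp(−t/τ)) + c (rise) or A·exp(−t/τ) + c (decay),
with amplitude and offset free because raw tail amplitudes need not be
normalized; τ is the quantity of interest. τ is optimized in log space
(positivity by construction).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the electrophysiology that produced it:

- **Single drugs** — per-cell fa at each dose = Hill curve + i.i.d.
  Gaussian noise on the percent scale, clamped to [0, 1] (fa is a
  fraction); defaults are 8 cells and noise SD 3 percentage points,
  matching the reported group sizes and standard-error scale of the
  study this pipeline reanalyzes. Both per-cell replicates and the mean
  column are returned, so either fitting convention can be exercised.
- **Combinations** — for each total dose Dt the combined fa solves the
  Loewe dose-equivalence condition Σ wi·Dt/Dxi(fa) = θ by bracketed
  root finding (brentq on fa ∈ [1e-9, 1−1e-9], rtol 1e-14; the left
  side is strictly decreasing in fa so the root is unique; Dx diverges
  at fa→1 and vanishes at fa→0, hence the bracket). The interaction
  multiplier θ is the generator's only non-physiological knob: θ = 1
  produces exactly additive data (downstream CI = 1 identically), and
  any θ is recovered as CI = θ, which is what the recovery tests turn.
- **Gating** — Boltzmann or exponential curve + Gaussian noise, *not*
  clamped: measured normalized currents overshoot [0, 1] slightly and
  the fitters must tolerate that.

All generators require an explicit integer seed (no global random
state) and are bit-reproducible given one.

What the generator does **not** emulate: raw traces, voltage-protocol
waveforms, leak/capacitance artifacts, heteroscedastic or correlated
noise across doses, rundown, or any kinetic state model. Passing
recovery tests therefore demonstrate correctness of the *estimation
machinery* under the assumed noise model, not robustness to every
artifact of real recordings.

## Estimator precision limits (known limitation)

At noise SD 0.03 on a normalized-current curve, the information content
of the sparse step protocols bounds what any fitter can do. Cramér–Rao
bounds: the 15-point activation sweep (−90…+50 mV, 10 mV steps) gives
SE(V½) ≈ 0.67 mV and SE(k)/k ≈ 7.1%; the 9-duration envelope-of-tails
series with free amplitude and offset gives SE(τ)/τ ≈ 8.0%. Recovery
rates inside ±1 mV / ±10% bands are therefore intrinsically below 90%
on those protocols, and the measured rates of this package's fitters
sit at the bounds (the estimators are efficient). A densely digitized
decay trace (0.15 ms/point over 60 ms) constrains τ to ~1.5% and
clears the band comfortably. The unit suite asserts median-error
properties on the sparse protocols and the hard 90% band on the dense
trace; one acceptance-level check intentionally retains the hard band
on the sparse protocols and documents this limit by failing.

## Pipeline and I/O choices

CSV schemas are minimal comma-separated text with a `#` metadata/
comment block; readers are hand-validated line by line so every
diagnostic carries a file name and line number. Combination files
declare components and ratio in metadata, and every data row is checked
against the declared fixed ratio (tolerance 1e-9) — a violated ratio is
a design error, not noise. Reports are JSON (full double precision,
schema-versioned) plus a CSV summary rounded to 6 significant digits.
The pipeline records input SHA-256 hashes and a config echo for
provenance, continues past per-input failures, and exits nonzero if any
input failed.

## Problem sizes

Stochastic recovery checks use 200 seeded replicates per condition;
deterministic checks run on the published 4–6-level dose tables. The
whole suite completes in a few seconds on one CPU.
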