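# Methods

This note documents the models implemented in `dvcqmri`, the defaults and
why they were chosen, and what the synthetic phantom does and does not
emulate.

## Phantom geometry

The rat tail is a stylized cylinder stack (axis 2 = tail axis, 0-based
voxel indices), not an anatomical atlas. One vertebral unit along the tail
axis is

    disc (NP core + AF ring) → CEP → GP → SB → vertebral body → SB → GP → CEP

repeated `n_vertebrae` times. Defaults: 64×64×32 voxels at 0.15 mm
isotropic, two vertebrae, disc height 4 voxels, NP radius 12 voxels, AF
ring 2 voxels. Maturity enters through the endplate: mature animals have
1-voxel CEP and GP slabs, immature animals 2-voxel slabs (and a 40-slice
matrix so two units still fit). The geometry constructor rejects units
that overflow the matrix and slabs thinner than one voxel.

ROIs are the label regions themselves (optionally eroded; the default
pipeline uses no erosion because the phantom has no partial-volume mixing),
plus a background ROI drawn from the volume corners.

## Tissue parameter tables

Each compartment carries T1 (ms), T2 (ms), a proton density (arbitrary
units) and a UTE SNR target. Healthy tables are constant across D0/W1/W2;
degenerative (DDD) tables equal the healthy ones at D0 (pre-induction) and
differ only in NP and AF at W1/W2 — the induced lesion lowers NP T2/T1
(water loss) and raises AF T2 (inflammation), with both structures
brightening on UTE. Values that cannot be measured in vivo are package
assumptions flagged `assumed=true` in the table: GP T2 = 2 ms (the GP must
stay invisible on T2 maps, its decay dying before the first echo),
GP T1 = 1200 ms, CEP T1 = 900 ms, and all vertebral-body entries
(SB-like marrow values). Proton densities (60–100 a.u.) are ordered by
water content; absolute units are arbitrary because the protocol only ever
reports amplitudes relative to the noise.

## Noise model

Magnitude images come from an L-element phased array (default L = 4)
combined by root sum of squares. Each channel receives `A/√L` plus
independent complex Gaussian noise of std σ per real/imaginary component;
equal sensitivities make the noiseless magnitude exactly `A` and the second
moment exactly `A² + 2Lσ²`. A noise-only voxel is chi-distributed with 2L
degrees of freedom and mean `√2·Γ(L+½)/Γ(L)·σ` — 2.7416σ for L = 4, the
"2.74" correction divisor used to estimate σ from a background ROI.

**Default σ = 0.2 a.u.** The T2 fitting model adds the fixed floor `2Lσ²`
to the *magnitude* signal although that term is the offset of the squared
magnitude; the model is therefore only self-consistent when the floor is a
small perturbation, and it biases T2 low by roughly `2Lσ²/PD` otherwise.
σ = 0.2 keeps the floor at 0.32 a.u. — ≤ 0.5% of the weakest compartment's
proton density — while leaving a measurable background (mean 0.55 a.u.).
UTE amplitudes are calibrated as `SNR_target × σ`, so the UTE contrast
matches the study values at any σ.

An optional multiplicative lognormal jitter on per-voxel T1/T2
(`jitter_cv`, default 0) emulates inter-animal spread; by default the only
replicate-to-replicate variation is the noise realization.

## MSME simulation and T2 mapping

Clean echo signal: `PD·exp(−TE/T2)` per voxel, 100 echoes uniform from 3.8
to 378.6 ms, chi noise per echo. TR = 8000 ms is ≥ 4× the longest T1, so
T1 saturation is neglected; no stimulated echoes or slice-profile effects
are modelled (the fit model is a pure mono-exponential plus offset, so
including them would only add a bias the model cannot represent).

The fit minimizes `Σ[S(t) − (S0·exp(−t/T2) + 2Lσ²)]²` over (S0, T2) with
the offset fixed from the background-estimated σ, initialized by a
signal-weighted log-linear regression on the offset-subtracted data, with
bounds S0 ≥ 0, T2 ∈ [0.5, 2000] ms, trust-region least squares at 1e-8
tolerances and ≤ 200 evaluations. Voxels are flagged invalid (NaN, excluded
from ROI means) rather than clamped when: the offset-subtracted signal has
no positive part; the solver fails; T2 lands on a bound; or the fitted
amplitude stays below 5σ — chi fluctuations in signal-free voxels can mimic
a shallow decay, and tissue amplitudes in the phantom are > 100σ, so the
amplitude gate rejects only noise.

Measured on the default phantom, ROI-mean T2 recovers the ground truth to
about 1% (NP, 105 ms) up to ~2% (SB, 96.1 ms; AF, 6 ms). The AF estimate is
tolerance-limited by the echo grid: a 6 ms decay leaves only ~5 echoes
above the floor, and the documented accuracy band for it is a relaxed 25%.

## MP2RAGE simulation and T1 mapping

Longitudinal magnetization over one cycle — inversion (Mz → −eff·Mz),
relax TA, 160-pulse GRE block (each pulse ×cos α, each 6 ms gap relaxing
toward M0), relax TB, second block, relax TC — is an affine map in Mz, and
the periodic steady state is its closed-form fixed point (|slope| < 1 is
guaranteed and asserted). The iterative propagation is retained in the test
suite as an independent oracle; the two agree to < 1e-6.

TI is measured to the center of each block (linear phase encoding):
TA/TB/TC = 320/440/3570 ms at the default parameters. Inversion efficiency
defaults to 1.0 (ideal adiabatic pulse). The combination
`R·GRE1·GRE2/(GRE1²+GRE2²)` uses R = 1 (the scaling constant is a
pass-through); 0/0 voxels give 0 and are flagged.

**Lookup table range.** The ratio is strictly monotone in T1 only up to
the point where |S1| = |S2| (ratio = −0.5), which falls near 3400 ms at the
default parameters with ideal inversion; beyond it the curve folds back.
The default grid is therefore 100→3300 ms in 1 ms steps — well beyond every
tissue T1 in the phantom (≤ 1894 ms) — and `build_lookup_table` refuses a
grid that crosses the fold. Inversion is linear interpolation on the
inverted table; ratios outside the table range are flagged invalid, never
clamped.

Simulated GRE volumes are signed; noise is real Gaussian of std σ on the
coil-combined signal (the matched-filter combination of L channels each
seeing `A/√L` plus noise σ). A receiver gain (default 20) scales PD so the
readout SNR is realistically high; T1 recovery through the full chain is
then accurate to ≪ 1%.

## Quantification

SNR = ROI mean / σ with σ from the background chi-mean rule (the protocol
also mentions an SD-based definition; the explicit 2.74 rule is the
default). CNR is computed for the four neighboring pairs only. The
quantification table is long-form — one row per arm × timepoint ×
structure × metric × replicate — because the downstream tests need
per-replicate samples; `summarize_records` collapses it to mean ± SD.
Cells that are unmeasurable in vivo (GP on T2 maps; CEP and GP on T1 maps)
are excluded by an explicit list and reported as not quantifiable, mirroring
the study tables, rather than by a data-driven rule the noiseless geometry
could not reproduce.

## Statistics

Gates: Shapiro-Wilk on each sample and Bartlett across samples, all at
p > 0.05, select an unpaired equal-variance Student t-test; any gate
failure routes to the two-sided Mann–Whitney U (exact null distribution for
n ≤ 8 without ties, normal approximation with tie correction otherwise).
Identical constant samples return p = 1 on the Mann–Whitney branch.
Comparisons are unpaired (a `force` hook exposes both branches), raw
p-values are reported with the number of contrasts, and no values are
excluded by default. The optional `z3` outlier rule is a jackknifed
z-score — each value scored against the mean/SD of the others — because the
ordinary z-score is bounded by (n−1)/√n and cannot flag an outlier in small
groups; `iqr` is the usual 1.5×IQR fence.

## What the phantom does and does not show

Passing recovery tests demonstrates that the reconstruction chain is
unbiased under the stated acquisition model: piecewise-constant tissue,
ideal coil sensitivities, mono-exponential decay, no B0/B1 inhomogeneity,
no k-space/trajectory effects, no partial volume, no motion, no
T2* decay at the 31 µs UTE echo time. Real data add all of those; in
particular the in-vivo inter-animal SDs are far larger than the
noise-only replicate spread here (use `jitter_cv` to emulate them), and
the UTE compartment amplitudes are calibrated contrast, not a tissue
model. Problem sizes in the shipped experiments (64×64×32 phantom, 10
replicates for recovery, 8 per arm for the longitudinal contrast) were
chosen as the smallest cohorts at which the recovery bands and the gated
tests are stable across seeds.

## Known limitations

* The printed noise-floor offset `2Lσ²` is applied to the magnitude (not
  squared-magnitude) signal, exactly as specified by the protocol; the fit
  is consequently biased low by ~`2Lσ²/PD` and the package keeps σ small
  relative to PD. A squared-domain fit would remove this coupling but is
  deliberately not used.
* Single-component T2 only; no EPG/stimulated-echo correction, no B1+
  correction for MP2RAGE, no Bruker/DICOM readers.
* The Mann–Whitney exact branch refuses nothing: with ties it silently
  uses the tie-corrected normal approximation, which is inaccurate for
  very small heavily-tied samples.
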