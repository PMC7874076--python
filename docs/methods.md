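# Methods

## The study design being modeled

Two participants sit face to face and debate assigned topics on which they
either agree or disagree. Speaking turns alternate on a fixed 15 s cycle over
180 s runs, so each run holds 12 turns, six per speaker, and the experimental
cycle — one talking plus one listening epoch — is 30 s. fNIRS records
multi-channel hemodynamic signals from both heads simultaneously (42 channels
per head in the default montage, grouped into 15 bilateral ROIs with 2–3
channels each); head-mounted microphones record each turn's speech. The
package analyzes three things: channel-level task activation (talking vs.
listening, by condition), cross-brain coupling of slow hemodynamic
fluctuations between partners, and turn-level prosody.

## Signal model of the synthetic generator

Each HbO channel of subject *s* is

    y(t) = β_talk · (talk_s ⊛ h)(t) + β_listen · (listen_s ⊛ h)(t)
         + g · G_s(t) + κ · O(t) · 1[channel ∈ coupled ROI] + σ · ε(t)

with h the canonical double-gamma HRF; G_s a per-subject low-pass (≤0.1 Hz)
Gaussian process identical across that subject's channels (the systemic
global component); O a shared oscillation added to subject 1's `roi_a` and
subject 2's `roi_b`; and ε unit-variance pink Gaussian noise per channel.
HbR is the negative-going mirror of the neural term (activation decreases
deoxyhemoglobin) plus the same non-neural terms; HbT = HbO + HbR exactly.
Defaults: sampling interval 0.1 s (all analyzed frequencies are ≤0.4 Hz, so
nothing above 0.5 Hz matters and desk-scale tests stay fast; the hardware's
27 ms grid is available by argument), β_talk 1.0 (agree) / 1.3 (disagree),
β_listen 0.4, g = 0.3, σ = 0.3, coupling at 12.8 s in AG–SMG (κ 0.7 agree /
0.15 disagree) and OTC–STG (0.6 / 0.15).

Two generator choices deserve explanation because they were forced by the
physics of the measure, not convenience:

* **The shared oscillation is amplitude-modulated.** The coherence statistic
  correlates wavelet **amplitude** envelopes (phase is discarded). A
  constant-amplitude shared sinusoid has a constant envelope — it carries no
  amplitude information at all, and in experiments the detection it produced
  was weak and inverted with SNR. Coupled physiological rhythms wax and wane;
  the generator therefore modulates the shared sinusoid with a shared slow
  envelope (depth 0.6, bandwidth ≤0.03 Hz), which is exactly the feature an
  amplitude-only measure can see.
* **Channel noise is pink, not white.** White noise at σ = 0.3 has almost no
  power in the analyzed 10–20 s band, so after averaging 2–3 channels any
  minuscule shared artifact dominated the band and uncoupled ROI pairs
  cohered spuriously. Real fNIRS channel noise is strongly colored
  (instrument drift, local physiology); 1/f noise restores an honest
  independent noise floor in-band.

Speech per turn is a train of `round(rate × duration)` syllable bursts:
120 ms raised-cosine envelopes (≥60 ms silent dips, so a peak-picking counter
has a defined correct answer) over a sawtooth carrier at a per-syllable F0
drawn uniformly from median ± range/2; male speakers synthesize one octave
lower. Condition defaults (female-reference): agree 3.5 syll/s, 200 Hz
median, 40 Hz range, 0.10 amplitude; disagree 4.0, 214, 54, 0.13 — every
parameter elevated under disagreement. A within-debate decline (last three
turns: rate ×0.90, amplitude ×0.85) models the flagging momentum of a debate
and gives the BINS effect its direction for rate and energy only.

## Preprocessing

* Beer–Lambert: least-squares solve of ΔA = εLΔc per sample; extinction
  coefficients are literature values at 780/805/830 nm (the middle wavelength
  near the isosbestic point) and the differential-pathlength factor defaults
  to 6; both are configuration, since calibrated values are
  instrument-specific.
* Dead channels: RMS > 10× the mean RMS of the *other* channels of that
  subject; excluding the candidate from its own reference prevents an extreme
  channel from masking itself. (Under this rule "all channels dead" is
  mathematically impossible for n ≥ 2; the error branch is defensive.)
* Wavelet detrend: discard the DWT approximation at the level whose band edge
  is nearest the 128 s cutoff (sym8), reconstruct, mean-center. Series
  shorter than one cutoff period are only mean-centered, with a warning.
* Global removal, two operationalizations:
  * `remove_global_pca` — iteratively remove the leading principal component
    while it explains >30% of variance **and** ≥80% of its loadings share a
    sign (a component that moves all channels together). Iteration to a fixed
    point makes the filter idempotent. This is the right tool for activation
    mapping.
  * `remove_global_median` — regress every channel on the cross-channel
    median time course. Used inside the coherence pipeline: a strong
    oscillation confined to 2–3 of 42 channels contaminates the leading PC's
    time course, and subtracting that PC smears an anti-phase copy of the
    oscillation into *every* channel — which then appears as cross-brain
    coherence everywhere (measured: uncoupled-pair rejection 0.88 with the
    PC filter vs. 0.97–0.98 with the median estimate). The median is robust
    to minority-channel structure by construction.

## GLM

OLS per channel on [talk⊛h, listen⊛h, ASE⊛h, 1]; contrast [talk − listen];
two-sided t with df = n − rank; BH-FDR across channels at q = 0.05 (backed by
`statsmodels.multipletests`, checked in tests against an exhaustive step-up
oracle). Second level: paired t per channel across subjects between
conditions, FDR again. The ASE co-regressor is one series per session (both
speakers' turns concatenated), built from 100 ms-window energy at 10 Hz,
HRF-convolved and resampled to the session grid. Because detrending precedes
the GLM, the only drift term is the constant.

## Coherence

Pipeline per subject: regress out the task design per channel **first** (the
DWT detrend distorts the block-periodic design enough that OLS could no
longer cancel it exactly — order matters and is tested), then median-global
removal, ROI averaging, detrending, CWT. The kernel is PyWavelets' `cgau2`
(complex Gaussian, Mexican-hat-shaped). The scale↔period conversion uses the
amplitude-response center frequency of the discretized kernel, 0.4443,
located numerically by scanning scales against known sinusoids;
`pywt.central_frequency` returns the coarser FFT-bin value 0.4, which
misaligns the period grid by ~10%. Period grid: 32 log-spaced points over
2.5–40 s; a cone of influence of √2 × period is excluded at each end; periods
with fewer than three cycles in the record are dropped.

Coherence per period = Pearson r of the two amplitude envelopes; for
cross-ROI pairs both orientations (subject 1's A vs. subject 2's B, and vice
versa) are averaged, making the statistic symmetric under subject exchange.
Condition comparison: per-dyad mean coherence in three equal bins over
10–20 s ([10, 13.33), [13.33, 16.67), [16.67, 20]); paired t-tests when the
same dyads appear in both conditions; significant only if ≥2 consecutive bins
pass at α = 0.05. The 10–20 s window reflects the resolution argument: three
wavelet cycles of the 10 s minimum cycle put the coarsest resolvable period
at 30 s, and hemodynamic coupling concentrates at 10–20 s. The shuffled
control re-pairs subjects within condition by a uniformly drawn cyclic
derangement (Sattolo's algorithm — fixed-point-free by construction) and runs
the identical comparison; cached per-subject amplitude envelopes make 50
re-pairings cost only re-correlation.

## Prosody

* Envelope: 50 ms sliding RMS computed on the **full-band** waveform, then
  decimated ×100. Decimating the audio first (the literal instrumental
  recipe) would put the anti-alias cutoff inside the voice band — at 8 kHz
  synthesis the carrier vanishes entirely — making energy depend on F0 rather
  than loudness.
* ASE: trapezoidal area under the envelope / turn duration; a constant
  envelope of value c yields ASE = c, and ASE is exactly linear in amplitude.
* F0: autocorrelation per 40 ms frame every 10 ms, search 75–500 Hz, voicing
  by normalized-peak threshold 0.45 plus an energy floor, parabolic lag
  refinement. MF0 doubles male values; RF0 applies the Tukey fence
  (±1.5 IQR) before max − min.
* Syllables: peaks of the dB envelope with prominence ≥2 dB and spacing
  ≥100 ms (both configurable); on generator audio the count is exact by
  construction of the burst spacing.
* Keyword scoring: case-insensitive word-boundary phrase counts against
  agree/disagree cue lexicons.

## Behavioral statistics

z-scores use the sample SD (n−1) within speaker pooled over all debates.
The LMM is `z ~ AGREE_NO + TURNS_LAST3` (middle turns excluded when a
speaker has more than six; with six per debate every turn is in a bin),
REML, random intercepts + slopes by speaker, falling back to intercept-only
and then pooled OLS on failure, each fallback flagged in the result.
Satterthwaite degrees of freedom are not available in the installed stack;
t-tests use residual df and the result carries `df_method="residual"` as an
explicit approximation flag. The paired one-sided t-test takes H1: disagree >
agree on turn-matched values; zero-variance differences report p → 0/1 by
sign. The mixed logistic regression uses the variational-Bayes fit of a
binomial mixed GLM with speaker random intercepts (the installed stack has no
Laplace GLMM); its CI calibration was verified by simulation — 95% intervals
covered a true odds ratio of 1.6 in 96 of 100 replicates — and a penalized
plain logistic fallback (flagged) handles separation.

## What the synthetic cohorts do and do not show

Passing tests demonstrate that every stage recovers what the generator put in
at realistic sizes (19 dyads, 180 s runs), that the decision rules control
their false-positive rates on null cohorts, and that the shuffled-pair
control behaves as a genuine null. They do not show that real conversations
produce these effect sizes: synthetic prosodic contrasts are
near-deterministic (t statistics far larger than real speech would give), the
hemodynamic model has no motion artifacts, no Mayer waves or cardiac/
respiratory lines, no inter-subject HRF variability, and speech synthesis is
at the syllable-burst level with no formants, so phonetic-convergence
questions are out of reach. Problem sizes in the test suite and acceptance
script (8 kHz audio, 10 Hz hemodynamics, 100–200 Monte-Carlo replicates) were
chosen as the smallest at which the statistical claims are stable.

## Numerical choices

* Degenerate inputs: constant series give NaN coherence (recorded as
  missing, never fabricated); zero-variance speakers give missing z-scores;
  identical spectra give t = 0, p = 1 rather than NaN.
* The BH implementation is exercised against brute-force enumeration for all
  vector lengths ≤ 12.
* Seeds: every stochastic routine takes an explicit seed or Generator;
  cohort builders derive per-dyad seeds from one root so sessions are
  individually reproducible.
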