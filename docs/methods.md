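# Methods

This note documents the models, the generative design of the synthetic
cohort, the numerical choices, and the known limitations of `pefmri`.

## Learning model

Behavior on the probabilistic learning task is modeled with a basic
Q-learning rule. Each stimulus pair (reward, punishment, neutral) has its
own two action values, initialized at zero; after a choice `c` with
outcome `r` (coded +1 for a win, 0 for no change, −1 for a loss),

    delta = r − Q(c)
    Q(c) ← Q(c) + alpha · delta,

with the unchosen value untouched. Choices follow a softmax with inverse
temperature `beta`. One `(alpha, beta)` pair is shared across the three
stimulus pairs within a subject-session; missed-response trials trigger
no update and contribute nothing to the likelihood. Zero initialization
and unit outcome coding keep values and PEs dimensionless in [−1, 1].

Fitting maximizes the choice likelihood over `alpha ∈ [0.001, 0.999]`,
`beta ∈ [0.01, 20]` with a 50 × 50 log-spaced grid followed by
Nelder–Mead refinement from the best grid point (no random restarts —
the fit is a deterministic function of the data). On every session we
have examined, this matches the minimum of a 400 × 400 exhaustive grid,
so the procedure can be treated as exact maximum likelihood.

**Identifiability.** With ~80 informative trials per session (neutral
trials carry no choice signal), `alpha` is only moderately identified
when `beta` is small: in recovery simulations the generating-vs-recovered
rank correlation is ≈ 0.55–0.65 for `alpha` drawn U[0.1, 0.5] and `beta`
U[1, 6], rising above 0.7 once `beta > 3.5`, and the median absolute
`alpha` error falls below 0.05 only around 400 trials. This is a Fisher-
information limit of the task length, not an optimizer artifact; users
comparing groups on fitted parameters should expect heavily attenuated
effects at 40 trials per valence.

## First-level GLM

Eight event classes are built per session: reward/punishment expected
value at cue onset (height = pre-choice value of the chosen option),
positive and negative reward PE and their punishment analogues at
feedback onset (height = signed `delta`), and unmodulated feedback and
cue events. All events have 2 s duration. "Positive" PE means
better-than-expected in both valences (reward delivered; punishment
omitted). Event classes empty in a session (e.g. no reward omissions)
are dropped with a warning.

Regressors are rendered as height-scaled boxcars on a 0.1 s grid,
convolved with a double-gamma HRF (response gamma peaking at 6 s,
undershoot at 16 s, undershoot ratio 1/6, unit peak), sampled at frame
times, and paired with finite-difference temporal-derivative columns.
Data and design are high-pass filtered by projecting out a cosine/sine
drift basis of harmonics with period ≥ 60 s (both quadratures, so a slow
cosine of any phase is removed exactly; filtering the data and design
is algebraically identical to including the basis as nuisance
regressors). OLS with an intercept yields betas; COPEs are +1 contrasts
on single PE regressors, never weighting derivative columns. A positive
negative-PE COPE means BOLD fell below baseline when an expected reward
was omitted.

**Modulator scaling.** Parametric-modulator heights are standardized to
unit RMS per event class per session (sign preserved; `normalize=None`
restores raw model units and `demean` optionally mean-centers first).
Rationale: the COPE for a raw modulator is "response per unit of modeled
PE", and the modeled PE amplitude depends on the fitted learning rate —
a session fitted near `alpha ≈ 0` has all modeled values near zero, so
its raw-units COPE is an ill-conditioned ratio that can explode by an
order of magnitude. Unit-RMS modulators bound this at
`w · corr(fitted, generating regressor)` and make COPEs comparable
across subjects; since BOLD units are scanner-arbitrary, no
interpretable scale is lost. The simulator builds its signals through
the same code path, so a zero-noise cohort is recovered exactly
regardless of this choice.

## Synthetic cohort

The generator emulates a two-group (control/OCD, 18 each), three-session
(placebo/amisulpride/pramipexole, order counterbalanced) study of the
120-trial task (40 per valence; win probability 0.7 for the good option,
0.3 for the bad; mirrored loss probabilities on punishment pairs;
neutral pairs never pay). The task timing makes each trial exactly 6.5 s
(cue + decision, 3 s choice display, 1 s feedback, fixation absorbing
the unused response window), so the default run length is derived from
the schedule — 398 volumes at TR 2 s including a 16 s tail — rather than
assumed.

Per-subject parameters: `alpha` truncated-normal around 0.27 (controls)
or 0.22 (OCD) with SD 0.085 (a group-mean standard error of 0.02 at
n = 18); `beta` around 3 (SD 1). RTs are truncated lognormal with
session-specific medians (0.75 / 0.74 / 0.83 s), encoding a slowing
under pramipexole. Missed responses are off by default (`p_miss`
configurable); the analysis path handles them regardless.

ROI BOLD is a weighted sum of the session's own convolved regressors
plus slow drift (random sub-1/60 Hz cosines, SD 0.8) and white noise
(SD 0.5, giving a COPE estimation SE ≈ 0.1 at ~400 volumes). Coupling
weights per group × session × ROI × PE-sign are the study conditions:

| measure | control | OCD |
|---|---|---|
| cingulate negative-PE | 0 everywhere | 0.5 placebo, 0 drugs |
| cingulate positive-PE | 0.1 | 0.1 |
| accumbens positive-PE | 0.15 | 0.65 |
| accumbens negative-PE | 0 | 0 |

with a stable per-subject offset (SD 0.4) and per-session jitter
(SD 0.25) added to every realized weight, and constant feedback/cue
couplings (0.3 / 0.2) shared by everyone. The 0.5 group contrasts were
chosen analytically so the standardized placebo group effect lands near
partial η² ≈ 0.2 and the accumbens group effect near ≈ 0.3 at n = 18
per group — the magnitudes the design targets — with the between-subject
offset dominating the between-subject error term and the smaller session
jitter keeping within-subject tests (interaction, post-hocs) stronger
than the univariate group test, as in the target pattern.

OCD trait scores: SRQ totals are drawn through a Gaussian copula against
the subject's realized placebo cingulate negative-PE coupling with a
latent Pearson correlation `2·sin(π·ρ_s/6)` targeting Spearman
ρ_s = −0.7; subscales correlate ≈ 0.7 with the total; Y-BOCS is drawn
independently of everything (its null correlation with the cingulate
signal is part of the emulated pattern). A dichotomized medication class
(high / not-high dose, roughly 10:8) is assigned at random, independent
of the signal, so the medication factor is null by construction.

An optional outlier switch spikes the cingulate coupling of 1–3 subjects
to exercise the exclusion rule; an optional volume mode renders each
session into a 12³-voxel, 4 mm NIfTI with the cingulate sphere and a
*synthetic* accumbens block (pure geometry, not anatomy) embedded, to
exercise the voxelwise-GLM and mask-extraction path end to end.

What the simulator does **not** emulate: motion, physiological noise,
spatial/temporal autocorrelation beyond cosine drift, hemodynamic
variability across regions, non-Q-learning behavioral strategies, or
model misspecification. Passing tests therefore demonstrate that the
pipeline is correct and well-calibrated under its own assumptions — not
that those assumptions hold in real data.

## Group statistics

COPE records (one scalar per subject × session × ROI × contrast) pass
through: (1) pooled outlier exclusion — mean and SD over *all* values of
a ROI × contrast (both groups, all sessions); a subject with any session
strictly beyond 3 SD is dropped listwise from that ROI × contrast; (2) a
mixed group × session ANOVA (pingouin backend) reporting F, dfs, p and
partial η² = SS_effect/(SS_effect + SS_error), uncorrected dfs by
default with Greenhouse–Geisser behind a flag; (3) within-group
repeated-measures ANOVAs with paired post-hocs, Bonferroni-adjusted
(`p_adj = min(1, 3·p)` for three pairs); (4) per-session one-way group
ANOVAs computed from the SS decomposition and cross-checked against the
F = t² identity at every call; (5) the medication-class mixed ANOVA
within patients; (6) Spearman correlations with average-rank ties,
p-values from the t approximation for n > 10 and a seeded permutation
test otherwise.

The interaction test's type-I error is calibrated: with group-equal
couplings (compound-symmetric errors) it rejects at 5.0 ± 1% over
thousands of replicates.

## Problem sizes and numerical choices

Tests and the acceptance script run everything at the study's own scale
(36 subjects × 3 sessions × ~400 volumes) or smaller. The end-to-end
pattern check uses 100 independent cohort seeds; the type-I calibration
uses 2000 ROI-level replicates (coupling draws analyzed directly,
no BOLD); generator-only properties (e.g. the SRQ copula) shorten the
task to a few trials since they do not depend on BOLD content; recovery
studies use 60–100 simulated subjects. Convolution uses a 0.1 s grid and
a 32 s kernel; the drift basis includes the harmonic at exactly the
cutoff period; OLS uses `lstsq` with a rank check (pseudoinverse plus
warning on deficiency); all RNG streams descend from a single seed via
`numpy.random.SeedSequence.spawn` (cohort → subject → session →
schedule/behavior/BOLD), so equal seeds give byte-identical studies.

## Known limitations

- Parameter recovery at 40 reward trials is weak (see above); group
  differences in fitted `alpha` of the emulated size (0.05) are rarely
  significant at n = 18 — consistent with a marginal effect at best.
- Punishment-PE regressors are built but no group hypotheses are tested
  on them.
- The accumbens mask in volume mode is synthetic geometry; real analyses
  should supply an anatomical mask NIfTI (`RoiSpec(kind="mask")`,
  threshold 0.5 by default). The "14 mm" cingulate sphere is interpreted
  as a radius; a `radius_is_diameter` flag covers the other convention.
- No prewhitening or slice-timing correction (temporal derivatives stand
  in for the latter); no voxelwise group inference.
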