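# Methods

This note documents the model, the synthetic benchmark, the numerical
choices, and the limits of what the package's tests demonstrate.

## Model

The architecture is a perception–action (PerAc) stack: a reflex visual
pathway proposes where to look, an incremental prototype memory describes
what is seen, and associative conditioning links those descriptions to the
robot's own motor state. Person recognition is never trained directly; it
emerges from coupling a prediction-error novelty detector to the prototype
memory's recruitment dynamics.

### Visual front-end

The saliency map is the difference-of-Gaussians filtering (σ₁ = 1 px,
σ₂ = 2 px, reflect borders) of the gradient norm (central differences,
reflect borders). Focus points are selected greedily in descending saliency
with Chebyshev non-max suppression (radius 6 px), ties broken row-major so
the output is deterministic; 20 points per 128×128 frame. Around each point
a log-polar view is sampled: 16 rings geometrically spaced from 1 to
r_max = 56 px, 16 uniform angles, bilinear interpolation, nearest-border
padding. Each output cell averages a 3×3 sub-grid in (log r, θ) space;
without this the outer rings (neighbouring samples tens of pixels apart)
alias badly and the views become dominated by sampling noise rather than
body shape. r_max = 56 makes every view semi-global: local placement comes
from the focus point, while the outer rings see overall body proportions,
which is where partner identity lives. Rotations and rescalings of the
underlying pattern become (approximate) circular shifts of the grid, which
the tests verify.

### Prototype memory (VF)

Similarity is normalized L1: VF_j = max(0, 1 − mean|I − W_j|), which is 1
exactly at a bit-identical match. Recruitment is vigilance-gated: if no
prototype reaches γ the view is stored one-shot as a new neuron; otherwise
only the winner moves, W_k += ε(I − W_k)(1 − VF_k), a long-term average that
moves less the better the match. Neurons are never removed. Defaults
γ = 0.96, ε = 0.1. γ was calibrated against the measured view statistics of
the default avatars: re-rendered views of the same avatar score ≈ 0.95 to
their best prototype while views of a different avatar score ≈ 0.93, so the
gate must sit between jitter noise and identity differences; values near
0.9 recognize everything and identity is never encoded.

The Heaviside gate of the vigilance is applied to the activity vector that
feeds all conditioning: entries below γ are silenced. This keeps the LMS
input sparse (1–3 active prototypes per view), which is required for
stability of the fixed-rate delta rule (the update diverges when
rate > 2/‖x‖², and ungated vectors have hundreds of entries near 0.9) and
prevents every prototype from leaking into every association. Recruitment
itself uses the raw similarity.

### Conditioning, STM, readout

Posture conditioning (MISP) is plain Widrow-Hoff at rate 0.3 from gated
activities to the commanded-posture one-hot; the rate is high because
desk-scale sessions give each prototype only a handful of conditioning
steps. The short-term memory is a leaky integrator, s ← 0.7 s + 0.3 y,
reset at the start of every test sequence; readouts are winner-take-all
with ties to the lowest index.

### Novelty detection and the person network

The detector consumes a scalar error stream e(t): by default the person
pathway's *self-prediction error* — the scaled Euclidean distance between
the person map's output for the current views and the one-hot of the
partner the system currently believes it is seeing. While the partner is
familiar this is low (the map keeps confirming the belief); a new partner's
views excite freshly recruited prototypes (predicting nothing) or another
person's associations, and the error jumps. Two alternative streams are
selectable in the config: the posture (MISP) prediction error, and the VF
recruitment rate. In this generator the posture error carries almost no
partner information — posture prediction generalizes across partners by
design, which is desirable for imitation — so it is not the default.

The detector keeps E(t), the mean of e over a 5-frame window, and
V = EMA₀.₆(−dE/dt), the smoothed negative gradient of the mean error. An
event fires when V crosses below −θ (θ = 0.01) outside a 15-frame
refractory period; t = 0 always fires event 0 because the first partner has
no baseline to rise from. The (window, smoothing, θ) triple was calibrated
once on the benchmark's error statistics: the switch-induced error jump is
≈ 0.3 over a ≈ 0.35 baseline with ≈ 0.07 frame noise, giving a wide stable
operating band (θ anywhere in roughly 0.004–0.015 detects every switch
exactly once); θ = 0.01 is the centre of that band. Note the race inherent
to a closed loop: conditioning toward the old belief re-absorbs the error
jump within a few frames, so the detector must respond within ~2–3 frames —
hence the short window and light smoothing. A partner's tenure must also
exceed the refractory period (15 learning frames), or switches are
swallowed; with the default 1/10 subsampling this means blocks of at least
~200 raw frames.

Each event recruits a neuron in the person network. Two person pathways
share the events:

* a *belief map* (full gated activities → current person, Widrow-Hoff)
  whose error drives the detector, and
* the *recognition readout*: each VF prototype is owned by the person
  current at its recruitment, and the connection from prototype to its
  owner's neuron is set to 1 one-shot. At test, each view passes a local
  competition (only its best-matching prototype keeps activity, if above
  γ) and thereby votes for the owner of the prototype it most resembles;
  votes are averaged over the frame's 20 views, optionally integrated by
  the STM, then read by WTA.

The one-shot ownership wiring is deliberate. A sequentially trained LMS
readout suffers catastrophic recency here: partners appear in blocks, so
shared prototypes end up associated with whichever partner used them last,
and early partners become invisible (measured: 10 of 12 partners at 0%).
Ownership wiring cannot be eroded, and implements directly the premise that
the neurons *needed to learn* a partner are that partner's signature.

## Synthetic benchmark

The generator emulates a turn-taking imitation session: 12 humanoid
silhouettes ("avatars"), one contiguous block each, imitating 5 postures
(arms down / both up / left up / right up / T-pose) over 300 frames per
block, learning on the 1/10 temporal subsample. Avatars share gray level
and differ in morphology: arm length {28, 36, 44} × torso width {18, 26} ×
head radius {8, 12} crossed to give 12, each then perturbed by a small
seeded amount per trait and given its own torso height and arm width — real
bodies never share exact measurements, and exactly shared trait values
would mean a new partner introduces no novel local views at all. Each
avatar also has a fixed idiosyncratic imitation style (per-arm posture
offset up to ±8°, derived from its seed): the "social signature" with which
different people perform the same posture, which real partners always have.
Per-frame variability is ±2 px body translation, ±3° limb-angle noise, and
additive Gaussian pixel noise (σ = 0.02). Commanded postures cycle through
shuffled permutations (run lengths 5–15 frames), keeping classes balanced
the way a robot drawing each posture about equally often would.

What the generator does *not* emulate: backgrounds and clutter, lighting,
clothing and texture, non-rigid motion, imperfect or delayed imitation,
scale changes from distance, or any appearance overlap between posture and
identity beyond shared geometry. Passing tests therefore show that the
architecture's emergence story works when its assumptions (temporal
continuity, distinct morphologies, shared repertoire) hold — they do not
show robustness to real video.

## Test protocol and statistics

Known frames are the learning subsample (frame index ≡ 0 mod 10), unknown
frames the complement. Per partner and condition, 100 frames are drawn
seeded from the pool — without replacement when the pool suffices, with
replacement otherwise (logged; the known pools of 30 frames require it) —
and presented in original order or shuffled; the same seed draws the same
multiset either way. The STM is reset between batteries and disabled in the
shuffled conditions, where temporal continuity is meaningless. Chance is
100/N percent; condition means are tested against chance with exact
one-sided binomial tests on pooled hits, and 95% confidence intervals use a
seeded percentile bootstrap of the mean (10 000 replications). No
multiple-testing correction is applied. The known/unknown and
random/non-random effects are reported as signs of mean differences only;
mixed-model estimation is out of scope.

## Determinism and degenerate inputs

Every stochastic choice (session schedule, jitter, battery sampling,
bootstrap) flows from explicit integer seeds; the learning stack itself is
deterministic given the frame stream, and two runs with equal seeds are
bit-identical. Ties are resolved lowest-index (WTA) or row-major (focus
points). Degenerate cases are defined: empty prototype banks yield empty
activity vectors, constant images yield zero saliency and hence no focus
points, all-equal bootstrap samples collapse the CI to a point, and a
single-partner session trivially scores 100% in all conditions.

## Known limitations

* The benchmark is desk-scaled: 300 frames per partner (≈ 30 learning
  frames) rather than minutes of video; absolute scores are therefore not
  comparable to human-video studies, only the qualitative pattern is.
* Event detection assumes blockwise partner presence with tenures longer
  than the refractory period; interleaved or very short encounters merge
  partners.
* There is no open-set rejection: every frame is attributed to some known
  person, and person neurons are never merged or forgotten.
* A handful of avatar pairs that differ only in fine morphology remain
  partly confusable (per-partner scores range from ≈ 45% to 100%), which
  mirrors the spread reported for hard identification regimes.
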