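# imitrec

Sensory-motor imitation learning with emergent person recognition.

`imitrec` implements a perception–action (PerAc) learning architecture for
the mutual-imitation setting in developmental robotics: a robot commands a
posture, its partner imitates it, and the robot — seeing only the partner —
learns to associate what it sees with what it did. Nothing in the
architecture is ever told *who* the partner is; yet, by monitoring its own
prediction error, the system detects each change of partner as a novelty
event, recruits one person neuron per partner, and can afterwards re-identify
each partner from images alone. The package is aimed at researchers in
developmental robotics and computational cognitive modelling who want a
desk-scale, fully reproducible testbed for this emergence effect, with no
robot and no video data required.

## The architecture

Per frame, the pipeline is:

1. **Reflex attention** — focus points are the non-max-suppressed peaks of a
   difference-of-Gaussians filtering of the image gradient norm
   ‖∇I‖ ∗ (G<sub>σ1</sub> − G<sub>σ2</sub>), which lands on corners and limb
   extremities. A log-polar local view (16 rings × 16 angles) is extracted
   around each of the 20 strongest points.
2. **Visual features (VF)** — an incremental prototype network. Each view's
   similarity to prototype j is VF<sub>j</sub> = max(0, 1 − mean|I − W<sub>j</sub>|).
   If max<sub>j</sub> VF<sub>j</sub> < γ (vigilance), a neuron is recruited
   one-shot (W = I); otherwise the winner is averaged toward the view,
   W<sub>k</sub> += ε (I − W<sub>k</sub>)(1 − VF<sub>k</sub>). Activities
   below γ are silenced (Heaviside gate) before conditioning.
3. **Posture conditioning (MISP)** — a Widrow-Hoff / LMS map from gated VF
   activities to the commanded-posture one-hot (MIS):
   Δw = η (target − w·x) x. A leaky short-term memory
   (s ← λ s + (1 − λ) y) feeds a winner-take-all posture readout (PR).
4. **Novelty detection** — the person pathway keeps predicting the partner
   it believes it is seeing; the scalar error e(t) between that prediction
   and the belief is averaged over a sliding window, E(t), and
   V = EMA(−dE/dt) is tracked. A crossing of V below −θ (the mean error
   rising persistently) is a rising edge of novelty: a new person. Each
   event recruits a person neuron, and every VF prototype recruited during
   that person's tenure is wired to it one-shot — identity is coded by the
   set of visual prototypes a partner's learning required.
5. **Recognition test** — learning is frozen and each partner is re-presented
   under 4 conditions crossing two contrasts: frames *known* (the 1/10
   subsample used during learning) vs *unknown* (the held-out 9/10), in the
   *original order* vs *shuffled* (the shuffled conditions disable the STM).
   The score per partner and condition is the percentage of images whose
   winner-take-all person readout matches the true partner, compared to
   chance = 100/N percent.

A seeded avatar generator supplies the benchmark: 12 humanoid silhouettes
differing only in parametric morphology (arm length/width, head radius,
torso size) and idiosyncratic imitation style, each imitating the robot's
5 postures over a 300-frame block with per-frame jitter and pixel noise.

## Worked example

```python
import imitrec as ir

cfg = ir.Config()                       # all architecture parameters
specs = ir.default_avatar_specs()       # the 12-avatar benchmark set
result = ir.run_experiment(specs, cfg, seed=1)

print(result.n_persons, len(result.events))
print(ir.summarize(result)[["condition", "mean_score", "binomial_p"]])
print(ir.contrast_check(result.table))
```

Output (about 2.5 minutes on one CPU):

```
12 12
         condition  mean_score  binomial_p
      random/known   82.666667         0.0
  non-random/known   83.750000         0.0
    random/unknown   76.750000         0.0
non-random/unknown   79.583333         0.0
{'known_effect_sign': 1, 'random_effect_sign': -1}
```

The system detected exactly 12 novelty events for 12 partners and recruited
12 person neurons. All four condition means are far above the 8.3% chance
level (one-sided binomial p ≈ 0 on 1200 pooled images per condition), frames
seen during learning are recognized better than held-out ones
(`known_effect_sign = +1`), and shuffling the presentation order — which
removes the temporal continuity the short-term memory exploits — lowers the
score (`random_effect_sign = -1`).

The same pipeline is scriptable from the shell: `imitrec generate` writes a
synthetic session as PNG frames with a CSV manifest, `imitrec train` runs
learning plus the battery and stores a JSON checkpoint with CSV logs, and
`imitrec test` / `imitrec report` print the score table, bootstrap 95%
confidence intervals, binomial p-values and contrast signs.

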