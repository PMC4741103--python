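"""Self-assessment by prediction error and the emergent person network.

While being imitated, the system continuously predicts the signals it has
learned to expect -- which partner it believes it is seeing, and which
posture it commanded. A scalar prediction error e(t) is low while the
current partner is familiar; when a new partner appears the prediction
stops matching and the error jumps. The novelty detector tracks the
windowed mean error E(t) and a smoothed version V(t) of its negative
gradient -dE/dt. A sustained *increase* of the mean error drives V below a
(negative) threshold; that crossing is the rising edge of the novelty
signal and is interpreted as a new event -- a new person. Each event
recruits one neuron in the person-recognition network, so after a session
the person network holds exactly one neuron per detected partner.

The default error stream is the person pathway's own self-prediction error
(its output versus the running belief about who is present); the posture
(MISP) prediction error and the VF recruitment rate are alternative
detector channels, selectable in the configuration.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .neural import AssociativeMap, STMBuffer, lms_step, one_hot, stm_update, wta

SQRT2 = math.sqrt(2.0)


def frame_error(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Scalar prediction error: ``||predicted - actual|| / sqrt(2)``.

    For predictions bounded in [0, 1] against a one-hot target the value lies
    in [0, 1]; it is 0 exactly for a perfect one-hot prediction.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have the same length")
    return float(np.linalg.norm(predicted - actual) / SQRT2)


@dataclass
class NoveltyState:
    """Running novelty statistics over a scalar error stream.

    ``V`` is an exponential smoothing of ``-dE/dt`` where E is the sliding-
    window mean error. An event fires when V crosses below ``-threshold``
    (i.e. the mean error is rising persistently) outside the refractory
    period. The very first sample always fires event 0: the first partner
    has no error baseline to rise from.
    """

    window: int = 5
    smoothing: float = 0.6
    threshold: float = 0.01
    refractory: int = 15
    errors: deque = field(default_factory=deque)
    E: float = 0.0
    E_prev: float = 0.0
    V: float = 0.0
    refractory_remaining: int = 0
    started: bool = False
    events: list[tuple[int, int]] = field(default_factory=list)  # (time, event_index)

    def __post_init__(self) -> None:
        self.errors = deque(self.errors, maxlen=self.window)


def novelty_step(state: NoveltyState, e_t: float, t: int) -> tuple[NoveltyState, bool]:
    """Advance the detector by one frame; returns (state, event_fired)."""
    if not math.isfinite(e_t):
        raise ValueError("error sample must be finite")
    state.errors.append(float(e_t))
    state.E = float(np.mean(state.errors))
    if not state.started:
        state.started = True
        state.E_prev = state.E
        state.events.append((t, 0))
        state.refractory_remaining = state.refractory
        return state, True
    g = state.E - state.E_prev
    state.E_prev = state.E
    v_new = state.smoothing * state.V + (1.0 - state.smoothing) * (-g)
    fired = False
    if state.refractory_remaining > 0:
        state.refractory_remaining -= 1
    elif state.V >= -state.threshold and v_new < -state.threshold:
        state.events.append((t, len(state.events)))
        state.refractory_remaining = state.refractory
        fired = True
    state.V = v_new
    return state, fired


def person_prediction_error(view_activities: list[np.ndarray], model: "PersonModel") -> float:
    """Self-assessment signal: how badly the person pathway predicts its own belief.

    For each view the person map's prediction is compared (scaled Euclidean
    distance, as in :func:`frame_error`) against the one-hot of the partner
    the system currently believes it is interacting with. While a familiar
    partner is present the map keeps confirming the belief and the error is
    low; a new partner's views either excite freshly recruited prototypes
    (predicting nothing) or another person's associations, so the error
    jumps. Before any person exists the error is maximal (1.0).
    """
    if model.current_person < 0 or not view_activities:
        return 1.0
    belief = one_hot(model.current_person, model.n_persons)
    width = max(model.belief_map.n_inputs, max(a.shape[0] for a in view_activities))
    model.belief_map.grow_inputs(width)
    errs = []
    for acts in view_activities:
        padded = np.zeros(width)
        padded[: acts.shape[0]] = acts
        errs.append(frame_error(model.belief_map.predict(padded), belief))
    return float(np.mean(errs))


@dataclass
class PersonModel:
    """Person-recognition network: one output neuron per detected partner.

    Two conditioning pathways share the novelty events:

    * ``belief_map`` is conditioned on the full activity vector toward the
      current person. It keeps confirming the running belief, and its
      prediction error is the novelty detector's input stream.
    * ``person_map`` (the frozen recognition readout) is wired one-shot: when
      a VF prototype is recruited, the connection from it to the current
      person's neuron is set to 1. Identity is coded by the set of visual
      prototypes a partner's learning required -- exactly the coupling
      between VF recruitment dynamics and the person network that makes
      person recognition emerge -- and, being one-shot, it cannot be eroded
      when a later partner re-activates a shared prototype.
    """

    person_map: AssociativeMap
    belief_map: AssociativeMap
    stm: STMBuffer
    current_person: int = -1
    owners: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @classmethod
    def empty(cls, lms_rate: float = 0.05, stm_decay: float = 0.7) -> "PersonModel":
        return cls(AssociativeMap(np.zeros((0, 0)), lms_rate),
                   AssociativeMap(np.zeros((0, 0)), lms_rate),
                   STMBuffer.zeros(0, stm_decay))

    @property
    def n_persons(self) -> int:
        return self.person_map.n_outputs


def person_learn_frame(view_activities: list[np.ndarray], model: PersonModel,
                       event: bool) -> PersonModel:
    """One learning step of the person pathway for one frame.

    A novelty event recruits a fresh person neuron and switches the current
    person to it. VF prototypes first seen on this frame are owned by the
    current person and wired one-shot to its readout neuron; every view's
    full activity vector is additionally Widrow-Hoff-conditioned toward the
    current person in the belief map that feeds the novelty detector.
    """
    if event:
        model.person_map.grow_outputs(model.n_persons + 1)
        model.belief_map.grow_outputs(model.person_map.n_outputs)
        model.stm.grow(model.n_persons)
        model.current_person = model.n_persons - 1
    if model.current_person < 0:
        raise ValueError("no person neuron exists; an event must precede conditioning")
    if not view_activities:
        return model
    width = max(a.shape[0] for a in view_activities)
    old_width = model.person_map.n_inputs
    model.person_map.grow_inputs(width)
    model.belief_map.grow_inputs(width)
    if width > model.owners.shape[0]:
        new = np.full(width - model.owners.shape[0], model.current_person, dtype=np.int64)
        model.owners = np.concatenate([model.owners, new])
    if width > old_width:  # one-shot wiring of the newly recruited prototypes
        model.person_map.weights[model.current_person, old_width:width] = 1.0
    target = one_hot(model.current_person, model.n_persons)
    for acts in view_activities:
        padded = np.zeros(model.belief_map.n_inputs)
        padded[: acts.shape[0]] = acts
        lms_step(padded, target, model.belief_map)
    return model


def predict_person_frame(views: list[np.ndarray], net, model: PersonModel) -> np.ndarray:
    """Frozen per-frame person activation: mean over views of the map output.

    Each view first passes a local competition: only its best-matching
    prototype keeps its activity, and only if it clears the vigilance gate,
    so a view effectively votes for the person whose learning recruited the
    prototype it resembles most. Votes are averaged across the frame's views.
    """
    if not views:
        return np.zeros(model.n_persons)
    mat = np.stack(views)  # (n_views, dim)
    acts = np.maximum(0.0, 1.0 - np.mean(np.abs(mat[:, None, :] - net.prototypes[None, :, :]), axis=2))
    winners = acts.argmax(axis=1)
    wta_acts = np.zeros_like(acts)
    rows = np.arange(acts.shape[0])
    wta_acts[rows, winners] = acts[rows, winners]
    wta_acts = np.where(wta_acts >= net.gamma, wta_acts, 0.0)  # vigilance gate
    if wta_acts.shape[1] != model.person_map.n_inputs:  # pad if map lags recruitment
        padded = np.zeros((wta_acts.shape[0], model.person_map.n_inputs))
        w = min(wta_acts.shape[1], model.person_map.n_inputs)
        padded[:, :w] = wta_acts[:, :w]
        wta_acts = padded
    return (model.person_map.weights @ wta_acts.T).mean(axis=1)


def recognize_person(frame_predictions: list[np.ndarray], model: PersonModel,
                     use_stm: bool = True,
                     true_person: int | None = None) -> tuple[list[int], float | None]:
    """Read out person identity over an ordered image sequence (frozen model).

    ``frame_predictions`` are per-frame person activation vectors (see
    :func:`predict_person_frame`). The STM is reset at the start of the
    sequence and integrates activations only when ``use_stm`` is true (the
    random-order test condition disables it, since temporal continuity is
    meaningless there). Returns the per-image winning neuron indices and, if
    the true identity is given, the recognition score in percent.
    """
    if not frame_predictions:
        raise ValueError("empty image sequence")
    model.stm.reset()
    model.stm.grow(model.n_persons)
    winners: list[int] = []
    for pred in frame_predictions:
        read = stm_update(model.stm, pred) if use_stm else pred
        winners.append(wta(read))
    score = None
    if true_person is not None:
        hits = sum(1 for w in winners if w == true_person)
        score = 100.0 * hits / len(winners)
    return winners, score
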