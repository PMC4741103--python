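"""The learning stack: incremental visual-feature prototypes, associative
conditioning, short-term memory and winner-take-all readout.

The visual-feature (VF) network is an incremental prototype memory: each
neuron stores one log-polar local view. A view is *recognized* when its best
prototype similarity reaches the vigilance gamma; otherwise a new neuron is
recruited one-shot with weights equal to the view. Recognized views pull the
winning prototype toward themselves at rate epsilon, weighted by how far the
view is from the prototype, which performs long-term averaging. Neurons are
never removed, so the neuron count is a monotone record of visual novelty.

Conditioning from VF activities to a one-hot target (commanded posture
during learning, later person identity) uses the Widrow-Hoff / least-mean-
squares delta rule. A leaky short-term memory integrates the instantaneous
class activations before the winner-take-all readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MotorInternalState:
    """The robot's commanded posture, exposed as a one-hot vector."""

    posture: int
    n_postures: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.posture < self.n_postures:
            raise ValueError("posture index out of range")

    @property
    def one_hot(self) -> np.ndarray:
        return one_hot(self.posture, self.n_postures)


def one_hot(index: int, n: int) -> np.ndarray:
    if not 0 <= index < n:
        raise ValueError("index out of range")
    v = np.zeros(n)
    v[index] = 1.0
    return v


@dataclass
class VFNetwork:
    """Growing bank of prototype vectors with vigilance-gated recruitment."""

    gamma: float = 0.96
    epsilon: float = 0.1
    prototypes: np.ndarray | None = None  # (n_neurons, dim)
    recruit_log: list[tuple[int, int]] = field(default_factory=list)  # (time, neuron)

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must be in [0, 1)")

    @property
    def n_neurons(self) -> int:
        return 0 if self.prototypes is None else self.prototypes.shape[0]


def vf_activities(view: np.ndarray, net: VFNetwork) -> np.ndarray:
    """Similarity of a view to every prototype: ``max(0, 1 - mean |I - W|)``.

    Activities lie in [0, 1] and equal 1 exactly when the view matches the
    prototype bit-for-bit. An empty network yields an empty vector.
    """
    if net.prototypes is None:
        return np.zeros(0)
    view = np.asarray(view, dtype=np.float64)
    d = np.mean(np.abs(net.prototypes - view[None, :]), axis=1)
    return np.maximum(0.0, 1.0 - d)


def gated_activities(activities: np.ndarray, gamma: float) -> np.ndarray:
    """Vigilance (Heaviside) gate: activities below gamma are silenced.

    The raw similarity drives the recruitment decision; the *gated* vector is
    what the conditioning pathway sees. Gating keeps the LMS input sparse
    (only recognized prototypes fire), which both stabilizes the fixed-rate
    delta rule and stops unrelated prototypes from leaking into every
    association. After recruitment the winner is at activity 1, so the gate
    never starves learning.
    """
    return np.where(activities >= gamma, activities, 0.0)


def vf_learn(view: np.ndarray, net: VFNetwork, t: int = 0) -> tuple[VFNetwork, int, bool]:
    """One vigilance-gated learning step; returns (net, winner, recruited).

    Below-vigilance recognition (or an empty network) recruits a neuron whose
    weights are a one-shot copy of the view. Otherwise only the best-matching
    neuron k is updated, ``W_k += epsilon * (I - W_k) * (1 - VF_k)``: the
    closer the view already is, the smaller the adjustment.
    """
    view = np.asarray(view, dtype=np.float64)
    if not np.all(np.isfinite(view)):
        raise ValueError("view contains non-finite values")
    acts = vf_activities(view, net)
    if acts.size == 0 or float(np.max(acts)) < net.gamma:
        new = view[None, :].copy()
        net.prototypes = new if net.prototypes is None else np.vstack([net.prototypes, new])
        j = net.n_neurons - 1
        net.recruit_log.append((t, j))
        return net, j, True
    k = int(np.argmax(acts))  # ties resolve to the lowest index
    net.prototypes[k] += net.epsilon * (view - net.prototypes[k]) * (1.0 - acts[k])
    return net, k, False


@dataclass
class AssociativeMap:
    """LMS-trained linear map from input activities to class activations."""

    weights: np.ndarray  # (n_outputs, n_inputs)
    learning_rate: float = 0.05

    @classmethod
    def empty(cls, n_outputs: int, learning_rate: float = 0.05) -> "AssociativeMap":
        return cls(np.zeros((n_outputs, 0)), learning_rate)

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    def grow_inputs(self, n_inputs: int) -> None:
        """Zero-pad new input columns as VF neurons are recruited."""
        if n_inputs < self.n_inputs:
            raise ValueError("input count cannot shrink")
        if n_inputs > self.n_inputs:
            pad = np.zeros((self.n_outputs, n_inputs - self.n_inputs))
            self.weights = np.hstack([self.weights, pad])

    def grow_outputs(self, n_outputs: int) -> None:
        """Zero-pad new output rows as classes (persons) are recruited."""
        if n_outputs < self.n_outputs:
            raise ValueError("output count cannot shrink")
        if n_outputs > self.n_outputs:
            pad = np.zeros((n_outputs - self.n_outputs, self.n_inputs))
            self.weights = np.vstack([self.weights, pad])

    def predict(self, activities: np.ndarray) -> np.ndarray:
        activities = np.asarray(activities, dtype=np.float64)
        if activities.shape[0] != self.n_inputs:
            raise ValueError("activity vector length does not match map inputs")
        return self.weights @ activities


def lms_step(activities: np.ndarray, target: np.ndarray, amap: AssociativeMap) -> AssociativeMap:
    """One Widrow-Hoff step: ``W += rate * outer(target - W x, x)``."""
    activities = np.asarray(activities, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if target.shape[0] != amap.n_outputs:
        raise ValueError("target length does not match map outputs")
    y = amap.predict(activities)
    amap.weights += amap.learning_rate * np.outer(target - y, activities)
    return amap


@dataclass
class STMBuffer:
    """Leaky integrator over class activations: sums and filters recent input."""

    state: np.ndarray
    decay: float = 0.7

    @classmethod
    def zeros(cls, n: int, decay: float = 0.7) -> "STMBuffer":
        return cls(np.zeros(n), decay)

    def reset(self) -> None:
        self.state = np.zeros_like(self.state)

    def grow(self, n: int) -> None:
        if n > self.state.shape[0]:
            self.state = np.concatenate([self.state, np.zeros(n - self.state.shape[0])])


def stm_update(buffer: STMBuffer, instantaneous: np.ndarray) -> np.ndarray:
    """``state <- decay * state + (1 - decay) * input``; returns the state."""
    instantaneous = np.asarray(instantaneous, dtype=np.float64)
    if instantaneous.shape != buffer.state.shape:
        raise ValueError("input length does not match buffer")
    buffer.state = buffer.decay * buffer.state + (1.0 - buffer.decay) * instantaneous
    return buffer.state


def wta(activations: np.ndarray) -> int:
    """Winner-take-all readout; ties break to the smallest index."""
    activations = np.asarray(activations, dtype=np.float64)
    if activations.size == 0:
        raise ValueError("cannot take winner of an empty vector")
    return int(np.argmax(activations))


def learn_frame(views: list[np.ndarray], posture: np.ndarray, net: VFNetwork,
                misp: AssociativeMap, t: int = 0) -> dict:
    """Process one labelled frame: VF learning + posture conditioning.

    Every local view is presented to the VF network (recruiting or averaging),
    the posture-prediction map grows columns to track recruitment, and each
    view's activity vector is conditioned toward the commanded-posture
    one-hot. Returns a per-frame log with the neuron count, recruit count,
    mean per-view prediction error and the frame's mean posture prediction
    (computed with the pre-update weights of each view step).
    """
    posture = np.asarray(posture, dtype=np.float64)
    recruits = 0
    errors: list[float] = []
    preds = np.zeros_like(posture)
    view_activities: list[np.ndarray] = []
    for view in views:
        net, _, recruited = vf_learn(view, net, t)
        recruits += int(recruited)
        misp.grow_inputs(net.n_neurons)
        acts = gated_activities(vf_activities(view, net), net.gamma)
        view_activities.append(acts)
        y = misp.predict(acts)
        errors.append(float(np.linalg.norm(posture - y)))
        preds += y
        lms_step(acts, posture, misp)
    n_views = max(1, len(views))
    return {
        "neuron_count": net.n_neurons,
        "recruits": recruits,
        "mean_error": float(np.mean(errors)) if errors else 0.0,
        "prediction": preds / n_views,
        "view_activities": view_activities,
    }
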