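"""Experimental protocol: learning phase, 4-condition recognition battery,
scoring and statistics.

A run mirrors the benchmark design: N partners imitate the robot's postures
in contiguous blocks; the model learns on a 1/10 temporal subsample of the
stream; learning is then frozen and each partner is re-presented under four
test conditions crossing two contrasts -- images *known* (seen during
learning) vs *unknown* (the held-out 9/10), shown in the *original temporal
order* vs *randomly shuffled*. Recognition scores are percentages compared to
the chance level 100/N; orderly conditions may exploit the short-term memory,
shuffled ones may not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config
from .neural import AssociativeMap, VFNetwork, learn_frame, one_hot
from .novelty import (NoveltyState, PersonModel, frame_error, novelty_step,
                      person_learn_frame, person_prediction_error,
                      predict_person_frame, recognize_person)
from .synthetic import AvatarSpec, Frame, Session, generate_session, subsample_session
from .vision import extract_views

logger = logging.getLogger("imitrec")

CONDITIONS = (
    ("random/known", True, True),
    ("non-random/known", False, True),
    ("random/unknown", True, False),
    ("non-random/unknown", False, False),
)


@dataclass(frozen=True)
class TestCondition:
    __test__ = False  # not a pytest class, despite the name

    known: bool
    randomized: bool
    n_images: int = 100

    @property
    def name(self) -> str:
        return f"{'random' if self.randomized else 'non-random'}/{'known' if self.known else 'unknown'}"


@dataclass(frozen=True)
class RecognitionResult:
    partner_id: int
    condition: TestCondition
    score: float
    hits: int
    n_images: int
    chance: float


# --- chance arithmetic ------------------------------------------------------

def chance_level(n_partners: int) -> float:
    """Chance recognition rate in percent: 100/N."""
    if n_partners < 1:
        raise ValueError("need at least one partner")
    return 100.0 / n_partners


def poor_recognition_threshold(n_partners: int) -> float:
    """The 'poorly recognized' cutoff: 10 times chance, in percent."""
    return 10.0 * chance_level(n_partners)


def percent(count: int, total: int) -> float:
    """A count as a percentage rounded to one decimal, as reported."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


# --- pools and batteries ----------------------------------------------------

def split_known_unknown(session: Session, stride: int) -> tuple[list[Frame], list[Frame]]:
    """Partition frames into the 1/stride learning subsample and its complement."""
    if stride < 2:
        raise ValueError("stride must be >= 2")
    if stride > len(session):
        raise ValueError("stride exceeds session length")
    known = [f for f in session.frames if f.frame_index % stride == 0]
    unknown = [f for f in session.frames if f.frame_index % stride != 0]
    return known, unknown


def build_condition_battery(pool: list[Frame], condition: TestCondition,
                            seed: int) -> list[Frame]:
    """Draw the test sequence for one partner and condition.

    Frames are sampled without replacement when the pool is large enough
    (with replacement otherwise, logged); the same seed draws the same
    multiset whether or not the order is then shuffled, so the randomized
    battery is exactly a permutation of the ordered one.
    """
    if not pool:
        raise ValueError("empty frame pool")
    rng = np.random.default_rng(seed)
    n = condition.n_images
    if len(pool) >= n:
        idx = rng.choice(len(pool), size=n, replace=False)
    else:
        logger.info("pool of %d frames < %d requested; sampling with replacement",
                    len(pool), n)
        idx = rng.choice(len(pool), size=n, replace=True)
    selected = [pool[i] for i in idx]
    if condition.randomized:
        rng.shuffle(selected)
    else:
        selected.sort(key=lambda f: f.frame_index)
    return selected


# --- statistics -------------------------------------------------------------

def binomial_vs_chance(hits: int, n: int, chance: float) -> float:
    """Exact one-sided (upper-tail) binomial p-value against chance."""
    if not 0 < chance < 1:
        raise ValueError("chance must be in (0, 1)")
    if not 0 <= hits <= n:
        raise ValueError("hits must lie in [0, n]")
    return float(stats.binomtest(hits, n, chance, alternative="greater").pvalue)


def bootstrap_ci(scores: list[float] | np.ndarray, n_boot: int = 10000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the mean."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    rng = np.random.default_rng(seed)
    means = rng.choice(scores, size=(n_boot, scores.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def contrast_check(table: pd.DataFrame) -> dict[str, int]:
    """Signs of the two design contrasts on mean scores.

    Returns +1/0/-1 for (known - unknown) and (random - non-random); the
    architecture predicts + and - respectively.
    """
    for col in ("known", "randomized", "score"):
        if col not in table.columns:
            raise ValueError(f"result table lacks column '{col}'")
    if table["known"].nunique() < 2 or table["randomized"].nunique() < 2:
        raise ValueError("result table must cover all four conditions")
    d_known = table[table.known].score.mean() - table[~table.known].score.mean()
    d_random = table[table.randomized].score.mean() - table[~table.randomized].score.mean()
    return {"known_effect_sign": int(np.sign(d_known)),
            "random_effect_sign": int(np.sign(d_random))}


# --- the full experiment ----------------------------------------------------

@dataclass
class ExperimentResult:
    table: pd.DataFrame             # one row per partner x condition
    training_log: pd.DataFrame      # per learning-frame log
    events: list[tuple[int, int]]   # novelty events (learning-frame position, index)
    n_persons: int
    person_for_partner: dict[int, int]
    net: VFNetwork
    misp: AssociativeMap
    person_model: PersonModel
    config: Config
    seed: int
    condition_means: dict[str, float] = field(default_factory=dict)


def _battery_seed(seed: int, partner_id: int, cond_index: int) -> int:
    return int(np.random.SeedSequence([seed, partner_id, cond_index]).generate_state(1)[0] % (2**31))


def _vision_kwargs(cfg: Config) -> dict:
    return dict(sigma1=cfg.dog_sigma1, sigma2=cfg.dog_sigma2,
                n_points=cfg.n_focus_points, suppression_radius=cfg.suppression_radius,
                r_max=cfg.lp_r_max, n_rings=cfg.lp_n_rings, n_angles=cfg.lp_n_angles)


def run_learning_phase(learning_frames: list[Frame], cfg: Config,
                       view_cache: dict[int, list[np.ndarray]] | None = None):
    """Sequential learning over the subsampled stream.

    Per frame: extract local views, run VF recruitment + posture (MISP)
    conditioning, score the posture-prediction error, step the novelty
    detector(s), and condition the person network toward the current person
    neuron (recruiting a new one on each novelty event).
    """
    vk = _vision_kwargs(cfg)
    cache = view_cache if view_cache is not None else {}
    net = VFNetwork(gamma=cfg.gamma, epsilon=cfg.epsilon)
    misp = AssociativeMap.empty(cfg.n_postures, cfg.lms_rate)
    person = PersonModel.empty(cfg.lms_rate, cfg.stm_decay)
    det_kwargs = dict(window=cfg.novelty_window, smoothing=cfg.novelty_smoothing,
                      threshold=cfg.novelty_threshold, refractory=cfg.novelty_refractory)
    err_state = NoveltyState(**det_kwargs)
    rec_state = NoveltyState(**det_kwargs)
    log_rows = []
    person_trace: list[int] = []
    events: list[tuple[int, int]] = []
    for t, frame in enumerate(learning_frames):
        if frame.frame_index not in cache:
            cache[frame.frame_index] = [v.values for v in extract_views(frame.image, **vk)]
        views = cache[frame.frame_index]
        target = one_hot(frame.posture, cfg.n_postures)
        flog = learn_frame(views, target, net, misp, t)
        acts = flog.pop("view_activities")
        e_posture = frame_error(flog["prediction"], target)
        e_person = person_prediction_error(acts, person)
        e_t = e_posture if cfg.novelty_channel == "posture" else e_person
        _, err_event = novelty_step(err_state, e_t, t)
        r_t = flog["recruits"] / max(1, len(views))
        _, rec_event = novelty_step(rec_state, r_t, t)
        if cfg.novelty_channel in ("error", "posture"):
            event = err_event
        elif cfg.novelty_channel == "recruit":
            event = rec_event
        else:
            event = err_event or rec_event
        if event:
            events.append((t, len(events)))
        person_learn_frame(acts, person, event)
        person_trace.append(person.current_person)
        log_rows.append({"t": t, "frame_index": frame.frame_index,
                         "partner_id": frame.partner_id, "posture": frame.posture,
                         "neuron_count": flog["neuron_count"],
                         "recruits": flog["recruits"],
                         "mean_error": flog["mean_error"],
                         "e_posture": e_posture, "e_t": e_t,
                         "E": err_state.E, "V": err_state.V,
                         "event": bool(event),
                         "current_person": person.current_person})
    return net, misp, person, events, pd.DataFrame(log_rows), person_trace, cache


def _map_persons_to_partners(learning_frames: list[Frame],
                             person_trace: list[int]) -> dict[int, int]:
    """True person label per partner: the neuron current for most of its block."""
    mapping: dict[int, int] = {}
    by_partner: dict[int, list[int]] = {}
    for frame, p in zip(learning_frames, person_trace):
        by_partner.setdefault(frame.partner_id, []).append(p)
    for pid, persons in by_partner.items():
        mapping[pid] = int(np.bincount(np.asarray(persons)).argmax())
    return mapping


def run_experiment(specs: list[AvatarSpec], cfg: Config, seed: int) -> ExperimentResult:
    """Full benchmark: generate, learn, freeze, test in 4 conditions, score."""
    if not specs:
        raise ValueError("need at least one avatar spec")
    session = generate_session(specs, cfg.frames_per_partner, posture_schedule_seed=seed,
                               noise_level=cfg.noise_level, image_size=cfg.image_size)
    learning = subsample_session(session, cfg.learning_stride)
    net, misp, person, events, tlog, trace, cache = run_learning_phase(learning.frames, cfg)
    person_for_partner = _map_persons_to_partners(learning.frames, trace)

    vk = _vision_kwargs(cfg)
    pred_cache: dict[int, np.ndarray] = {}

    def frame_pred(frame: Frame) -> np.ndarray:
        if frame.frame_index not in pred_cache:
            if frame.frame_index not in cache:
                cache[frame.frame_index] = [v.values for v in extract_views(frame.image, **vk)]
            pred_cache[frame.frame_index] = predict_person_frame(cache[frame.frame_index], net, person)
        return pred_cache[frame.frame_index]

    known, unknown = split_known_unknown(session, cfg.learning_stride)
    chance = chance_level(len(specs))
    rows = []
    for spec in specs:
        pid = spec.avatar_id
        pools = {
            True: [f for f in known if f.partner_id == pid],
            False: [f for f in unknown if f.partner_id == pid],
        }
        true_person = person_for_partner.get(pid, 0)
        for ci, (name, randomized, is_known) in enumerate(CONDITIONS):
            cond = TestCondition(known=is_known, randomized=randomized, n_images=cfg.n_test_images)
            battery = build_condition_battery(pools[is_known], cond,
                                              _battery_seed(seed, pid, ci))
            preds = [frame_pred(f) for f in battery]
            winners, score = recognize_person(preds, person, use_stm=not randomized,
                                              true_person=true_person)
            hits = sum(1 for w in winners if w == true_person)
            rows.append({"partner_id": pid, "condition": name, "known": is_known,
                         "randomized": randomized, "score": score, "hits": hits,
                         "n_images": len(battery), "chance": chance})
    table = pd.DataFrame(rows)
    means = table.groupby("condition", sort=False)["score"].mean().to_dict()
    return ExperimentResult(table=table, training_log=tlog, events=events,
                            n_persons=person.n_persons,
                            person_for_partner=person_for_partner,
                            net=net, misp=misp, person_model=person, config=cfg,
                            seed=seed, condition_means=means)


def summarize(result: ExperimentResult, boot_seed: int = 0) -> pd.DataFrame:
    """Per-condition summary: mean score, bootstrap 95% CI, pooled binomial p."""
    rows = []
    chance_p = result.table["chance"].iloc[0] / 100.0
    for name, grp in result.table.groupby("condition", sort=False):
        scores = grp["score"].to_numpy()
        hits = int(grp["hits"].sum())
        n = int(grp["n_images"].sum())
        lo, hi = bootstrap_ci(scores, seed=boot_seed) if scores.size >= 2 else (scores[0], scores[0])
        rows.append({"condition": name, "mean_score": float(scores.mean()),
                     "ci_low": lo, "ci_high": hi, "hits": hits, "n": n,
                     "binomial_p": binomial_vs_chance(hits, n, chance_p)})
    return pd.DataFrame(rows)
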