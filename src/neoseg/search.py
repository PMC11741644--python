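"""The outer reinforcement loop driving the configuration search.

A team of learning automata — one per searchable layer — jointly proposes a
candidate configuration each iteration.  The environment (candidate
training plus Dice evaluation, or a deterministic oracle table in tests)
returns a scalar quality in [0, 1].  If the quality strictly exceeds the
best seen so far, every automaton rewards its last action and the
configuration is saved as the new best; otherwise every automaton is
penalised.  The loop stops at the iteration cap ``T``, after ``K``
consecutive iterations without improvement, or when the quality reaches the
ceiling ``q_max``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .automaton import LearningAutomaton
from .config_space import (
    N_CONV_ACTIONS,
    N_CONV_LAYERS,
    N_POOLING_LAYERS,
    NetworkConfiguration,
    assemble_configuration,
)

__all__ = [
    "SearchState",
    "Environment",
    "OracleEnvironment",
    "CnnEnvironment",
    "check_termination",
    "run_search",
    "make_cnn_environment",
    "make_cnn_automata",
]


@dataclass
class SearchState:
    """Progress of one search run."""

    iteration: int = 0
    best_quality: float = -np.inf
    best_actions: Optional[Tuple[int, ...]] = None
    best_iteration: int = 0
    history: List[dict] = field(default_factory=list)
    stop_reason: Optional[str] = None

    @property
    def stall_count(self) -> int:
        return self.iteration - self.best_iteration


class Environment:
    """Contract: map a joint action tuple to a quality in [0, 1]."""

    def evaluate(self, actions: Sequence[int]) -> float:  # pragma: no cover
        raise NotImplementedError


class OracleEnvironment(Environment):
    """Deterministic lookup environment with a known optimum (test double)."""

    def __init__(
        self,
        quality_fn: Callable[[Tuple[int, ...]], float],
        n_actions_per_automaton: Sequence[int],
        known_optimum: Tuple[int, ...],
    ) -> None:
        self._fn = quality_fn
        self.n_actions_per_automaton = tuple(int(n) for n in n_actions_per_automaton)
        self.known_optimum = tuple(int(a) for a in known_optimum)

    def evaluate(self, actions: Sequence[int]) -> float:
        return float(self._fn(tuple(int(a) for a in actions)))

    def enumerate_qualities(self):
        """Exhaustive (joint action, quality) pairs; for verification only."""
        import itertools

        for joint in itertools.product(*[range(n) for n in self.n_actions_per_automaton]):
            yield joint, self.evaluate(joint)


def check_termination(
    state: SearchState, T: int, K: int, q_max: float = 1.0
) -> Tuple[bool, Optional[str]]:
    """Stop decision with a named reason.

    Reasons: ``max_iterations`` (iteration cap ``T`` reached), ``stalled``
    (no improvement in the last ``K`` iterations), ``quality_ceiling``
    (best quality reached ``q_max``).
    """
    if state.best_quality >= q_max:
        return True, "quality_ceiling"
    if state.iteration >= 1 and state.stall_count >= K:
        return True, "stalled"
    if state.iteration >= T:
        return True, "max_iterations"
    return False, None


def _automata_digest(automata: Sequence[LearningAutomaton]) -> str:
    h = hashlib.sha1()
    for la in automata:
        h.update(la.probabilities.tobytes())
    return h.hexdigest()[:12]


def run_search(
    env: Environment,
    automata: Sequence[LearningAutomaton],
    T: int = 200,
    K: int = 15,
    q_max: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    log_path=None,
    decode_actions: Optional[Callable[[Sequence[int]], dict]] = None,
) -> Tuple[Tuple[int, ...], SearchState]:
    """Run the automata-team search and return the best joint action seen.

    Each iteration every automaton selects an action, the joint proposal is
    evaluated, and all automata are rewarded (strict improvement over the
    running best) or penalised together.  An environment exception is
    logged as quality 0 and penalised; the search continues.  When
    ``log_path`` is given, one JSON line per iteration is appended for
    crash recovery.
    """
    if not (T >= 1 and 1 <= K <= T and 0.0 < q_max <= 1.0):
        raise ValueError("require T >= 1, 1 <= K <= T and q_max in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    state = SearchState()
    log_fh = open(log_path, "a") if log_path is not None else None
    try:
        while True:
            stop, reason = check_termination(state, T, K, q_max)
            if stop:
                state.stop_reason = reason
                break
            state.iteration += 1
            actions = tuple(la.select_action(rng) for la in automata)
            try:
                quality = float(env.evaluate(actions))
                if not np.isfinite(quality):
                    quality = 0.0
            except Exception:
                quality = 0.0
            improved = quality > state.best_quality
            if improved:
                state.best_quality = quality
                state.best_actions = actions
                state.best_iteration = state.iteration
                for la, act in zip(automata, actions):
                    la.apply_reward(act)
            else:
                for la, act in zip(automata, actions):
                    la.apply_penalty(act)
            record = {
                "iteration": state.iteration,
                "actions": list(actions),
                "quality": quality,
                "best_so_far": state.best_quality,
                "improved": improved,
            }
            if decode_actions is not None:
                record["configuration"] = decode_actions(actions)
            state.history.append(record)
            if log_fh is not None:
                full = dict(record, automata_digest=_automata_digest(automata))
                log_fh.write(json.dumps(full) + "\n")
                log_fh.flush()
    finally:
        if log_fh is not None:
            log_fh.close()
    return state.best_actions, state


def make_cnn_automata(
    reward_coeff: float = 0.5,
    penalty_coeff: float = 0.5,
    exploration_rate: float = 0.3,
) -> List[LearningAutomaton]:
    """The 21-automaton team: 19 convolution automata (375 actions each,
    initial probability 1/375) and 2 pooling automata (2 actions each,
    initial probabilities {1/2, 1/2})."""
    team = [
        LearningAutomaton(N_CONV_ACTIONS, reward_coeff, penalty_coeff, exploration_rate)
        for _ in range(N_CONV_LAYERS)
    ]
    team += [
        LearningAutomaton(2, reward_coeff, penalty_coeff, exploration_rate)
        for _ in range(N_POOLING_LAYERS)
    ]
    return team


class CnnEnvironment(Environment):
    """Environment that trains a candidate CNN and returns its mean Dice."""

    def __init__(
        self,
        train_data,
        val_data,
        settings,
        labels: Sequence[int] = (1, 2, 3),
        n_modalities: int = 2,
        n_classes: int = 4,
        spatial_rank: int = 3,
    ) -> None:
        from .network import TrainingSettings  # noqa: F401  (type of settings)

        if not len(train_data) or not len(val_data):
            raise ValueError("training and validation datasets must be non-empty")
        self.train_data = train_data
        self.val_data = val_data
        self.settings = settings
        self.labels = list(labels)
        self.n_modalities = n_modalities
        self.n_classes = n_classes
        self.spatial_rank = spatial_rank

    def evaluate_configuration(self, config: NetworkConfiguration) -> float:
        from .metrics import LabelVolume, mean_quality
        from .network import build_model, predict_segmentation, train_candidate

        model = build_model(
            config,
            n_modalities=self.n_modalities,
            n_classes=self.n_classes,
            spatial_rank=self.spatial_rank,
            seed=self.settings.seed,
        )
        # fixed per-candidate seed: environment noise reflects configuration
        # differences rather than initialisation luck
        rng = np.random.default_rng(self.settings.seed)
        model, history = train_candidate(
            model, self.train_data, self.settings, rng=rng
        )
        if history.diverged:
            return 0.0
        dices = []
        for img, lab in self.val_data:
            pred = predict_segmentation(model, np.asarray(img))
            truth = lab if isinstance(lab, LabelVolume) else LabelVolume(np.asarray(lab))
            dices.append(mean_quality(pred, truth, self.labels))
        return float(np.mean(dices))

    def evaluate(self, actions: Sequence[int]) -> float:
        config = assemble_configuration(
            actions[:N_CONV_LAYERS], actions[N_CONV_LAYERS:]
        )
        return self.evaluate_configuration(config)


def make_cnn_environment(
    train_data,
    val_data,
    settings,
    labels: Sequence[int] = (1, 2, 3),
    **kwargs,
) -> CnnEnvironment:
    """Build the training-and-evaluation environment used by the search."""
    return CnnEnvironment(train_data, val_data, settings, labels, **kwargs)
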