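"""Variable-structure learning automata with linear reward-penalty updates.

A learning automaton holds a probability vector over a finite action set.
After each interaction with the environment the vector is updated by one of
two linear schemes:

* reward  -- mass moves toward the chosen action ``i``::

      p_i <- p_i + a * (1 - p_i)
      p_j <- (1 - a) * p_j          (j != i)

* penalty -- mass moves away from the chosen action and is redistributed
  uniformly over the other ``K - 1`` actions::

      p_i <- (1 - b) * p_i
      p_j <- b / (K - 1) + (1 - b) * p_j   (j != i)

Both maps preserve ``sum(p) == 1`` exactly in real arithmetic; the vector is
renormalised after every update to absorb floating-point drift.

Action selection mixes exploration and exploitation: with probability
``exploration_rate`` the action is drawn uniformly, otherwise from the
current probability vector.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

__all__ = ["LearningAutomaton", "InvalidActionSpaceError", "ParameterError"]

_SUM_TOL = 1e-9


class InvalidActionSpaceError(ValueError):
    """Raised when the action set is too small to learn over."""


class ParameterError(ValueError):
    """Raised when a learning coefficient lies outside its valid range."""


class LearningAutomaton:
    """A finite-action automaton with a linear reward-penalty update rule.

    Parameters
    ----------
    n_actions:
        Number of selectable actions (>= 2).
    reward_coeff:
        Reward step size ``a`` in (0, 1].
    penalty_coeff:
        Penalty step size ``b`` in [0, 1).  ``b = 0`` gives the
        linear reward-inaction scheme.
    exploration_rate:
        Probability of selecting uniformly at random instead of from the
        probability vector (default 0.3, i.e. 30% of selections).
    """

    def __init__(
        self,
        n_actions: int,
        reward_coeff: float = 0.5,
        penalty_coeff: float = 0.5,
        exploration_rate: float = 0.3,
    ) -> None:
        if n_actions < 2:
            raise InvalidActionSpaceError(
                f"an automaton needs at least 2 actions, got {n_actions}"
            )
        if not (0.0 < reward_coeff <= 1.0):
            raise ParameterError(f"reward_coeff must be in (0, 1], got {reward_coeff}")
        if not (0.0 <= penalty_coeff < 1.0):
            raise ParameterError(f"penalty_coeff must be in [0, 1), got {penalty_coeff}")
        if not (0.0 <= exploration_rate <= 1.0):
            raise ParameterError(
                f"exploration_rate must be in [0, 1], got {exploration_rate}"
            )
        self.n_actions = int(n_actions)
        self.reward_coeff = float(reward_coeff)
        self.penalty_coeff = float(penalty_coeff)
        self.exploration_rate = float(exploration_rate)
        self.probabilities = np.full(self.n_actions, 1.0 / self.n_actions)
        self.last_action: Optional[int] = None
        self.update_count = 0

    # ------------------------------------------------------------------ #
    # selection
    # ------------------------------------------------------------------ #
    def select_action(self, rng: np.random.Generator) -> int:
        """Draw an action index and record it as ``last_action``.

        With probability ``exploration_rate`` the draw is uniform over all
        actions; otherwise it follows the current probability vector.
        """
        if rng.random() < self.exploration_rate:
            action = int(rng.integers(self.n_actions))
        else:
            action = int(rng.choice(self.n_actions, p=self.probabilities))
        self.last_action = action
        return action

    # ------------------------------------------------------------------ #
    # updates
    # ------------------------------------------------------------------ #
    def _check_index(self, chosen: int) -> None:
        if not (0 <= chosen < self.n_actions):
            raise IndexError(
                f"action index {chosen} out of range for {self.n_actions} actions"
            )

    def apply_reward(self, chosen: int) -> None:
        """Increase the probability of ``chosen`` by step ``a``."""
        self._check_index(chosen)
        a = self.reward_coeff
        p = self.probabilities
        p *= 1.0 - a
        p[chosen] += a
        self._finish_update()

    def apply_penalty(self, chosen: int) -> None:
        """Decrease the probability of ``chosen`` by step ``b``.

        The removed mass is redistributed as ``b / (K - 1)`` to each of the
        other actions, where ``K`` is the number of actions.
        """
        self._check_index(chosen)
        b = self.penalty_coeff
        p = self.probabilities
        p *= 1.0 - b
        p += b / (self.n_actions - 1)
        p[chosen] -= b / (self.n_actions - 1)
        self._finish_update()

    def _finish_update(self) -> None:
        p = self.probabilities
        np.clip(p, 0.0, 1.0, out=p)
        p /= p.sum()
        self.update_count += 1
        assert abs(p.sum() - 1.0) < _SUM_TOL

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return {
            "n_actions": self.n_actions,
            "reward_coeff": self.reward_coeff,
            "penalty_coeff": self.penalty_coeff,
            "exploration_rate": self.exploration_rate,
            "probabilities": self.probabilities.tolist(),
            "last_action": self.last_action,
            "update_count": self.update_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LearningAutomaton":
        la = cls(
            d["n_actions"],
            d["reward_coeff"],
            d["penalty_coeff"],
            d["exploration_rate"],
        )
        la.probabilities = np.asarray(d["probabilities"], dtype=float)
        la.last_action = d["last_action"]
        la.update_count = int(d["update_count"])
        return la

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "LearningAutomaton":
        return cls.from_dict(json.loads(s))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LearningAutomaton(n_actions={self.n_actions}, a={self.reward_coeff}, "
            f"b={self.penalty_coeff}, updates={self.update_count})"
        )
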