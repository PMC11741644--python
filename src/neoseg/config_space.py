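"""Discrete hyperparameter spaces for the configurable segmentation CNN.

Each searchable convolution layer is described by a triple ``<N, L, W>``:
the number of filters ``N`` (a multiple of 16 from 32 to 256, 15 values),
the filter length ``L`` and width ``W`` (odd values 1..9, 5 values each).
That gives 15 x 5 x 5 = 375 unique actions per convolution layer.  The two
searchable encoder pooling stages each choose between max pooling (code 0)
and average pooling (code 1).

A full network genotype consists of 19 convolution actions (six dense
blocks of three convolutions plus the final feature convolution before the
class head) and 2 pooling actions, i.e. 19 * 3 + 2 = 59 scalar
hyperparameters controlled by 21 automata in total.

Action indices are frozen in ``n_filters``-major order (then length, then
width) so that indices are stable across runs and checkpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from typing import List, Sequence

import yaml

__all__ = [
    "FILTER_COUNTS",
    "KERNEL_SIZES",
    "N_CONV_ACTIONS",
    "N_CONV_LAYERS",
    "N_POOLING_LAYERS",
    "N_AUTOMATA",
    "ConvLayerAction",
    "PoolingAction",
    "NetworkConfiguration",
    "ConfigurationError",
    "enumerate_conv_actions",
    "encode_conv_action",
    "decode_conv_action",
    "assemble_configuration",
]

FILTER_COUNTS: tuple = tuple(range(32, 257, 16))  # 15 values
KERNEL_SIZES: tuple = (1, 3, 5, 7, 9)  # 5 values

N_CONV_ACTIONS = len(FILTER_COUNTS) * len(KERNEL_SIZES) * len(KERNEL_SIZES)  # 375
N_CONV_LAYERS = 19
N_POOLING_LAYERS = 2
N_AUTOMATA = N_CONV_LAYERS + N_POOLING_LAYERS  # 21


class ConfigurationError(ValueError):
    """Raised for malformed network genotypes."""


@dataclass(frozen=True)
class ConvLayerAction:
    """A <N, L, W> filter specification for one convolution layer."""

    n_filters: int
    filter_length: int
    filter_width: int

    def __post_init__(self) -> None:
        if self.n_filters not in FILTER_COUNTS:
            raise ConfigurationError(
                f"n_filters must be a multiple of 16 in [32, 256], got {self.n_filters}"
            )
        if self.filter_length not in KERNEL_SIZES:
            raise ConfigurationError(
                f"filter_length must be an odd value in [1, 9], got {self.filter_length}"
            )
        if self.filter_width not in KERNEL_SIZES:
            raise ConfigurationError(
                f"filter_width must be an odd value in [1, 9], got {self.filter_width}"
            )

    def as_tuple(self) -> tuple:
        return (self.n_filters, self.filter_length, self.filter_width)


class PoolingAction(IntEnum):
    """Pooling operator for a searchable encoder pooling stage."""

    MAX = 0
    AVERAGE = 1


def enumerate_conv_actions() -> List[ConvLayerAction]:
    """All 375 convolution actions in the frozen n_filters-major order."""
    return [
        ConvLayerAction(n, length, width)
        for n in FILTER_COUNTS
        for length in KERNEL_SIZES
        for width in KERNEL_SIZES
    ]


def decode_conv_action(index: int) -> ConvLayerAction:
    """Map an automaton action index in [0, 374] to its <N, L, W> triple."""
    if not (0 <= index < N_CONV_ACTIONS):
        raise IndexError(f"conv action index {index} out of range [0, {N_CONV_ACTIONS})")
    n_kernel = len(KERNEL_SIZES)
    n_idx, rest = divmod(index, n_kernel * n_kernel)
    l_idx, w_idx = divmod(rest, n_kernel)
    return ConvLayerAction(FILTER_COUNTS[n_idx], KERNEL_SIZES[l_idx], KERNEL_SIZES[w_idx])


def encode_conv_action(action: ConvLayerAction) -> int:
    """Inverse of :func:`decode_conv_action`."""
    n_kernel = len(KERNEL_SIZES)
    return (
        FILTER_COUNTS.index(action.n_filters) * n_kernel * n_kernel
        + KERNEL_SIZES.index(action.filter_length) * n_kernel
        + KERNEL_SIZES.index(action.filter_width)
    )


@dataclass
class NetworkConfiguration:
    """The joint genotype chosen by all 21 automata.

    ``conv_actions`` holds the 19 convolution specifications in network
    order: encoder blocks 1-3 (3 layers each), decoder blocks 1-3 (3 layers
    each), then the final feature convolution.  ``pooling_actions`` holds
    the two encoder pooling choices.
    """

    conv_actions: List[ConvLayerAction]
    pooling_actions: List[PoolingAction]

    def __post_init__(self) -> None:
        if len(self.conv_actions) != N_CONV_LAYERS:
            raise ConfigurationError(
                f"expected {N_CONV_LAYERS} conv actions, got {len(self.conv_actions)}"
            )
        if len(self.pooling_actions) != N_POOLING_LAYERS:
            raise ConfigurationError(
                f"expected {N_POOLING_LAYERS} pooling actions, "
                f"got {len(self.pooling_actions)}"
            )
        self.pooling_actions = [PoolingAction(p) for p in self.pooling_actions]

    @property
    def n_scalar_hyperparameters(self) -> int:
        """Total count of tunable scalars: 19 x 3 + 2 = 59."""
        return 3 * len(self.conv_actions) + len(self.pooling_actions)

    # ---------------------------------------------------------------- #
    # canonical text form
    # ---------------------------------------------------------------- #
    def to_dict(self) -> dict:
        return {
            "conv_layers": [
                {"n": a.n_filters, "l": a.filter_length, "w": a.filter_width}
                for a in self.conv_actions
            ],
            "pooling": [
                "max" if p is PoolingAction.MAX else "avg" for p in self.pooling_actions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfiguration":
        pool_codes = {"max": PoolingAction.MAX, "avg": PoolingAction.AVERAGE}
        try:
            convs = [
                ConvLayerAction(entry["n"], entry["l"], entry["w"])
                for entry in d["conv_layers"]
            ]
            pools = [pool_codes[p] for p in d["pooling"]]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed configuration document: {exc}") from exc
        return cls(convs, pools)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfiguration":
        return cls.from_dict(json.loads(s))

    def save(self, path) -> None:
        """Write the canonical configuration file (YAML or JSON by suffix)."""
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "NetworkConfiguration":
        path = str(path)
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))


def assemble_configuration(
    conv_indices: Sequence[int], pooling_indices: Sequence[int]
) -> NetworkConfiguration:
    """Build a validated genotype from raw automaton action indices."""
    if len(conv_indices) != N_CONV_LAYERS:
        raise ConfigurationError(
            f"expected {N_CONV_LAYERS} conv indices, got {len(conv_indices)}"
        )
    if len(pooling_indices) != N_POOLING_LAYERS:
        raise ConfigurationError(
            f"expected {N_POOLING_LAYERS} pooling indices, got {len(pooling_indices)}"
        )
    try:
        convs = [decode_conv_action(int(i)) for i in conv_indices]
    except IndexError as exc:
        raise ConfigurationError(str(exc)) from exc
    pools = []
    for i in pooling_indices:
        if int(i) not in (0, 1):
            raise ConfigurationError(f"pooling index must be 0 or 1, got {i}")
        pools.append(PoolingAction(int(i)))
    return NetworkConfiguration(convs, pools)
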