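"""Recursion control: when is a subset aligned directly vs. recursively.

Base aligners handle a few hundred sequences comfortably but degrade past
that, so subsets larger than a threshold are aligned by a nested run of the
whole divide-and-conquer pipeline rather than handed to the base aligner.
The default threshold is the greater of the backbone size and the target
subset size used for decomposition.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

DEFAULT_MAX_NUM_SUBSETS = 25
DEFAULT_RECURSION_DEPTH_CAP = 3


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class DecompositionPlan:
    max_num_subsets: int
    target_subset_size: int
    recursion_threshold: int
    recurse_enabled: bool


def make_plan(
    n_sequences: int,
    max_num_subsets: int = DEFAULT_MAX_NUM_SUBSETS,
    backbone_size: int = 200,
    user_threshold: int | None = None,
    recurse_enabled: bool = True,
) -> DecompositionPlan:
    """Derive the decomposition/recursion plan for a dataset of ``n_sequences``.

    ``target_subset_size = ceil(n / max_num_subsets)``; the recursion
    threshold defaults to ``max(backbone_size, target_subset_size)`` unless
    the user overrides it.
    """
    if n_sequences < 1:
        raise ConfigError("n_sequences must be >= 1")
    if max_num_subsets < 1 or backbone_size < 1:
        raise ConfigError("max_num_subsets and backbone_size must be positive")
    if user_threshold is not None and user_threshold < 1:
        raise ConfigError("recursion threshold must be >= 1")
    target = math.ceil(n_sequences / max_num_subsets)
    threshold = user_threshold if user_threshold is not None else max(
        backbone_size, target
    )
    return DecompositionPlan(
        max_num_subsets=max_num_subsets,
        target_subset_size=target,
        recursion_threshold=threshold,
        recurse_enabled=recurse_enabled,
    )


def should_recurse(subset_size: int, plan: DecompositionPlan) -> bool:
    """True iff this subset goes to a nested pipeline run instead of the base aligner."""
    return plan.recurse_enabled and subset_size > plan.recursion_threshold


def child_seed(parent_seed: int, subset_index: int) -> int:
    """Deterministic seed for a nested run, derived from the parent's stream."""
    digest = hashlib.sha256(f"{parent_seed}:{subset_index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
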