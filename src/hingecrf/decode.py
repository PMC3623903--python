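"""Decision-threshold decoding of three-state marginals into final
domain/boundary calls.

The chain is first segmented into maximal runs of the per-position argmax
state ("predicted regions").  Residues in predicted boundary regions are
called boundary.  Residues in predicted hinge regions are called boundary
when their hinge posterior exceeds ``t_hinge`` (default 0.4, the operating
point that maximizes the weighted score Sw on the tuning set).  Residues in
predicted domain regions are called domain, unless the domain-region
threshold is enabled, in which case they are called domain only when their
domain posterior exceeds ``t_domain`` (default 0.75).  The per-residue
boundary score used for ROC analysis is 1 - P(domain), i.e. the combined
hinge+boundary posterior mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .crf import MarginalMatrix
from .labels import BOUNDARY, HINGE, LabelString

Mode = Literal["hinge_only", "domain_only", "both"]

# marginal-matrix column of each state
_COL_DOMAIN, _COL_HINGE, _COL_BOUNDARY = 0, 1, 2


@dataclass(frozen=True)
class DecodeConfig:
    t_hinge: float = 0.4
    t_domain: float = 0.75
    mode: Mode = "hinge_only"

    def __post_init__(self) -> None:
        if not (0 <= self.t_hinge <= 1 and 0 <= self.t_domain <= 1):
            raise ValueError("thresholds must lie in [0,1]")
        if self.mode not in ("hinge_only", "domain_only", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Prediction:
    calls2: LabelString
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.calls2),):
            raise ValueError("scores and calls lengths differ")
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError("scores must lie in [0,1]")
        object.__setattr__(self, "scores", scores)


def argmax_regions(marginals: MarginalMatrix) -> list[tuple[int, int, int]]:
    """Maximal runs of the per-position argmax state.

    Returns (state_code, start, end) triples with 1-based inclusive
    coordinates partitioning 1..L.  Ties in the argmax go to the lower
    label code (domain < boundary < hinge).
    """
    by_code = marginals.by_code()  # columns in code order -> argmax = lowest code
    states = by_code.argmax(axis=1)
    regions: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            regions.append((int(states[start]), start + 1, i))
            start = i
    return regions


def decide_two_state(
    marginals: MarginalMatrix,
    regions: list[tuple[int, int, int]],
    cfg: DecodeConfig = DecodeConfig(),
) -> Prediction:
    """Apply the hinge/domain decision thresholds region by region."""
    values = marginals.values
    L = len(marginals)
    calls = np.zeros(L, dtype=np.int8)
    for state, start, end in regions:
        sl = slice(start - 1, end)
        if state == BOUNDARY:
            calls[sl] = 1
        elif state == HINGE:
            if cfg.mode in ("hinge_only", "both"):
                calls[sl] = values[sl, _COL_HINGE] > cfg.t_hinge
            else:
                calls[sl] = 1  # hinge mass counts as boundary evidence
        else:  # domain region
            if cfg.mode in ("domain_only", "both"):
                calls[sl] = ~(values[sl, _COL_DOMAIN] > cfg.t_domain)
            else:
                calls[sl] = 0
    scores = 1.0 - values[:, _COL_DOMAIN]
    return Prediction(LabelString(calls, arity=2), scores)


def decode(marginals: MarginalMatrix, cfg: DecodeConfig = DecodeConfig()) -> Prediction:
    """Convenience: segment and threshold in one call."""
    return decide_two_state(marginals, argmax_regions(marginals), cfg)
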