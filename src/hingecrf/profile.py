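"""Alignment-derived domain/hinge/boundary (DHB) frequency profiles.

For query position p and state s in (domain, hinge, boundary), the profile
value is the normalized count of hits whose aligned subject residue carries
state s:

    profile(p, s) = sum_l A_l(p, s) / sum_{s'} sum_l A_l(p, s')

where A_l(p, s) = 1 when hit l aligns p to a subject residue labeled s.
The denominator is position-wise: only hits that actually align p
contribute.  Positions aligned by no hit are all-zero and flagged
uncovered — zero encodes "no homology evidence", which downstream feature
binning maps to its own category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentHit, ReferenceDB

STATE_COLUMNS = ("P_domain", "P_hinge", "P_boundary")

# Label codes are 0=domain, 1=boundary, 2=hinge; profile columns are ordered
# (domain, hinge, boundary).
COL_OF_CODE = np.array([0, 2, 1], dtype=np.intp)
CODE_OF_COL = np.array([0, 2, 1], dtype=np.intp)  # involution


@dataclass(frozen=True)
class DHBProfile:
    """L x 3 row-stochastic (or all-zero) matrix, columns (domain, hinge,
    boundary), plus a per-position coverage flag."""

    values: np.ndarray
    covered: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        covered = np.asarray(self.covered, dtype=bool)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("profile values must be L x 3")
        if covered.shape != (values.shape[0],):
            raise ValueError("covered flag length mismatch")
        sums = values.sum(axis=1)
        if covered.any() and not np.allclose(sums[covered], 1.0, atol=1e-9):
            raise ValueError("covered rows must sum to 1")
        if (~covered).any() and np.any(values[~covered] != 0.0):
            raise ValueError("uncovered rows must be exactly zero")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "covered", covered)

    def __len__(self) -> int:
        return int(self.values.shape[0])


def compute_dhb_profile(
    query_length: int, hits: list[AlignmentHit], db: ReferenceDB
) -> DHBProfile:
    """Count aligned subject states per query position and normalize."""
    counts = np.zeros((query_length, 3), dtype=float)
    for hit in hits:
        labels = db[hit.subject_id].labels3.codes
        for qpos, spos in hit.pairs:
            if spos < 1 or spos > labels.size:
                raise ValueError(
                    f"hit {hit.subject_id}: subject position {spos} outside label string"
                )
            if qpos < 1 or qpos > query_length:
                raise ValueError(
                    f"hit {hit.subject_id}: query position {qpos} outside query"
                )
            counts[qpos - 1, COL_OF_CODE[labels[spos - 1]]] += 1.0
    totals = counts.sum(axis=1)
    covered = totals > 0
    values = np.zeros_like(counts)
    values[covered] = counts[covered] / totals[covered, None]
    return DHBProfile(values, covered)
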