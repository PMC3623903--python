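"""Per-residue domain / hinge / boundary labeling.

Residues are labeled from CATH-style domain annotations.  Two-state labels
distinguish domain (0) from boundary (1); a boundary residue is any residue
outside every domain segment, plus the first and last residue of every
segment (so when two domains touch, the two contacted residues are both
boundary).  Three-state labels add a hinge class (2): a window of 2R
residues straddling each segment terminus, R residues on the domain side
and R on the boundary side.  Hinge relabeling overrides both other codes;
overlapping windows take their union; windows are truncated at chain ends.

Coordinates in annotations are 1-based inclusive throughout; label arrays
are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOMAIN, BOUNDARY, HINGE = 0, 1, 2

Segment = tuple[int, int]


class AnnotationError(ValueError):
    """Raised when a domain annotation violates its invariants."""


@dataclass(frozen=True)
class LabelString:
    """Per-residue integer codes, arity 2 ({0,1}) or 3 ({0,1,2})."""

    codes: np.ndarray
    arity: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        object.__setattr__(self, "codes", codes)
        if self.arity not in (2, 3):
            raise ValueError(f"arity must be 2 or 3, got {self.arity}")
        if codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if codes.size and (codes.min() < 0 or codes.max() >= self.arity):
            raise ValueError(f"codes outside alphabet for arity {self.arity}")

    def __len__(self) -> int:
        return int(self.codes.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelString):
            return NotImplemented
        return self.arity == other.arity and np.array_equal(self.codes, other.codes)

    def to_text(self) -> str:
        return "".join(str(int(c)) for c in self.codes)

    @classmethod
    def from_text(cls, text: str, arity: int) -> "LabelString":
        return cls(np.array([int(ch) for ch in text], dtype=np.int8), arity)


@dataclass(frozen=True)
class DomainAnnotation:
    """Chain length plus ordered domains, each an ordered list of residue
    segments in 1-based inclusive coordinates.  Discontinuous domains are
    lists of more than one segment."""

    chain_id: str
    length: int
    domains: tuple[tuple[Segment, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "domains",
            tuple(tuple((int(s), int(e)) for s, e in dom) for dom in self.domains),
        )
        if self.length < 1:
            raise AnnotationError(f"{self.chain_id}: length must be >= 1")
        occupied = np.zeros(self.length, dtype=bool)
        for dom in self.domains:
            prev_end = 0
            for start, end in dom:
                if not (1 <= start <= end <= self.length):
                    raise AnnotationError(
                        f"{self.chain_id}: segment ({start},{end}) outside 1..{self.length}"
                    )
                if start <= prev_end:
                    raise AnnotationError(
                        f"{self.chain_id}: segments within a domain overlap or are unsorted"
                    )
                if occupied[start - 1 : end].any():
                    raise AnnotationError(
                        f"{self.chain_id}: segment ({start},{end}) overlaps another domain"
                    )
                occupied[start - 1 : end] = True
                prev_end = end

    @property
    def segments(self) -> list[Segment]:
        """All segments across domains, in annotation order."""
        return [seg for dom in self.domains for seg in dom]


@dataclass(frozen=True)
class HingeConfig:
    """Hinge half-width R (residues on each side of a segment terminus)."""

    R: int = 10

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("R must be >= 0")


def assign_two_state_labels(annotation: DomainAnnotation) -> LabelString:
    """Two-state labels: 1 = boundary, 0 = domain.

    Every residue outside all segments is boundary; the first and last
    residue of every segment are boundary; contacted domains therefore get
    two consecutive boundary residues automatically.
    """
    codes = np.full(annotation.length, BOUNDARY, dtype=np.int8)
    for start, end in annotation.segments:
        codes[start - 1 : end] = DOMAIN
    for start, end in annotation.segments:
        codes[start - 1] = BOUNDARY
        codes[end - 1] = BOUNDARY
    return LabelString(codes, arity=2)


def assign_hinge_labels(
    labels2: LabelString,
    annotation: DomainAnnotation,
    cfg: HingeConfig = HingeConfig(),
) -> LabelString:
    """Three-state labels: overlay 2R-residue hinge windows on the two-state
    labels.

    For a segment N-terminus at position t the window is t-R .. t+R-1; for a
    C-terminus at t it is t-R+1 .. t+R (R residues on the domain side, R on
    the boundary side, the terminus itself on the domain side of the count).
    Windows are truncated at chain ends and their union is taken.
    """
    if len(labels2) != annotation.length:
        raise ValueError("label string length does not match annotation length")
    if labels2.arity != 2:
        raise ValueError("labels2 must be two-state")
    codes = labels2.codes.copy()
    R = cfg.R
    if R > 0:
        L = annotation.length
        for start, end in annotation.segments:
            lo, hi = max(1, start - R), min(L, start + R - 1)
            codes[lo - 1 : hi] = HINGE
            lo, hi = max(1, end - R + 1), min(L, end + R)
            codes[lo - 1 : hi] = HINGE
    return LabelString(codes, arity=3)


def collapse_to_two_state(labels3: LabelString, annotation: DomainAnnotation) -> LabelString:
    """Map hinge residues back to their underlying two-state code."""
    if labels3.arity != 3:
        raise ValueError("labels3 must be three-state")
    base = assign_two_state_labels(annotation)
    codes = np.where(labels3.codes == HINGE, base.codes, labels3.codes).astype(np.int8)
    return LabelString(codes, arity=2)
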