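"""Windowed unigram feature encoding for the chain CRF.

Each residue carries four observation columns: the three DHB profile
probabilities (numeric) and one shape-string symbol (categorical).  A
unigram template reads every column at offsets -window_back .. +window_fwd
around the current position (default +-4), yielding
(window_back + 1 + window_fwd) x 4 categorical features per position.
Numeric values are discretized by round-half-up binning on a fixed grid
(default width 0.1) so that real-valued profile columns behave like the
string-valued features of classic CRF toolkits; offsets falling off the
ends of the chain emit the sentinels ``_BOS_`` / ``_EOS_``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .profile import DHBProfile

SHAPE_ALPHABET = set("RSUVKATG")
SHAPE_UNKNOWN = "-"

_NUMERIC_COLUMNS = ("Pd", "Ph", "Pb")
_SHAPE_COLUMN = "sh"


@dataclass(frozen=True)
class ShapeString:
    """One backbone-shape symbol per residue over the 8-letter alphabet
    {R,S,U,V,K,A,T,G} (torsion-angle clusters), '-' for unknown."""

    symbols: str

    def __post_init__(self) -> None:
        bad = set(self.symbols) - SHAPE_ALPHABET - {SHAPE_UNKNOWN}
        if bad:
            raise ValueError(f"shape symbols outside alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def unknown(cls, length: int) -> "ShapeString":
        return cls(SHAPE_UNKNOWN * length)


@dataclass(frozen=True)
class TemplateConfig:
    window_back: int = 4
    window_fwd: int = 4
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.window_back < 0 or self.window_fwd < 0:
            raise ValueError("window sizes must be >= 0")
        if not (0 < self.bin_width <= 1):
            raise ValueError("bin_width must be in (0, 1]")
        inv = 1.0 / self.bin_width
        if abs(inv - round(inv)) > 1e-9:
            raise ValueError("1/bin_width must be integral")

    @property
    def window(self) -> int:
        return self.window_back + 1 + self.window_fwd

    @property
    def features_per_position(self) -> int:
        return self.window * 4


FeatureSequence = list[list[str]]


def bin_category(value: float, bin_width: float) -> str:
    """Round-half-up a numeric value onto the bin grid, e.g. 0.6667 -> '0.7'."""
    idx = math.floor(value / bin_width + 0.5 + 1e-9)
    return f"{idx * bin_width:g}"


def encode_features(
    profile: DHBProfile,
    shape: ShapeString,
    cfg: TemplateConfig = TemplateConfig(),
) -> FeatureSequence:
    """Expand the four observation columns through the unigram template.

    Feature identifiers have the form ``col:offset:category``.
    """
    L = len(profile)
    if len(shape) != L:
        raise ValueError("profile and shape string lengths differ")
    # Pre-bin each column once; offsets then just index the binned arrays.
    binned = [
        [bin_category(profile.values[i, c], cfg.bin_width) for i in range(L)]
        for c in range(3)
    ]
    offsets = range(-cfg.window_back, cfg.window_fwd + 1)
    out: FeatureSequence = []
    for i in range(L):
        feats: list[str] = []
        for off in offsets:
            j = i + off
            if j < 0:
                for col in (*_NUMERIC_COLUMNS, _SHAPE_COLUMN):
                    feats.append(f"{col}:{off}:_BOS_")
            elif j >= L:
                for col in (*_NUMERIC_COLUMNS, _SHAPE_COLUMN):
                    feats.append(f"{col}:{off}:_EOS_")
            else:
                for c, col in enumerate(_NUMERIC_COLUMNS):
                    feats.append(f"{col}:{off}:{binned[c][j]}")
                feats.append(f"{_SHAPE_COLUMN}:{off}:{shape.symbols[j]}")
        out.append(feats)
    return out
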