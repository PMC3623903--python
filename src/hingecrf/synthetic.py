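"""Synthetic annotated-sequence generator with planted domain families.

Chains are built as alternating linkers (random residues) and domains
(copies of per-family prototype sequences), so that alignment of a query
against the reference set recovers informative domain/hinge/boundary
profiles.  Divergence between copies of a prototype is injected three ways:

* point substitutions at ``mutation_rate`` per residue;
* single-residue insertions/deletions at ``indel_frac * mutation_rate``
  per residue.  Indels fragment local alignments once frequent, giving a
  realistic homology-detection cliff at high mutation rates: substitutions
  alone keep the expected BLOSUM62 column score positive at any allowed
  rate, so without indels every homolog would stay detectable no matter
  how mutated.  The default fraction makes the mean ungapped run shorter
  than the affine-gap chaining break-even near the mutation-rate cap while
  leaving low-mutation alignments essentially full-length;
* per-end trimming of 0..``boundary_jitter`` residues of each domain copy,
  emulating the boundary-position disagreement among real homologs of a
  domain family (this is what makes hinge posteriors graded rather than
  step-shaped near domain termini).

Shape strings emit helix/strand-like symbols {A,T,G,K} inside domain
segments and loop-like symbols {R,S,U,V} elsewhere, each flipped to a
uniformly random symbol with probability ``shape_noise``.

Default sizes keep the two-state boundary:domain residue imbalance near
the 1:15 regime of real domain-annotated chains.  All randomness flows
from one seeded generator; outputs are reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ReferenceEntry
from .features import ShapeString
from .labels import (
    DomainAnnotation,
    HingeConfig,
    LabelString,
    assign_hinge_labels,
    assign_two_state_labels,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DOMAIN_SHAPES = "ATGK"
LOOP_SHAPES = "RSUV"
ALL_SHAPES = "RSUVKATG"


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_families: int = 3
    n_ref: int = 300
    n_query: int = 150
    domain_len_range: tuple[int, int] = (120, 200)
    linker_len_range: tuple[int, int] = (10, 20)
    domains_per_chain_weights: tuple[float, ...] = (0.3, 0.4, 0.3)
    mutation_rate: float = 0.05
    shape_noise: float = 0.1
    boundary_jitter: int = 8
    indel_frac: float = 1.0
    tail_prob: float = 0.0
    hinge: HingeConfig = field(default_factory=HingeConfig)

    def __post_init__(self) -> None:
        lo, hi = self.domain_len_range
        llo, lhi = self.linker_len_range
        if not (0 < lo <= hi) or not (0 < llo <= lhi):
            raise ValueError("length ranges must be positive and ordered")
        if abs(sum(self.domains_per_chain_weights) - 1.0) > 1e-9:
            raise ValueError("domains_per_chain_weights must sum to 1")
        if not (0 <= self.mutation_rate <= 0.5):
            raise ValueError("mutation_rate must lie in [0, 0.5]")
        if not (0 <= self.shape_noise <= 1):
            raise ValueError("shape_noise must lie in [0, 1]")

    @property
    def indel_rate(self) -> float:
        return self.indel_frac * self.mutation_rate


@dataclass(frozen=True)
class QueryRecord:
    """A generated query chain with its ground truth."""

    id: str
    sequence: str
    annotation: DomainAnnotation
    shape: ShapeString
    labels2: LabelString
    labels3: LabelString


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_family_prototypes(cfg: SynthConfig) -> list[str]:
    """Random prototype sequences, one per family, lengths within
    ``domain_len_range``; fixed by the config seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.domain_len_range
    protos = []
    for _ in range(cfg.n_families):
        protos.append(_random_sequence(rng, int(rng.integers(lo, hi + 1))))
    return protos


def _mutate(proto: str, cfg: SynthConfig, rng: np.random.Generator) -> str:
    """One domain instance: trim ends, substitute, apply single-residue
    indels."""
    j = cfg.boundary_jitter
    if j > 0:
        t1 = int(rng.integers(0, j + 1))
        t2 = int(rng.integers(0, j + 1))
        proto = proto[t1 : len(proto) - t2]
    out: list[str] = []
    aas = list(AMINO_ACIDS)
    for ch in proto:
        r = rng.random()
        if r < cfg.indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(aas[int(rng.integers(20))])  # insertion before residue
            out.append(ch)
        elif r < cfg.indel_rate + cfg.mutation_rate:
            repl = aas[int(rng.integers(19))]
            if repl == ch:  # pick from the other 19 residues
                repl = aas[19]
            out.append(repl)
        else:
            out.append(ch)
    if not out:
        out.append(aas[int(rng.integers(20))])
    return "".join(out)


def generate_annotated_chain(
    cfg: SynthConfig, rng: np.random.Generator, prototypes: list[str]
) -> tuple[str, DomainAnnotation, ShapeString]:
    """One chain: alternating linkers and mutated prototype copies."""
    n_dom = 1 + int(
        rng.choice(len(cfg.domains_per_chain_weights), p=cfg.domains_per_chain_weights)
    )
    llo, lhi = cfg.linker_len_range
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    if rng.random() < cfg.tail_prob:
        tail = int(rng.integers(llo, lhi + 1))
        parts.append(_random_sequence(rng, tail))
        pos += tail
    for d in range(n_dom):
        if d > 0:
            linker = int(rng.integers(llo, lhi + 1))
            parts.append(_random_sequence(rng, linker))
            pos += linker
        fam = int(rng.integers(cfg.n_families))
        instance = _mutate(prototypes[fam], cfg, rng)
        parts.append(instance)
        segments.append((pos + 1, pos + len(instance)))
        pos += len(instance)
    if rng.random() < cfg.tail_prob:
        tail = int(rng.integers(llo, lhi + 1))
        parts.append(_random_sequence(rng, tail))
        pos += tail
    sequence = "".join(parts)
    annotation = DomainAnnotation(
        chain_id="", length=len(sequence), domains=tuple((seg,) for seg in segments)
    )
    in_domain = np.zeros(len(sequence), dtype=bool)
    for s, e in segments:
        in_domain[s - 1 : e] = True
    shape_chars = []
    for i in range(len(sequence)):
        pool = DOMAIN_SHAPES if in_domain[i] else LOOP_SHAPES
        ch = pool[int(rng.integers(len(pool)))]
        if rng.random() < cfg.shape_noise:
            ch = ALL_SHAPES[int(rng.integers(8))]
        shape_chars.append(ch)
    return sequence, annotation, ShapeString("".join(shape_chars))


def generate_dataset(
    cfg: SynthConfig,
) -> tuple[list[ReferenceEntry], list[QueryRecord]]:
    """Reference entries (with three-state labels) and disjoint query
    chains sharing the same prototype families.

    No query sequence exactly equals a reference sequence; collisions are
    resampled (they essentially never occur at nonzero mutation rates).
    """
    rng = np.random.default_rng(cfg.seed)
    prototypes = generate_family_prototypes(cfg)
    refs: list[ReferenceEntry] = []
    ref_seqs: set[str] = set()
    for i in range(cfg.n_ref):
        seq, ann, _shape = generate_annotated_chain(cfg, rng, prototypes)
        ann = DomainAnnotation(f"ref{i:04d}", ann.length, ann.domains)
        labels3 = assign_hinge_labels(assign_two_state_labels(ann), ann, cfg.hinge)
        refs.append(ReferenceEntry(ann.chain_id, seq, labels3))
        ref_seqs.add(seq)
    queries: list[QueryRecord] = []
    for i in range(cfg.n_query):
        for _attempt in range(100):
            seq, ann, shape = generate_annotated_chain(cfg, rng, prototypes)
            if seq not in ref_seqs:
                break
        else:
            raise RuntimeError("could not draw a query distinct from the references")
        ann = DomainAnnotation(f"query{i:04d}", ann.length, ann.domains)
        labels2 = assign_two_state_labels(ann)
        labels3 = assign_hinge_labels(labels2, ann, cfg.hinge)
        queries.append(QueryRecord(ann.chain_id, seq, ann, shape, labels2, labels3))
    return refs, queries


def boundary_domain_ratio(records: list[QueryRecord]) -> float:
    """Two-state boundary:domain residue ratio across a chain set."""
    n_boundary = sum(int((q.labels2.codes == 1).sum()) for q in records)
    n_domain = sum(int((q.labels2.codes == 0).sum()) for q in records)
    return n_boundary / n_domain
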