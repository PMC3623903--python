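"""Readers and writers for the on-disk formats.

* sequences: FASTA (Biopython).
* per-residue strings (labels, shape strings): FASTA-style records whose
  body is one character per residue ('0'/'1'/'2' for labels, the 8-letter
  shape alphabet or '-' for shapes).
* domain annotations: TSV with columns chain_id, domain_index (1-based),
  seg_start, seg_end (1-based inclusive); chain lengths come from the
  FASTA record of the same id.
* profiles and predictions: TSV, 4 decimal places on probabilities.
* alignment hits: TSV with columns query_id, subject_id, evalue,
  bit_score, blocks (see :func:`hingecrf.align.import_tabular_hits`).
* metric reports and CRF models: JSON.
"""

from __future__ import annotations

import json
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentHit, ReferenceDB, ReferenceEntry
from .decode import DecodeConfig, Prediction
from .features import ShapeString
from .labels import DomainAnnotation, LabelString
from .metrics import MetricReport
from .profile import DHBProfile, STATE_COLUMNS


# ---------------------------------------------------------------- sequences

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        str(path),
        "fasta",
    )


# ------------------------------------------------- per-residue string files

def _read_string_records(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def _write_string_records(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, body in records:
            fh.write(f">{name}\n{body}\n")


def read_labels(path: str | Path, arity: int) -> dict[str, LabelString]:
    return {
        name: LabelString.from_text(body, arity)
        for name, body in _read_string_records(path).items()
    }


def write_labels(path: str | Path, labels: dict[str, LabelString]) -> None:
    _write_string_records(path, ((n, ls.to_text()) for n, ls in labels.items()))


def read_shapes(path: str | Path) -> dict[str, ShapeString]:
    return {n: ShapeString(b) for n, b in _read_string_records(path).items()}


def write_shapes(path: str | Path, shapes: dict[str, ShapeString]) -> None:
    _write_string_records(path, ((n, s.symbols) for n, s in shapes.items()))


# -------------------------------------------------------------- annotations

ANNOT_HEADER = "chain_id\tdomain_index\tseg_start\tseg_end"


def read_annotations(path: str | Path, lengths: dict[str, int]) -> dict[str, DomainAnnotation]:
    """Parse segment rows into per-chain annotations.

    ``lengths`` maps chain id to residue count (normally from the FASTA).
    Chains present in ``lengths`` but absent from the file get an
    annotation with no domains.
    """
    segs: dict[str, dict[int, list[tuple[int, int]]]] = defaultdict(lambda: defaultdict(list))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line == ANNOT_HEADER:
                continue
            chain_id, dom_idx, start, end = line.split("\t")
            segs[chain_id][int(dom_idx)].append((int(start), int(end)))
    missing = sorted(set(segs) - set(lengths))
    if missing:
        raise KeyError(f"annotated chains without a sequence record: {missing}")
    out: dict[str, DomainAnnotation] = {}
    for chain_id, length in lengths.items():
        doms = segs.get(chain_id, {})
        out[chain_id] = DomainAnnotation(
            chain_id,
            length,
            tuple(tuple(sorted(doms[k])) for k in sorted(doms)),
        )
    return out


def write_annotations(path: str | Path, annotations: Iterable[DomainAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write(ANNOT_HEADER + "\n")
        for ann in annotations:
            for d, dom in enumerate(ann.domains, start=1):
                for start, end in dom:
                    fh.write(f"{ann.chain_id}\t{d}\t{start}\t{end}\n")


# ------------------------------------------------------------- reference DB

def write_reference_db(dir_path: str | Path, db: ReferenceDB) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_fasta(dir_path / "refs.fasta", ((e.id, e.sequence) for e in db.entries))
    write_labels(dir_path / "refs.labels3", {e.id: e.labels3 for e in db.entries})


def read_reference_db(dir_path: str | Path) -> ReferenceDB:
    dir_path = Path(dir_path)
    seqs = read_fasta(dir_path / "refs.fasta")
    labels = read_labels(dir_path / "refs.labels3", arity=3)
    missing = sorted(set(seqs) ^ set(labels))
    if missing:
        raise KeyError(f"reference FASTA/label id mismatch: {missing}")
    return ReferenceDB(ReferenceEntry(i, seqs[i], labels[i]) for i in seqs)


# ------------------------------------------------------------------- hits

def write_hits(path: str | Path, query_id: str, hits: Sequence[AlignmentHit]) -> None:
    """Write hits in the tabular import format (ungapped runs as blocks)."""
    with open(path, "w") as fh:
        fh.write("# query_id\tsubject_id\tevalue\tbit_score\tblocks\n")
        for h in hits:
            blocks: list[str] = []
            run_start = 0
            pairs = h.pairs
            for i in range(1, len(pairs) + 1):
                if (
                    i == len(pairs)
                    or pairs[i][0] != pairs[i - 1][0] + 1
                    or pairs[i][1] != pairs[i - 1][1] + 1
                ):
                    qs, ss = pairs[run_start]
                    qe, se = pairs[i - 1]
                    blocks.append(f"{qs}-{qe}:{ss}-{se}")
                    run_start = i
            fh.write(
                f"{query_id}\t{h.subject_id}\t{h.evalue:.6g}\t{h.bit_score:.2f}\t"
                + ",".join(blocks)
                + "\n"
            )


# ----------------------------------------------------------------- profiles

def write_profile(path: str | Path, sequence: str, profile: DHBProfile) -> None:
    with open(path, "w") as fh:
        fh.write("position\tresidue\t" + "\t".join(STATE_COLUMNS) + "\n")
        for i, aa in enumerate(sequence):
            row = "\t".join(f"{v:.4f}" for v in profile.values[i])
            fh.write(f"{i + 1}\t{aa}\t{row}\n")


def read_profile(path: str | Path) -> DHBProfile:
    rows = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append([float(x) for x in fields[2:5]])
    values = np.array(rows, dtype=float)
    covered = values.sum(axis=1) > 0
    # re-normalize 4-decimal rounding on covered rows
    values[covered] /= values[covered].sum(axis=1, keepdims=True)
    return DHBProfile(values, covered)


# -------------------------------------------------------------- predictions

def write_prediction(
    path: str | Path,
    sequence: str,
    profile_like: np.ndarray,
    prediction: Prediction,
    model_id: str,
    cfg: DecodeConfig,
) -> None:
    """Prediction TSV; ``profile_like`` is the L x 3 marginal matrix in
    (domain, hinge, boundary) column order."""
    with open(path, "w") as fh:
        fh.write(
            f"# model={model_id} t_hinge={cfg.t_hinge} t_domain={cfg.t_domain} mode={cfg.mode}\n"
        )
        fh.write("position\tresidue\tP_domain\tP_hinge\tP_boundary\tscore\tcall\n")
        for i, aa in enumerate(sequence):
            probs = "\t".join(f"{v:.4f}" for v in profile_like[i])
            fh.write(
                f"{i + 1}\t{aa}\t{probs}\t{prediction.scores[i]:.4f}\t"
                f"{int(prediction.calls2.codes[i])}\n"
            )


# ------------------------------------------------------------------ reports

def report_to_json(report: MetricReport) -> str:
    obj: dict = {k: v for k, v in report.defined().items()}
    undefined = [
        k for k in ("Sn", "Sp", "Ac", "MCC", "Sw", "AUC") if getattr(report, k) is None
    ]
    if undefined:
        obj["undefined"] = undefined
    if report.SE:
        obj["SE"] = dict(report.SE)
    return json.dumps(obj, indent=2)


def report_to_text(report: MetricReport) -> str:
    lines = [f"{'metric':<8}{'value':>10}{'SE':>10}"]
    for name in ("Sn", "Sp", "Ac", "MCC", "Sw", "AUC"):
        v = getattr(report, name)
        vtxt = "undef" if v is None else f"{v:.4f}"
        se = (report.SE or {}).get(name)
        setxt = "" if se is None else f"{se:.4f}"
        lines.append(f"{name:<8}{vtxt:>10}{setxt:>10}")
    return "\n".join(lines) + "\n"
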