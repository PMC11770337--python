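"""Sequence-set and result serialization (FASTA, JSON lines)."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .potts import SolveResult

__all__ = ["read_fasta", "write_fasta", "write_results_jsonl", "read_results_jsonl"]


def read_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, seqs, ids=None) -> None:
    records = []
    for k, s in enumerate(seqs):
        rid = ids[k] if ids is not None else f"seq{k}"
        records.append(SeqRecord(Seq(s), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_results_jsonl(path: str | Path, results: list[SolveResult],
                        extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        for r in results:
            row = {"sequence": r.sequence, "score": r.score, "method": r.method,
                   "seed": r.seed}
            row.update({k: v for k, v in r.metadata.items() if _jsonable(v)})
            if extra:
                row.update(extra)
            fh.write(json.dumps(row) + "\n")


def read_results_jsonl(path: str | Path) -> list[dict]:
    return [json.loads(line) for line in Path(path).read_text().splitlines() if line.strip()]


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
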