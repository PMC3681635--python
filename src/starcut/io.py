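"""FASTA/BED/TSV/JSON input and output, via Biopython where applicable."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest_engine import CutSet, DsSequence, FragmentSet
from .library_sim import JunctionRead


def read_fasta(path: str | Path, circular: bool = False) -> list[DsSequence]:
    return [
        DsSequence(str(rec.seq), name=rec.id, circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]] | Iterable[DsSequence], path: str | Path) -> None:
    seq_records = []
    for rec in records:
        if isinstance(rec, DsSequence):
            name, seq = rec.name or "sequence", rec.seq
        else:
            name, seq = rec
        seq_records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def fragments_to_fasta(fragments: FragmentSet, path: str | Path, which: str = "top") -> None:
    records = []
    for i, f in enumerate(fragments):
        seq = f.top_sequence() if which == "top" else f.repaired_sequence()
        if not seq:
            continue
        records.append((f"fragment{i:05d}_{f.top[0]}_{f.top[1]}", seq))
    write_fasta(records, path)


def reads_to_fasta(reads: Sequence[JunctionRead], path: str | Path) -> None:
    write_fasta(((r.read_id, r.sequence) for r in reads), path)


def cuts_to_bed(cuts: CutSet, seq: DsSequence, path: str | Path) -> None:
    """Cut positions as BED6: the interval between the two scissions
    (0-based half-open), the matched site as the name, strand of the site."""
    lines = []
    for c in cuts:
        lo, hi = sorted((c.top, c.bottom))
        name = c.source.site if c.source else "."
        strand = c.source.strand if c.source else "."
        lines.append(f"{seq.name or 'seq'}\t{lo}\t{hi}\t{name}\t0\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def stats_to_json(stats: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
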