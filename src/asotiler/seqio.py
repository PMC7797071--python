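"""Sequence and table I/O with fixed, documented dialects.

Coordinate conventions: 0-based half-open internally; the oligo table is
1-based inclusive (ordering-sheet friendly); BED output is standard 0-based
half-open. Both writers state this in a comment header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeqIOError",
    "OligoTableRow",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "write_oligo_table",
    "read_oligo_table",
    "write_bed",
]

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_PLAIN_RNA = set("ACGUN")


class SeqIOError(ValueError):
    """Malformed input file or sequence string."""


def reverse_complement(seq: str, output_alphabet: str = "DNA") -> str:
    """Reverse complement with full IUPAC support (R<->Y, K<->M, S/W/N fixed).

    ``output_alphabet`` selects DNA (T) or RNA (U) in the result; U and T are
    both accepted on input.
    """
    if output_alphabet not in ("DNA", "RNA"):
        raise ValueError("output_alphabet must be 'DNA' or 'RNA'")
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in _IUPAC_DNA:
            raise SeqIOError(f"invalid IUPAC character {seq[i]!r} at position {i + 1}")
    rc = str(Seq(s).reverse_complement())
    return rc.replace("T", "U") if output_alphabet == "RNA" else rc


def _find_line_number(path, record_id: str) -> int:
    """Best-effort line number of a FASTA header, for error messages."""
    try:
        with open(path, encoding="utf-8") as fh:
            for n, line in enumerate(fh, start=1):
                if line.startswith(">") and line[1:].split()[0:1] == [record_id]:
                    return n
    except OSError:
        pass
    return 0


def read_fasta(path, aligned: bool = False):
    """Read target sequences (or a gapped alignment with ``aligned=True``).

    Headers are parsed up to the first whitespace; sequences are case-folded
    and T is normalized to U. Duplicate ids, illegal characters and empty
    files are rejected with errors naming the offending record/line.
    """
    from .multitarget import Alignment
    from .tiler import TargetSeq

    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise SeqIOError(f"{path}: empty or not FASTA")
    allowed = _PLAIN_RNA | ({"-"} if aligned else set())
    ids: List[str] = []
    seqs: List[str] = []
    for rec in records:
        rid = rec.id
        if not rid:
            raise SeqIOError(f"{path}: record with empty id near line {_find_line_number(path, rid)}")
        if rid in ids:
            raise SeqIOError(
                f"{path}: duplicate id {rid!r} (second occurrence near line {_find_line_number(path, rid)})"
            )
        s = str(rec.seq).upper().replace("T", "U")
        for i, c in enumerate(s):
            if c not in allowed:
                raise SeqIOError(
                    f"{path}: illegal character {c!r} at position {i + 1} of record {rid!r} "
                    f"(header near line {_find_line_number(path, rid)})"
                )
        ids.append(rid)
        seqs.append(s)
    if aligned:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise SeqIOError(f"{path}: aligned FASTA rows have unequal lengths {sorted(lengths)}")
        return Alignment(ids=ids, rows=seqs)
    return [TargetSeq(id=i, seq=s) for i, s in zip(ids, seqs)]


def write_fasta(targets, path, width: int = 70) -> None:
    """Write TargetSeq records (or an Alignment's rows) as FASTA."""
    items = getattr(targets, "ids", None)
    if items is not None:  # Alignment
        pairs = list(zip(targets.ids, targets.rows))
    else:
        pairs = [(t.id, t.seq) for t in targets]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, seq in pairs:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class OligoTableRow:
    oligo_id: str
    target_id: str
    start_1based: int
    end_1based: int
    length: int
    antisense_seq: str
    tm_c: float  # rounded to 2 decimals in the table
    oligo_class: str
    n_expansions: int
    gap_to_previous: int


_COLUMNS = [
    "oligo_id",
    "target_id",
    "start_1based",
    "end_1based",
    "length",
    "antisense_seq",
    "tm_c",
    "oligo_class",
    "n_expansions",
    "gap_to_previous",
]


def _iter_results(design) -> Iterable:
    """Yield TilingResult objects from a TilingResult, list, or SharedDesign."""
    if hasattr(design, "per_target"):
        yield from design.per_target.values()
    elif hasattr(design, "oligos"):
        yield design
    else:
        yield from design


def design_rows(design) -> List[OligoTableRow]:
    """Flatten a design into table rows, one per placed oligo, per target."""
    rows: List[OligoTableRow] = []
    for res in _iter_results(design):
        prev_end = 0
        for o in res.oligos:
            rows.append(
                OligoTableRow(
                    oligo_id=o.id,
                    target_id=o.target_id,
                    start_1based=o.start + 1,
                    end_1based=o.end,
                    length=o.end - o.start,
                    antisense_seq=o.antisense_seq,
                    tm_c=round(o.tm, 2),
                    oligo_class=o.oligo_class,
                    n_expansions=o.n_expansions,
                    gap_to_previous=o.start - prev_end,
                )
            )
            prev_end = o.end
    return rows


def write_oligo_table(design, path) -> None:
    """TSV oligo table: fixed column order, UTF-8, LF line endings.

    Coordinates are 1-based inclusive on the target; Tm is printed to two
    decimals (full precision is retained in memory).
    """
    rows = design_rows(design)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# antisense oligo table; coordinates 1-based inclusive on the target RNA\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.oligo_id,
                        r.target_id,
                        str(r.start_1based),
                        str(r.end_1based),
                        str(r.length),
                        r.antisense_seq,
                        f"{r.tm_c:.2f}",
                        r.oligo_class,
                        str(r.n_expansions),
                        str(r.gap_to_previous),
                    ]
                )
                + "\n"
            )


def read_oligo_table(path) -> List[OligoTableRow]:
    rows: List[OligoTableRow] = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != _COLUMNS:
                    raise SeqIOError(f"{path}:{lineno}: unexpected oligo-table header")
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise SeqIOError(f"{path}:{lineno}: expected {len(_COLUMNS)} columns")
            rows.append(
                OligoTableRow(
                    oligo_id=parts[0],
                    target_id=parts[1],
                    start_1based=int(parts[2]),
                    end_1based=int(parts[3]),
                    length=int(parts[4]),
                    antisense_seq=parts[5],
                    tm_c=float(parts[6]),
                    oligo_class=parts[7],
                    n_expansions=int(parts[8]),
                    gap_to_previous=int(parts[9]),
                )
            )
    if header is None:
        raise SeqIOError(f"{path}: empty oligo table (no header)")
    return rows


def write_bed(design, path) -> None:
    """BED6: 0-based half-open, name = oligo id, score = round(Tm), strand '-'.

    The oligo is antisense to the target's sense orientation, hence the minus
    strand.
    """
    rows = design_rows(design)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in rows:
            fh.write(
                f"{r.target_id}\t{r.start_1based - 1}\t{r.end_1based}\t"
                f"{r.oligo_id}\t{round(r.tm_c)}\t-\n"
            )
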