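"""File formats: TRF ``.dat`` tables, the package's TSV dialects,
FASTA/FASTQ, and BED export.

Coordinates in all files are 1-based inclusive (the convention of TRF
and VCF); they are converted to 0-based half-open on parsing.
"""

from __future__ import annotations

import csv
from typing import Iterable, Optional, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles import TandemRepeat
from .refset import ReferenceSet
from .simulate import SimRead, TruthRecord

REF_TSV_COLUMNS = [
    "id", "chrom", "start", "end", "pattern", "copies", "array",
    "left_flank", "right_flank", "category",
]

READTR_TSV_COLUMNS = [
    "read_id", "ordinal", "start", "end", "pattern", "copies", "array",
    "left_flank", "right_flank",
]


# ---------------------------------------------------------------------------
# TRF .dat
# ---------------------------------------------------------------------------

def parse_trf_dat(handle: TextIO, source_is_reads: bool = False
                  ) -> list[TandemRepeat]:
    """Parse a TRF ``.dat`` table into TandemRepeat records.

    Per-repeat lines hold: start, end, period size, copy number,
    consensus size, percent matches, percent indels, score, A%, C%, G%,
    T%, entropy, consensus pattern, array sequence, and optionally the
    left and right flanking sequences (TRF ``-f`` flag).  ``Sequence:``
    lines name the source sequence (chromosome, or read when
    ``source_is_reads``).
    """
    repeats: list[TandemRepeat] = []
    seq_name: Optional[str] = None
    ordinals: dict[str, int] = {}
    for line in handle:
        line = line.strip()
        if not line:
            continue
        if line.startswith("Sequence:"):
            seq_name = line.split(None, 1)[1].split()[0]
            continue
        if line.startswith(("Parameters:", "Tandem", "Program", "Version",
                            "Gary", "Boston", "Period", "Indices")):
            continue
        fields = line.split()
        if len(fields) < 15:
            continue
        try:
            start = int(fields[0])
            end = int(fields[1])
            copies = float(fields[3])
        except ValueError:
            continue
        consensus = fields[13]
        array = fields[14]
        left = fields[15] if len(fields) > 15 else ""
        right = fields[16] if len(fields) > 16 else ""
        left = "" if left == "." else left
        right = "" if right == "." else right
        if source_is_reads:
            ordinals[seq_name] = ordinals.get(seq_name, 0) + 1
            ordinal = ordinals[seq_name]
            tr = TandemRepeat(
                id=f"{seq_name}:{ordinal}", pattern=consensus, array=array,
                copies=copies, left_flank=left, right_flank=right,
                start=start - 1, end=end, source=(seq_name, ordinal),
            )
        else:
            tr = TandemRepeat(
                id=f"{seq_name}:{start}-{end}", pattern=consensus, array=array,
                copies=copies, left_flank=left, right_flank=right,
                chrom=seq_name, start=start - 1, end=end,
            )
        repeats.append(tr)
    return repeats


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def write_reference_tsv(refs: Sequence[TandemRepeat], handle: TextIO) -> None:
    w = csv.writer(handle, delimiter="\t", lineterminator="\n")
    w.writerow(REF_TSV_COLUMNS)
    for tr in refs:
        w.writerow([
            tr.id, tr.chrom or ".", (tr.start or 0) + 1, tr.end or 0,
            tr.pattern, f"{tr.copies:.2f}", tr.array,
            tr.left_flank or ".", tr.right_flank or ".", tr.category or ".",
        ])


def read_reference_tsv(handle: TextIO) -> ReferenceSet:
    r = csv.DictReader(handle, delimiter="\t")
    repeats = []
    categories = {}
    for row in r:
        tr = TandemRepeat(
            id=row["id"], pattern=row["pattern"], array=row["array"],
            copies=float(row["copies"]),
            chrom=None if row["chrom"] == "." else row["chrom"],
            start=int(row["start"]) - 1, end=int(row["end"]),
            left_flank="" if row["left_flank"] == "." else row["left_flank"],
            right_flank="" if row["right_flank"] == "." else row["right_flank"],
            category=None if row.get("category", ".") == "." else row["category"],
        )
        repeats.append(tr)
        if tr.category:
            categories[tr.id] = tr.category
    return ReferenceSet(repeats=repeats, categories=categories)


def write_read_tr_tsv(read_trs: Sequence[TandemRepeat], handle: TextIO) -> None:
    """Read-TR annotations; start/end are 1-based inclusive in the read."""
    w = csv.writer(handle, delimiter="\t", lineterminator="\n")
    w.writerow(READTR_TSV_COLUMNS)
    for tr in read_trs:
        read_id, ordinal = tr.source
        start = len(tr.left_flank)
        w.writerow([
            read_id, ordinal, start + 1, start + len(tr.array),
            tr.pattern, f"{tr.copies:.2f}", tr.array,
            tr.left_flank or ".", tr.right_flank or ".",
        ])


def read_read_tr_tsv(handle: TextIO) -> list[TandemRepeat]:
    r = csv.DictReader(handle, delimiter="\t")
    out = []
    for row in r:
        ordinal = int(row["ordinal"])
        out.append(TandemRepeat(
            id=f"{row['read_id']}:{ordinal}",
            pattern=row["pattern"], array=row["array"],
            copies=float(row["copies"]),
            start=int(row["start"]) - 1, end=int(row["end"]),
            left_flank="" if row["left_flank"] == "." else row["left_flank"],
            right_flank="" if row["right_flank"] == "." else row["right_flank"],
            source=(row["read_id"], ordinal),
        ))
    return out


def write_truth_tsv(truth: Sequence[TruthRecord], handle: TextIO) -> None:
    w = csv.writer(handle, delimiter="\t", lineterminator="\n")
    w.writerow(["ref_id", "delta_a", "delta_b", "zygosity"])
    for t in truth:
        w.writerow([t.ref_id, t.delta_a, t.delta_b, t.zygosity])


def read_truth_tsv(handle: TextIO) -> list[TruthRecord]:
    r = csv.DictReader(handle, delimiter="\t")
    return [TruthRecord(row["ref_id"], int(row["delta_a"]),
                        int(row["delta_b"]), row["zygosity"])
            for row in r]


def write_bed(refs: Sequence[TandemRepeat], handle: TextIO) -> None:
    """BED export of retained reference loci (0-based half-open)."""
    for tr in sorted(refs, key=lambda t: (t.chrom or "", t.start or 0)):
        handle.write(f"{tr.chrom}\t{tr.start}\t{tr.end}\t{tr.id}\n")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_genome_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_reads_fastq(reads: Sequence[SimRead], path: str) -> None:
    """FASTQ with uniform placeholder qualities (the method is quality
    blind)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_reads_fastq(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fastq")}


def read_reads_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}
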