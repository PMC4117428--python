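"""Genomic file IO and coordinate conventions.

All coordinates are 0-based, half-open. Minus-strand reads have their 5' end
at ``end - 1``. Reads are interchanged as 6-column BED (name = fragment id
with an optional ``/1`` ``/2`` mate suffix, score = fragment length, strand);
the pipeline consumes already-mapped coordinate lists, so no alignment formats
are needed. A SAM/BAM importer is a documented extension point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "READ_COLUMNS",
    "TSS_COLUMNS",
    "load_genome_fasta",
    "write_genome_fasta",
    "load_reads_bed",
    "write_reads_bed",
    "load_tss_table",
    "write_tss_table",
    "load_truth_table",
    "write_truth_table",
    "revcomp",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Column order of a read table (pandas DataFrame).
READ_COLUMNS = ["chrom", "start", "end", "name", "fragment_len", "strand"]

#: Column order of a TSS table.
TSS_COLUMNS = ["chrom", "tss_pos", "strand", "promoter_id", "class_label"]


def revcomp(seq: str) -> str:
    """Reverse complement over the A, C, G, T, N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Named chromosome strings over {A, C, G, T, N}, uppercase."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence [start, end); raises if outside the chromosome."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences.items())


def load_genome_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA genome.

    Lowercase is normalized to uppercase; characters outside {A,C,G,T,N} are
    mapped to N (the substitution count is logged). Empty files and duplicate
    headers are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    sequences: dict[str, str] = {}
    n_subst = 0
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = sum(1 for c in seq if c not in _VALID)
        if bad:
            n_subst += bad
            seq = "".join(c if c in _VALID else "N" for c in seq)
        sequences[rec.id] = seq
    if n_subst:
        logger.info("%s: %d non-ACGTN characters mapped to N", path, n_subst)
    return GenomeSequence(sequences)


def write_genome_fasta(genome: GenomeSequence, path: str | Path,
                       line_width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


def load_reads_bed(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Load mapped reads from 6-column BED.

    Returns a DataFrame with READ_COLUMNS plus ``mate_id`` (reconstructed from
    a shared name prefix with ``/1`` / ``/2`` suffixes, NaN otherwise).
    Records violating the invariants (start >= end, unknown strand) are
    rejected with their line numbers logged; ``strict=True`` turns rejection
    into an error.
    """
    rows = []
    rejected = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                rejected.append((lineno, "fewer than 6 columns"))
                continue
            chrom, start_s, end_s, name, score_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
                fragment_len = int(float(score_s))
            except ValueError:
                rejected.append((lineno, "non-integer coordinates/score"))
                continue
            if start >= end:
                rejected.append((lineno, f"start >= end ({start} >= {end})"))
                continue
            if strand not in ("+", "-"):
                rejected.append((lineno, f"unknown strand {strand!r}"))
                continue
            if fragment_len and fragment_len < end - start:
                rejected.append(
                    (lineno, f"fragment_len {fragment_len} < read length"))
                continue
            rows.append((chrom, start, end, name, fragment_len, strand))
    if rejected:
        msg = f"{path}: rejected {len(rejected)} BED records " \
              f"(first: line {rejected[0][0]}, {rejected[0][1]})"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    reads["mate_id"] = np.where(
        reads["name"].str.contains(r"/[12]$", regex=True),
        reads["name"].str.replace(r"/[12]$", "", regex=True),
        np.nan,
    )
    reads.attrs["n_rejected"] = len(rejected)
    return reads


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def load_tss_table(path: str | Path) -> pd.DataFrame:
    """Load a TSS/promoter table (TSV with header).

    Columns: chrom, tss_pos (0-based), strand, promoter_id, class_label and
    optionally expression_trend in {up, down, none}. Duplicate promoter ids
    are a hard error.
    """
    tss = pd.read_csv(path, sep="\t", dtype={"chrom": str, "promoter_id": str})
    missing = [c for c in TSS_COLUMNS[:4] if c not in tss.columns]
    if missing:
        raise ValueError(f"{path}: missing TSS columns {missing}")
    if tss["promoter_id"].duplicated().any():
        dupes = tss.loc[tss["promoter_id"].duplicated(), "promoter_id"]
        raise ValueError(f"{path}: duplicate promoter_id {dupes.iloc[0]!r}")
    bad_strand = ~tss["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError(f"{path}: invalid strand values")
    return tss


def write_tss_table(tss: pd.DataFrame, path: str | Path) -> None:
    tss.to_csv(path, sep="\t", index=False)


def load_truth_table(path: str | Path) -> pd.DataFrame:
    """Load a generator truth map (chrom, dyad_pos, retained_in_apoptosis...)."""
    truth = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    truth["retained_in_apoptosis"] = truth["retained_in_apoptosis"].astype(bool)
    return truth


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
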