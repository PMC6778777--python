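"""Paired-read processing: stitching, demultiplexing, cut-site and quality filters.

ddRAD fragments are sequenced strand-specifically: read 1 starts at the 5'
(SphI) end of the fragment, read 2 at the 3' (EcoRI) end on the opposite
strand.  Concatenating R1 with the reverse complement of R2 ("stitching")
recapitulates the fragment's original orientation, with an unsequenced gap
of unknown length in the middle.  All downstream locus assembly operates on
these fixed-length stitched sequences.

Processing order in the pipeline:

1. stitch R1 + revcomp(R2)
2. demultiplex on the 5 bp inline barcode at the start of the stitched read
3. sliding-window mean-Phred quality filter (window sized from the full,
   untrimmed stitched read; 300 bp reads -> 45 bp windows)
4. trim the barcode and verify the restriction-enzyme cut-site remnants at
   both ends
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

PHRED_OFFSET = 33  # Phred+33 encoding is assumed throughout

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    return sequence.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read with its per-base Phred+33 quality string."""

    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def phred(self) -> np.ndarray:
        """Per-base Phred scores as an integer array."""
        return np.frombuffer(self.qualities.encode(), dtype=np.uint8).astype(int) - PHRED_OFFSET


@dataclass(frozen=True)
class StitchedRead:
    """R1 concatenated with the reverse complement of R2."""

    read_id: str
    sequence: str
    qualities: str
    r1_length: int

    def phred(self) -> np.ndarray:
        return np.frombuffer(self.qualities.encode(), dtype=np.uint8).astype(int) - PHRED_OFFSET


def stitch(r1: FastqRecord, r2: FastqRecord) -> StitchedRead:
    """Stitch a read pair into genome orientation.

    The stitched sequence is ``r1.sequence + reverse_complement(r2.sequence)``
    and the quality string is R1's qualities followed by R2's reversed (each
    base keeps its own quality score).
    """
    if not r1.sequence or not r2.sequence:
        raise ValueError("cannot stitch length-0 reads")
    return StitchedRead(
        read_id=r1.read_id,
        sequence=r1.sequence + reverse_complement(r2.sequence),
        qualities=r1.qualities + r2.qualities[::-1],
        r1_length=len(r1.sequence),
    )


def split_stitched(read: StitchedRead, r1_length: int | None = None) -> tuple[FastqRecord, FastqRecord]:
    """Inverse of :func:`stitch`: recover the original (R1, R2) pair."""
    n = read.r1_length if r1_length is None else r1_length
    r1 = FastqRecord(read.read_id, read.sequence[:n], read.qualities[:n])
    r2 = FastqRecord(
        read.read_id,
        reverse_complement(read.sequence[n:]),
        read.qualities[n:][::-1],
    )
    return r1, r2


@dataclass
class DemuxParams:
    """Demultiplexing and quality-filter parameters.

    barcode_map maps each inline barcode to an individual id.  A read is
    assigned to the unique barcode within ``max_barcode_mismatch`` Hamming
    distance of its first ``barcode_length`` bases; ties go to "unassigned".
    """

    barcode_map: dict[str, str] = field(default_factory=dict)
    max_barcode_mismatch: int = 1
    window_fraction: float = 0.15
    min_window_mean_phred: float = 20.0

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.barcode_map}
        if len(lengths) > 1:
            raise ValueError("all barcodes must have the same length")
        if len(set(self.barcode_map)) != len(self.barcode_map):
            raise ValueError("duplicate barcodes in barcode map")
        if self.barcode_map and self.max_barcode_mismatch >= self.barcode_length:
            raise ValueError("max_barcode_mismatch must be smaller than the barcode length")

    @property
    def barcode_length(self) -> int:
        if not self.barcode_map:
            raise ValueError("empty barcode map")
        return len(next(iter(self.barcode_map)))


def demultiplex_read(sequence: str, params: DemuxParams) -> str | None:
    """Assign a stitched read to an individual by its leading barcode.

    Returns the individual id, or None ("unassigned") when no barcode — or
    more than one barcode — lies within ``max_barcode_mismatch`` of the
    observed prefix at the minimal distance.
    """
    observed = sequence[: params.barcode_length]
    exact = params.barcode_map.get(observed)
    if exact is not None:
        return exact
    best: list[str] = []
    best_d = params.max_barcode_mismatch + 1
    for barcode, individual in params.barcode_map.items():
        d = hamming(observed, barcode)
        if d < best_d:
            best, best_d = [individual], d
        elif d == best_d:
            best.append(individual)
    if best_d <= params.max_barcode_mismatch and len(best) == 1:
        return best[0]
    return None


def verify_cut_sites(sequence: str, enzyme5, enzyme3) -> bool:
    """Check both restriction remnants on a barcode-trimmed stitched read.

    True iff the read begins with the 5' enzyme's post-cut remnant and ends
    with the 3' enzyme's pre-cut remnant.  The match is exact: a substitution
    inside a remnant fails the read (no rescue of mutated sites).
    """
    return sequence.startswith(enzyme5.remnant_5prime) and sequence.endswith(enzyme3.remnant_3prime)


def window_length(read_length: int, window_fraction: float) -> int:
    """Sliding-window length: round(fraction x read length), at least 1."""
    return max(1, round(window_fraction * read_length))


def sliding_window_means(phred: np.ndarray, window: int) -> np.ndarray:
    """Means of all full windows of size ``window``, advancing one base."""
    if window > len(phred):
        return np.empty(0)
    c = np.concatenate([[0], np.cumsum(phred, dtype=float)])
    return (c[window:] - c[:-window]) / window


def quality_filter(read: StitchedRead | FastqRecord, params: DemuxParams) -> bool:
    """Keep a read iff every sliding window's mean Phred is strictly > threshold.

    The window length is round(window_fraction x len(read)); windows advance
    one base at a time and trailing partial windows are not evaluated.  A
    window whose mean is exactly the threshold discards the read.
    """
    w = window_length(len(read.sequence), params.window_fraction)
    means = sliding_window_means(read.phred(), w)
    return bool(np.all(means > params.min_window_mean_phred))


@dataclass
class ProcessResult:
    """Per-individual retained stitched sequences plus a demultiplexing report."""

    assigned: dict[str, list[str]]            # individual -> retained stitched sequences (barcode-trimmed)
    report: pd.DataFrame                      # individual, assigned, discarded_quality, discarded_cutsite, retained
    unassigned: int
    records: dict[str, list[StitchedRead]] | None = None  # retained trimmed records, when requested

    @property
    def total_reads(self) -> int:
        return int(self.report["assigned"].sum()) + self.unassigned


def process_read_pairs(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    params: DemuxParams,
    enzyme5,
    enzyme3,
    keep_records: bool = False,
) -> ProcessResult:
    """Stitch, demultiplex, quality-filter and cut-site-verify read pairs.

    Every read pair is assigned to exactly one individual or counted as
    unassigned; assigned reads are then dropped by the quality filter or the
    cut-site check, or retained (barcode-trimmed) for assembly.  With
    ``keep_records`` the retained reads are also kept as trimmed
    :class:`StitchedRead` objects for FASTQ export.
    """
    individuals = sorted(set(params.barcode_map.values()))
    counts = {i: {"assigned": 0, "discarded_quality": 0, "discarded_cutsite": 0, "retained": 0}
              for i in individuals}
    unassigned = 0
    kept: dict[str, list[str]] = {i: [] for i in individuals}
    records: dict[str, list[StitchedRead]] = {i: [] for i in individuals}
    bc_len = params.barcode_length
    for r1, r2 in pairs:
        read = stitch(r1, r2)
        individual = demultiplex_read(read.sequence, params)
        if individual is None:
            unassigned += 1
            continue
        counts[individual]["assigned"] += 1
        if not quality_filter(read, params):
            counts[individual]["discarded_quality"] += 1
            continue
        trimmed = read.sequence[bc_len:]
        if not verify_cut_sites(trimmed, enzyme5, enzyme3):
            counts[individual]["discarded_cutsite"] += 1
            continue
        counts[individual]["retained"] += 1
        kept[individual].append(trimmed)
        if keep_records:
            records[individual].append(
                StitchedRead(read.read_id, trimmed, read.qualities[bc_len:], read.r1_length - bc_len)
            )
    report = pd.DataFrame(
        [{"individual": i, **counts[i]} for i in individuals]
    )
    return ProcessResult(
        assigned=kept, report=report, unassigned=unassigned,
        records=records if keep_records else None,
    )


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Iterate FASTQ records (plain or gzip) as :class:`FastqRecord`."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield FastqRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities="".join(chr(q + PHRED_OFFSET) for q in rec.letter_annotations["phred_quality"]),
            )


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Iterate matched read pairs from two parallel FASTQ files."""
    for r1, r2 in zip(read_fastq(r1_path), read_fastq(r2_path), strict=True):
        if r1.read_id.split("/")[0] != r2.read_id.split("/")[0]:
            raise ValueError(f"read pair mismatch: {r1.read_id} vs {r2.read_id}")
        yield r1, r2


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write FASTQ (gzip if the path ends in .gz, with a fixed mtime so that
    identical records produce byte-identical files)."""
    path = Path(path)
    if path.suffix == ".gz":
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as handle:
                for rec in records:
                    handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n".encode())
    else:
        with open(path, "w") as handle:
            for rec in records:
                handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load a sample sheet TSV with columns individual, barcode, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "barcode", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if df["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in sample sheet")
    return df
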