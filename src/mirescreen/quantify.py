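"""Read demultiplexing and guide counting.

Turns screen FASTQ files into a construct x sample count matrix. Reads carry
an inline sample barcode followed by a constant flank and the guide sequence
at a fixed offset, so matching is pure Hamming lookup: no alignment, no
indels. A read is assigned only when both the barcode and the guide resolve
uniquely within the configured mismatch tolerances, and counts of a construct
accrue only to samples of its own pool. Everything else is tallied, never
fractionally assigned.
"""

from __future__ import annotations

import gzip
import itertools
import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import CountMatrix, ReadLayout, validate_library, validate_sheet

logger = logging.getLogger("mirescreen.quantify")


@dataclass
class DemuxStats:
    """Accounting of every processed read: assigned + unassigned_barcode +
    unmatched_guide + multi_hit equals the total read count."""

    per_sample: dict[str, int] = field(default_factory=dict)
    unassigned_barcode: int = 0
    unmatched_guide: int = 0
    multi_hit: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.per_sample.values())

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned_barcode + self.unmatched_guide + self.multi_hit

    def to_frame(self) -> pd.DataFrame:
        rows = [("assigned:" + s, n) for s, n in sorted(self.per_sample.items())]
        rows += [
            ("unassigned_barcode", self.unassigned_barcode),
            ("unmatched_guide", self.unmatched_guide),
            ("multi_hit_guide", self.multi_hit),
            ("total", self.total),
        ]
        return pd.DataFrame(rows, columns=["category", "reads"])


def _min_pairwise_hamming(seqs: Sequence[str]) -> int:
    """Smallest pairwise Hamming distance among equal-length sequences."""
    if len(seqs) < 2:
        return len(seqs[0]) if seqs else 0
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1)
    best = arr.shape[1]
    chunk = max(1, 2**24 // (len(seqs) * arr.shape[1] + 1))
    for i in range(0, len(seqs), chunk):
        block = arr[i : i + chunk]
        d = (block[:, None, :] != arr[None, :, :]).sum(axis=2)
        for r, row in enumerate(d):
            row[i + r] = arr.shape[1]  # ignore self-distance
        best = min(best, int(d.min()))
    return best


def _neighbors(seq: str, mismatches: int) -> Iterable[str]:
    """All sequences within Hamming distance <= mismatches of seq."""
    alphabet = "ACGT"
    for k in range(mismatches + 1):
        for positions in itertools.combinations(range(len(seq)), k):
            subs = [[c for c in alphabet if c != seq[p]] for p in positions]
            for repl in itertools.product(*subs):
                s = list(seq)
                for p, c in zip(positions, repl):
                    s[p] = c
                yield "".join(s)


def _lookup_table(seqs: Sequence[str], ids: Sequence, mismatches: int) -> dict[str, object]:
    """Exact-lookup dict mapping every sequence within tolerance to its id.

    Valid only when references are pairwise more than 2*mismatches apart
    (Hamming balls disjoint), which the caller enforces.
    """
    if mismatches == 0:
        return dict(zip(seqs, ids))
    table: dict[str, object] = {}
    for seq, ident in zip(seqs, ids):
        for nb in _neighbors(seq, mismatches):
            table[nb] = ident
    return table


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def demux_and_count(
    fastq: PathLike | str | Sequence[PathLike | str],
    library: pd.DataFrame,
    sheet: pd.DataFrame,
    barcode_mismatch: int = 0,
    guide_mismatch: int = 0,
    layout: ReadLayout | None = None,
) -> tuple[CountMatrix, DemuxStats]:
    """Demultiplex FASTQ reads into a CountMatrix.

    Refuses ambiguous designs up front: barcodes (and guides) must be pairwise
    more than twice the respective mismatch tolerance apart, which makes every
    in-tolerance match unique. Short reads and out-of-tolerance barcodes count
    as unassigned; resolvable barcodes with unknown or wrong-pool guides count
    as unmatched guides.
    """
    validate_library(library)
    validate_sheet(sheet)
    layout = layout or ReadLayout()
    if isinstance(fastq, (str, PathLike)):
        fastq = [fastq]

    barcodes = list(sheet["barcode"])
    if len(set(barcodes)) < len(barcodes):
        raise ValueError("ambiguous demultiplexing: duplicate sample barcodes")
    if barcode_mismatch > 0 and _min_pairwise_hamming(barcodes) <= 2 * barcode_mismatch:
        raise ValueError(
            "ambiguous demultiplexing: barcode pairs closer than "
            f"2 x barcode_mismatch ({barcode_mismatch})"
        )
    guides = list(library["guide_seq"])
    if guide_mismatch > 0 and _min_pairwise_hamming(guides) <= 2 * guide_mismatch:
        raise ValueError(
            "ambiguous guide matching: guide pairs closer than "
            f"2 x guide_mismatch ({guide_mismatch})"
        )

    bc_table = _lookup_table(barcodes, sheet["sample_id"], barcode_mismatch)
    guide_table = _lookup_table(guides, library["construct_id"], guide_mismatch)
    pool_of_sample = sheet.set_index("sample_id")["pool_id"].to_dict()
    pool_of_construct = library.set_index("construct_id")["pool_id"].to_dict()

    off, glen, blen = layout.guide_offset, layout.guide_len, layout.barcode_len
    min_len = off + glen
    stats = DemuxStats(per_sample={s: 0 for s in sheet["sample_id"]})
    tallies: dict[tuple[str, str], int] = {}
    for path in fastq:
        with _open_text(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                if len(seq) < min_len:
                    stats.unassigned_barcode += 1
                    continue
                sample = bc_table.get(seq[:blen])
                if sample is None:
                    stats.unassigned_barcode += 1
                    continue
                cid = guide_table.get(seq[off : off + glen])
                if cid is None or pool_of_construct[cid] != pool_of_sample[sample]:
                    stats.unmatched_guide += 1
                    continue
                stats.per_sample[sample] += 1
                tallies[(cid, sample)] = tallies.get((cid, sample), 0) + 1

    counts = pd.DataFrame(
        np.nan,
        index=pd.Index(library["construct_id"], name="construct_id"),
        columns=sheet["sample_id"],
    )
    pools = library.set_index("construct_id")["pool_id"]
    for sample in counts.columns:
        counts.loc[pools == pool_of_sample[sample], sample] = 0.0
    for (cid, sample), n in tallies.items():
        counts.loc[cid, sample] = float(n)
    matrix = CountMatrix(counts=counts, library=library, sheet=sheet)
    logger.info(
        "demux: %d reads, %d assigned, %d unassigned barcode, %d unmatched guide",
        stats.total,
        stats.assigned,
        stats.unassigned_barcode,
        stats.unmatched_guide,
    )
    return matrix, stats


def write_counts(matrix: CountMatrix, path: PathLike | str) -> None:
    """Write counts as TSV: construct_id column then one integer column per
    sample; cells outside a sample's pool are left empty."""
    out = matrix.counts.copy()
    out.to_csv(path, sep="\t", float_format="%.0f")


def read_counts(
    path: PathLike | str,
    library: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
) -> CountMatrix | pd.DataFrame:
    """Read a counts TSV, validating that every defined cell is a nonnegative
    integer (errors name the offending construct and sample). With a library
    and sheet, rows are checked against the library and a CountMatrix is
    returned; otherwise the bare frame."""
    frame = pd.read_csv(path, sep="\t", index_col="construct_id")
    frame.columns.name = "sample_id"
    for sample in frame.columns:
        col = frame[sample]
        bad = col.notna() & ((col < 0) | (col != np.floor(col)))
        if bad.any():
            cid = bad[bad].index[0]
            raise ValueError(
                f"invalid count at construct {cid!r}, sample {sample!r}: {col[cid]}"
            )
    if library is None:
        return frame
    unknown = set(frame.index) - set(library["construct_id"])
    if unknown:
        raise ValueError(f"counts contain constructs absent from the library: {sorted(unknown)[:5]}")
    frame = frame.reindex(pd.Index(library["construct_id"], name="construct_id"))
    if sheet is None:
        raise ValueError("a sample sheet is required alongside the library")
    matrix = CountMatrix(counts=frame, library=library, sheet=sheet)
    matrix.validate()
    return matrix
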