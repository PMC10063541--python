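"""Lightweight aligned-read container plus SAM/BAM import/export via pysam."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: columns of :attr:`ReadSet.table`
READ_COLUMNS = ("contig", "start", "length", "is_reverse")


@dataclass
class ReadSet:
    """Coordinate-sorted, gap-free read alignments.

    ``table`` has columns ``contig`` (str), ``start`` (0-based leftmost
    aligned base), ``length`` (aligned span, bp) and ``is_reverse`` (bool).
    Every record is primary and fully matching (cigar ``{length}M``); the 5'
    end of a forward read is ``start``, of a reverse read ``start+length-1``.
    """

    contig_lengths: dict[str, int]
    table: pd.DataFrame
    n_skipped: int = 0
    _by_contig: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in READ_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"read table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.table)

    def for_contig(self, contig: str) -> pd.DataFrame:
        if contig not in self.contig_lengths:
            raise ValueError(f"unknown contig {contig!r}")
        if contig not in self._by_contig:
            self._by_contig[contig] = self.table[self.table["contig"] == contig]
        return self._by_contig[contig]

    def write_sam(self, path: str | Path, contigs: Mapping[str, str] | None = None) -> None:
        """Write a valid coordinate-sorted SAM file.

        ``contigs`` (contig name -> sequence) supplies SEQ fields; without it
        SEQ is '*'.  Output is byte-stable for identical inputs.
        """
        names = list(self.contig_lengths)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": int(self.contig_lengths[n])} for n in names],
        }
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            i = 0
            for contig in names:
                sub = self.for_contig(contig)
                seq = contigs[contig] if contigs is not None else None
                order = np.lexsort((sub["is_reverse"].to_numpy(), sub["start"].to_numpy()))
                starts = sub["start"].to_numpy()[order]
                lengths = sub["length"].to_numpy()[order]
                revs = sub["is_reverse"].to_numpy()[order]
                tid = names.index(contig)
                for s, ln, rv in zip(starts, lengths, revs):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"sim{i:08d}"
                    a.flag = 16 if rv else 0
                    a.reference_id = tid
                    a.reference_start = int(s)
                    a.mapping_quality = 60
                    a.cigartuples = [(0, int(ln))]
                    if seq is not None:
                        a.query_sequence = seq[int(s) : int(s) + int(ln)]
                    out.write(a)
                    i += 1


def load_alignments(path: str | Path) -> ReadSet:
    """Read a SAM/BAM file into a :class:`ReadSet`.

    Unmapped, secondary and supplementary records are skipped; the skipped
    count is logged and recorded on the returned object.
    """
    contigs: list[str] = []
    starts: list[int] = []
    lengths: list[int] = []
    revs: list[bool] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as f:
        contig_lengths = dict(zip(f.references, f.lengths))
        for rec in f.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            contigs.append(rec.reference_name)
            starts.append(rec.reference_start)
            lengths.append(rec.reference_end - rec.reference_start)
            revs.append(rec.is_reverse)
    if n_skipped:
        logger.info("skipped %d unmapped/secondary/supplementary records", n_skipped)
    table = pd.DataFrame(
        {
            "contig": pd.Series(contigs, dtype="object"),
            "start": pd.Series(starts, dtype=np.int64),
            "length": pd.Series(lengths, dtype=np.int64),
            "is_reverse": pd.Series(revs, dtype=bool),
        }
    )
    table = table.sort_values(["contig", "start", "is_reverse"], kind="stable").reset_index(
        drop=True
    )
    return ReadSet(contig_lengths=contig_lengths, table=table, n_skipped=n_skipped)
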