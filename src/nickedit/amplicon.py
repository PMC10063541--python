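"""Amplicon deep-sequencing outcome calling for prime-editing experiments.

Reads are globally aligned to both the reference allele and the intended
edited allele and classified as ``correct`` / ``wt`` / ``indel`` / ``other``
inside a quantification window around the pegRNA nick and the edit span.
The PE3 two-nick deletion statistic flags reads whose deletion length falls
within a tolerance of the inter-nick distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

# scoring scheme: a gap of length k scores GAP_OPEN + (k - 1) * GAP_EXTEND
MATCH = 2
MISMATCH = -4
GAP_OPEN = -10
GAP_EXTEND = -1

# classification labels
WT = "wt"
CORRECT = "correct"
INDEL = "indel"
OTHER = "other"
DISCARDED = "discarded"

MIN_READ_LEN = 30
MIN_MEAN_PHRED = 20.0


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlnOp:
    """One alignment operation.

    ``op``: 'M' match, 'X' substitution, 'I' insertion (bases present in the
    read but not the reference, anchored at ``ref_pos``), 'D' deletion (bases
    present in the reference but not the read).  ``seq`` carries the read-side
    bases for X and I so the read can be reconstructed exactly.
    """

    op: str
    ref_pos: int
    read_pos: int
    length: int
    seq: str | None = None


@dataclass(frozen=True)
class AlignmentResult:
    ops: tuple[AlnOp, ...]
    score: float

    @property
    def read_length(self) -> int:
        return sum(o.length for o in self.ops if o.op in ("M", "X", "I"))

    def reconstruct_read(self, ref_seq: str) -> str:
        parts = []
        for o in self.ops:
            if o.op == "M":
                parts.append(ref_seq[o.ref_pos : o.ref_pos + o.length])
            elif o.op in ("X", "I"):
                parts.append(o.seq)
        return "".join(parts)

    def deletion_lengths(self) -> tuple[int, ...]:
        return tuple(o.length for o in self.ops if o.op == "D")


def _runs_from_block(read: str, ref: str, r0: int, q0: int, n: int) -> Iterator[AlnOp]:
    """Split an aligned (gap-free) block into alternating M/X runs."""
    i = 0
    while i < n:
        is_match = read[q0 + i] == ref[r0 + i]
        j = i
        while j < n and (read[q0 + j] == ref[r0 + j]) == is_match:
            j += 1
        if is_match:
            yield AlnOp("M", r0 + i, q0 + i, j - i)
        else:
            yield AlnOp("X", r0 + i, q0 + i, j - i, read[q0 + i : q0 + j])
        i = j


def _hamming_np(a: str, b: str) -> int:
    return int(
        np.count_nonzero(
            np.frombuffer(a.encode(), np.uint8) != np.frombuffer(b.encode(), np.uint8)
        )
    )


def global_align(read: str, ref_seq: str) -> AlignmentResult:
    """Global affine-gap alignment of ``read`` to ``ref_seq``.

    Scoring: match +2, mismatch -4, gap open -10, gap extend -1 (a length-k
    gap costs ``-10 - (k-1)``); end gaps are penalized.  Equal-length pairs
    with <= 3 mismatches take a direct substitution-only path (provably
    optimal under this scheme, since any gapped alternative costs at least an
    insertion plus a deletion, -20, against at most -18 of mismatches);
    everything else goes through a full dynamic program.  Among co-optimal
    alignments the first enumerated is returned, deterministically.
    """
    if not read:
        raise ValueError("empty read")
    if len(read) == len(ref_seq):
        k = _hamming_np(read, ref_seq)
        if k <= 3:
            ops = tuple(_runs_from_block(read, ref_seq, 0, 0, len(read)))
            return AlignmentResult(ops=ops, score=float(MATCH * (len(read) - k) + MISMATCH * k))
    aln = _ALIGNER.align(ref_seq, read)[0]
    coords = np.asarray(aln.coordinates)
    ops: list[AlnOp] = []
    for k in range(coords.shape[1] - 1):
        r0, r1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if r1 > r0 and q1 > q0:
            ops.extend(_runs_from_block(read, ref_seq, r0, q0, r1 - r0))
        elif r1 > r0:
            ops.append(AlnOp("D", r0, q0, r1 - r0))
        elif q1 > q0:
            ops.append(AlnOp("I", r0, q0, q1 - q0, read[q0:q1]))
    return AlignmentResult(ops=tuple(ops), score=float(aln.score))


# ---------------------------------------------------------------------------
# edit specification
# ---------------------------------------------------------------------------


def _map_ref_to_read(ops: Sequence[AlnOp], pos: int) -> int:
    """Project a reference coordinate through an alignment onto the read."""
    read_len = sum(o.length for o in ops if o.op in ("M", "X", "I"))
    for o in ops:
        if o.op in ("M", "X"):
            if pos < o.ref_pos:
                return o.read_pos
            if pos < o.ref_pos + o.length:
                return o.read_pos + (pos - o.ref_pos)
        elif o.op == "D":
            if o.ref_pos <= pos < o.ref_pos + o.length:
                return o.read_pos
    return read_len


@dataclass
class EditSpec:
    """An amplicon editing experiment.

    ``ref_seq`` / ``edited_seq`` are the unedited and intended-edit alleles of
    the amplicon.  ``peg_nick_pos`` is the pegRNA-directed nick (0-based, on
    ``ref_seq``); ``nicking_sgrna_pos`` the optional PE3 nicking-sgRNA nick.
    The quantification window spans the union of the edit span (from a global
    alignment of the two alleles) and the pegRNA nick, padded by
    ``window_pad`` bp on each side and clipped to the amplicon; reads must be
    clean inside the window (against the edited or reference allele) to count
    as ``correct`` or ``wt``.
    """

    ref_seq: str
    edited_seq: str
    peg_nick_pos: int
    nicking_sgrna_pos: int | None = None
    window_pad: int = 10

    # derived, filled in __post_init__
    window_ref: tuple[int, int] = field(init=False)
    window_edited: tuple[int, int] = field(init=False)
    edit_span: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.ref_seq or not self.edited_seq:
            raise ValueError("ref_seq and edited_seq must be non-empty")
        if self.ref_seq == self.edited_seq:
            raise ValueError("edited_seq must differ from ref_seq")
        for label, seq in (("ref_seq", self.ref_seq), ("edited_seq", self.edited_seq)):
            if not set(seq) <= _VALID_BASES:
                raise ValueError(f"{label} has characters outside A/C/G/T")
        if not 0 <= self.peg_nick_pos < len(self.ref_seq):
            raise ValueError("peg_nick_pos outside ref_seq")
        if self.nicking_sgrna_pos is not None and not (
            0 <= self.nicking_sgrna_pos < len(self.ref_seq)
        ):
            raise ValueError("nicking_sgrna_pos outside ref_seq")
        if self.window_pad < 0:
            raise ValueError("window_pad must be >= 0")

        aln = global_align(self.edited_seq, self.ref_seq)
        lo = hi = None
        for o in aln.ops:
            if o.op == "M":
                continue
            s = o.ref_pos
            e = o.ref_pos + (o.length if o.op in ("X", "D") else 0)
            lo = s if lo is None else min(lo, s)
            hi = e if hi is None else max(hi, e)
        w_lo = max(0, min(lo, self.peg_nick_pos) - self.window_pad)
        w_hi = min(len(self.ref_seq), max(hi, self.peg_nick_pos) + self.window_pad)
        self.edit_span = (lo, hi)
        self.window_ref = (w_lo, w_hi)
        self.window_edited = (
            _map_ref_to_read(aln.ops, w_lo),
            _map_ref_to_read(aln.ops, w_hi) if w_hi < len(self.ref_seq) else len(self.edited_seq),
        )

    @property
    def inter_nick_distance(self) -> int:
        if self.nicking_sgrna_pos is None:
            raise ValueError("EditSpec has no nicking_sgrna_pos")
        return abs(self.nicking_sgrna_pos - self.peg_nick_pos)


# ---------------------------------------------------------------------------
# read classification
# ---------------------------------------------------------------------------


def _overlaps(o: AlnOp, lo: int, hi: int) -> bool:
    if o.op == "I":  # zero reference width: anchored between ref bases
        return lo <= o.ref_pos <= hi
    return o.ref_pos < hi and o.ref_pos + o.length > lo


def _window_clean(aln: AlignmentResult, lo: int, hi: int) -> bool:
    return not any(o.op != "M" and _overlaps(o, lo, hi) for o in aln.ops)


def _indel_in_window(aln: AlignmentResult, lo: int, hi: int) -> bool:
    return any(o.op in ("I", "D") and _overlaps(o, lo, hi) for o in aln.ops)


def classify_read(
    aln_ref: AlignmentResult, aln_edited: AlignmentResult, spec: EditSpec
) -> str:
    """Label one read given its alignments to both alleles.

    Precedence ``correct > indel > wt > other``: a read must match the edited
    allele cleanly inside the window to be correct (so an intended
    insertion/deletion is never double-counted as an unwanted indel), any
    insertion or deletion overlapping the window makes it an unwanted indel,
    a clean match to the reference is wild type, and substitution-only
    deviations from both alleles are ``other`` (sequencing errors must not
    inflate indel rates).
    """
    if _window_clean(aln_edited, *spec.window_edited):
        return CORRECT
    if _indel_in_window(aln_ref, *spec.window_ref):
        return INDEL
    if _window_clean(aln_ref, *spec.window_ref):
        return WT
    return OTHER


def _norm_reads(reads) -> Iterator[tuple[str, str, Sequence[int] | None]]:
    """Yield (read_id, sequence, phred qualities or None) from flexible input."""
    if isinstance(reads, pd.DataFrame):
        for rid, seq in zip(reads["read_id"], reads["sequence"]):
            yield str(rid), str(seq), None
        return
    for i, r in enumerate(reads):
        if isinstance(r, str):
            yield f"read{i:06d}", r, None
        elif isinstance(r, SeqRecord):
            qual = r.letter_annotations.get("phred_quality")
            yield r.id, str(r.seq), qual
        elif len(r) == 2:
            yield str(r[0]), str(r[1]), None
        else:
            yield str(r[0]), str(r[1]), r[2]


def classify_reads(reads, spec: EditSpec) -> pd.DataFrame:
    """Classify every read; returns columns ``read_id``, ``label``,
    ``del_lengths`` (tuple of deletion-op lengths in the reference alignment).

    QC: reads shorter than 30 nt, or with mean Phred < 20 when qualities are
    present, are labelled ``discarded`` and not aligned.  Alignments are
    memoized per distinct sequence.
    """
    cache: dict[str, tuple[str, tuple[int, ...]]] = {}
    rows = []
    for rid, seq, qual in _norm_reads(reads):
        if len(seq) < MIN_READ_LEN or (
            qual is not None and len(qual) > 0 and float(np.mean(qual)) < MIN_MEAN_PHRED
        ):
            rows.append((rid, DISCARDED, ()))
            continue
        hit = cache.get(seq)
        if hit is None:
            aln_ref = global_align(seq, spec.ref_seq)
            aln_edited = global_align(seq, spec.edited_seq)
            hit = (classify_read(aln_ref, aln_edited, spec), aln_ref.deletion_lengths())
            cache[seq] = hit
        rows.append((rid, hit[0], hit[1]))
    return pd.DataFrame(rows, columns=["read_id", "label", "del_lengths"])


@dataclass(frozen=True)
class OutcomeCounts:
    """Read-level outcome tallies for one amplicon sample.

    Frequencies are percentages of ``n_total`` (usable reads; discarded reads
    are tracked separately and excluded from the denominator).
    """

    n_total: int
    n_wt: int
    n_correct: int
    n_indel: int
    n_other: int
    n_discarded: int

    def __post_init__(self) -> None:
        if self.n_wt + self.n_correct + self.n_indel + self.n_other != self.n_total:
            raise ValueError("outcome counts do not sum to n_total")

    @property
    def freq_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_total

    @property
    def freq_indel(self) -> float:
        return 100.0 * self.n_indel / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_wt": self.n_wt,
            "n_correct": self.n_correct,
            "n_indel": self.n_indel,
            "n_other": self.n_other,
            "n_discarded": self.n_discarded,
            "freq_correct": self.freq_correct,
            "freq_indel": self.freq_indel,
        }


def quantify(reads, spec: EditSpec) -> OutcomeCounts:
    """Tally classified reads into :class:`OutcomeCounts`.

    Raises on zero usable reads rather than dividing by zero.
    """
    labels = classify_reads(reads, spec)["label"]
    counts = labels.value_counts().to_dict()
    n_disc = counts.get(DISCARDED, 0)
    n_total = len(labels) - n_disc
    if n_total == 0:
        raise ValueError("no usable reads after QC")
    return OutcomeCounts(
        n_total=n_total,
        n_wt=counts.get(WT, 0),
        n_correct=counts.get(CORRECT, 0),
        n_indel=counts.get(INDEL, 0),
        n_other=counts.get(OTHER, 0),
        n_discarded=n_disc,
    )


def two_nick_deletion_frequency(
    reads, spec: EditSpec, tol: int = 10
) -> tuple[float, pd.DataFrame]:
    """Percent of reads carrying a deletion whose length is within ``tol`` bp
    (inclusive) of the inter-nick distance.

    A read is flagged iff any *single* deletion operation in its reference
    alignment has length L with ``D - tol <= L <= D + tol`` where D is the
    distance between the pegRNA nick and the PE3 nicking-sgRNA nick; split
    deletions are not summed.  Returns (percent of usable reads, per-read
    table with ``read_id``, ``flagged``, ``del_lengths``).
    """
    if spec.nicking_sgrna_pos is None:
        raise ValueError("two-nick deletion statistic requires nicking_sgrna_pos")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    dist = spec.inter_nick_distance
    df = classify_reads(reads, spec)
    usable = df[df["label"] != DISCARDED].copy()
    if len(usable) == 0:
        raise ValueError("no usable reads after QC")
    usable["flagged"] = [
        any(dist - tol <= ln <= dist + tol for ln in lens) for lens in usable["del_lengths"]
    ]
    percent = 100.0 * usable["flagged"].sum() / len(usable)
    return float(percent), usable[["read_id", "flagged", "del_lengths"]]


def reads_from_fastq(path: str | Path) -> list:
    """Load FASTQ records (plain or gzipped is handled by file extension)."""
    p = str(path)
    if p.endswith(".gz"):
        import gzip

        with gzip.open(p, "rt") as fh:
            return list(SeqIO.parse(fh, "fastq"))
    return list(SeqIO.parse(p, "fastq"))
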