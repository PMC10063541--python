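"""Shared genomic-site primitives: protospacer geometry and digestion models.

Coordinate conventions used throughout the package:

* all coordinates are 0-based, intervals half-open; 1-based only appears at
  SAM/BED serialization boundaries, handled by pysam / the writers;
* a blunt double-strand cut at ``cut_pos`` severs the duplex between
  ``cut_pos - 1`` and ``cut_pos`` on the forward genomic strand, so a severed
  forward strand yields a fragment (and read) starting at ``cut_pos`` and a
  severed reverse strand yields a 5' read end at ``cut_pos - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PROTOSPACER_LEN = 20
PAM_LEN = 3
ELEMENT_LEN = PROTOSPACER_LEN + PAM_LEN
#: SpCas9 cuts bluntly 3 bp 5' of the PAM, between protospacer bases 17|18.
CUT_OFFSET_FROM_PAM = 3

_VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement (upper/lower case preserved, N allowed)."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class TargetSite:
    """A protospacer + PAM locus with SpCas9 cut geometry.

    ``protospacer`` is the spacer-identical sequence, i.e. the sequence of the
    non-target genomic strand.  ``site_strand`` is the genomic strand on which
    protospacer + PAM read 5'->3'; by SpCas9 biology the non-target strand
    (cleaved by RuvC) *is* the site strand, and the target strand (base-paired
    with the guide, cleaved by HNH) is its opposite.

    ``cut_pos`` follows the package-wide blunt-cut convention: the cut falls
    between ``cut_pos - 1`` and ``cut_pos`` on the forward genomic strand.
    """

    name: str
    contig: str
    protospacer: str
    pam: str
    site_strand: str
    cut_pos: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"site '{self.name}': protospacer must be {PROTOSPACER_LEN} nt, "
                f"got {len(self.protospacer)}"
            )
        if not set(self.protospacer) <= _VALID_BASES:
            raise ValueError(f"site '{self.name}': protospacer has non-ACGT bases")
        if len(self.pam) != PAM_LEN or not self.pam.endswith("GG"):
            raise ValueError(f"site '{self.name}': PAM must match NGG, got {self.pam!r}")
        if self.site_strand not in ("+", "-"):
            raise ValueError(f"site '{self.name}': strand must be '+' or '-'")
        if self.cut_pos < 0:
            raise ValueError(f"site '{self.name}': negative cut_pos")

    @property
    def non_target_strand(self) -> str:
        return self.site_strand

    @property
    def target_strand(self) -> str:
        return "-" if self.site_strand == "+" else "+"


def element_cut_pos(start: int, strand: str, cut_offset: int = CUT_OFFSET_FROM_PAM) -> int:
    """Cut coordinate for a protospacer+PAM element placed at forward-strand
    ``start`` (the element occupies ``[start, start + 23)``).

    For a '+' element (protospacer then PAM left to right) the cut falls
    ``cut_offset`` bp 5' of the PAM: ``start + 20 - cut_offset``.  For a '-'
    element (PAM revcomp first) it is mirrored: ``start + 3 + cut_offset``.
    """
    if strand == "+":
        return start + PROTOSPACER_LEN - cut_offset
    if strand == "-":
        return start + PAM_LEN + cut_offset
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def site_from_element(
    name: str,
    contig: str,
    start: int,
    strand: str,
    element_seq: str,
    cut_offset: int = CUT_OFFSET_FROM_PAM,
) -> TargetSite:
    """Build a :class:`TargetSite` from the forward-strand 23-mer at ``start``."""
    if len(element_seq) != ELEMENT_LEN:
        raise ValueError(f"site '{name}': element must be {ELEMENT_LEN} nt")
    oriented = element_seq if strand == "+" else revcomp(element_seq)
    return TargetSite(
        name=name,
        contig=contig,
        protospacer=oriented[:PROTOSPACER_LEN],
        pam=oriented[PROTOSPACER_LEN:],
        site_strand=strand,
        cut_pos=element_cut_pos(start, strand, cut_offset),
    )


@dataclass(frozen=True)
class DigestionModel:
    """Per-strand, per-molecule cleavage probabilities of an enzyme.

    The two strands of a molecule are severed independently with the stated
    probabilities when the molecule spans the cut site.  ``(1, 1)`` emulates WT
    Cas9, ``(0, 1)`` an ideal D10A nickase, ``(1, 0)`` an ideal H840A-class
    non-target-strand nickase, and ``(1, q)`` with 0 < q < 1 the observed
    H840A phenotype (non-target strand always cut, target strand partially).
    """

    p_nontarget: float
    p_target: float

    def __post_init__(self) -> None:
        for label, p in (("p_nontarget", self.p_nontarget), ("p_target", self.p_target)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {p}")

    @classmethod
    def wt(cls) -> "DigestionModel":
        return cls(1.0, 1.0)

    @classmethod
    def d10a(cls) -> "DigestionModel":
        return cls(0.0, 1.0)

    @classmethod
    def nickase(cls) -> "DigestionModel":
        """Ideal non-target-strand nickase (H840A + N863A class)."""
        return cls(1.0, 0.0)

    @classmethod
    def h840a(cls, p_target: float = 0.5) -> "DigestionModel":
        """Leaky H840A phenotype: full non-target cut, partial target cut.

        The residual target-strand probability is illustrative (the real
        fraction is enzyme- and site-dependent); override as needed.
        """
        return cls(1.0, p_target)

    def prob_for_genomic_strand(self, site: TargetSite, genomic_strand: str) -> float:
        """Cleavage probability of one *genomic* strand at ``site``.

        Maps the biological strand labels onto genomic strands via the site's
        orientation: non-target strand == site strand.
        """
        if genomic_strand not in ("+", "-"):
            raise ValueError(f"genomic strand must be '+' or '-', got {genomic_strand!r}")
        if genomic_strand == site.non_target_strand:
            return self.p_nontarget
        return self.p_target
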