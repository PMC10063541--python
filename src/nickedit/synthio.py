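"""Seeded synthetic data: toy genomes, digestion-WGS alignments, amplicon reads.

This module emulates the statistical structure of the two sequencing assays
the rest of the package analyses:

* **digestion WGS** — purified genomic DNA incubated with a nuclease/nickase,
  randomly sheared to 400-500 bp, sequenced to ~30-40x.  A molecule spanning a
  guide-directed cut site has each strand severed independently with the
  per-strand probabilities of a :class:`~nickedit.sites.DigestionModel`; every
  fragment 5' end on a strand emits one read on that strand, so strand-specific
  severing shows up as a strand-specific read-start pileup at the cut.
* **amplicon deep sequencing** — reads drawn from a known mixture of
  wild-type, correctly edited, unwanted-indel, and two-nick-deletion outcomes,
  with uniform substitution errors.

All generators are deterministic for a fixed seed.  Child RNG streams are
derived per (purpose, contig/site, molecule) via ``numpy.random.SeedSequence``
with a CRC-32 spawn key of the tags, so the stream a consumer sees does not
depend on evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import EditSpec
from .samio import ReadSet
from .sites import (
    CUT_OFFSET_FROM_PAM,
    ELEMENT_LEN,
    PROTOSPACER_LEN,
    DigestionModel,
    TargetSite,
    element_cut_pos,
    revcomp,
    site_from_element,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES = "ACGT"


def child_rng(seed: int, *tags) -> np.random.Generator:
    """Independent, reproducible child stream for ``(seed, *tags)``.

    The spawn key is the CRC-32 of each tag rendered as text; identical
    (seed, tags) always select the same stream.
    """
    spawn = tuple(zlib.crc32(str(t).encode("utf8")) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn))


# ---------------------------------------------------------------------------
# toy genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSpec:
    """Where to plant a protospacer+PAM element.

    ``start`` is the forward-strand coordinate of the 23-bp element
    ``[start, start + 23)``; for strand '-' the element content is the reverse
    complement of protospacer+PAM.  ``protospacer`` is drawn at random when
    omitted.
    """

    name: str
    contig: str
    start: int
    strand: str = "+"
    protospacer: str | None = None


@dataclass(frozen=True)
class OfftargetSpec:
    """Plant a near-copy of ``source``'s protospacer with exactly ``mismatches``
    mismatched bases (PAM kept NGG)."""

    name: str
    source: str
    contig: str
    start: int
    strand: str = "+"
    mismatches: int = 0


@dataclass
class ToyGenome:
    contigs: dict[str, str]
    planted_sites: list[TargetSite]
    planted_offtargets: list[tuple[TargetSite, int]]
    #: site name -> (contig, element start, strand), for retrieval checks
    elements: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def all_sites(self) -> list[TargetSite]:
        return list(self.planted_sites) + [s for s, _ in self.planted_offtargets]

    def site_by_name(self, name: str) -> TargetSite:
        for s in self.all_sites():
            if s.name == name:
                return s
        raise KeyError(f"no planted site named {name!r}")

    def element_sequence(self, name: str) -> str:
        """Protospacer+PAM as read 5'->3' on the site strand, extracted from
        the genome at the recorded coordinates."""
        contig, start, strand = self.elements[name]
        raw = self.contigs[contig][start : start + ELEMENT_LEN]
        return raw if strand == "+" else revcomp(raw)

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as out:
            for name, seq in self.contigs.items():
                out.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    out.write(seq[i : i + width] + "\n")

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.planted_sites:
            rows.append((s.name, s.contig, s.cut_pos, s.site_strand, "on_target", 0))
        for s, k in self.planted_offtargets:
            rows.append((s.name, s.contig, s.cut_pos, s.site_strand, "off_target", k))
        return pd.DataFrame(
            rows, columns=["name", "contig", "cut_pos", "site_strand", "kind", "mismatches"]
        )


def _random_protospacer(rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=PROTOSPACER_LEN))


def _mutate_protospacer(proto: str, k: int, rng: np.random.Generator) -> str:
    pos = rng.choice(PROTOSPACER_LEN, size=k, replace=False)
    out = list(proto)
    for p in sorted(int(x) for x in pos):
        alternatives = [b for b in _BASES if b != out[p]]
        out[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def make_toy_genome(
    n_contigs: int,
    contig_len: int,
    site_specs: Sequence[SiteSpec],
    offtarget_specs: Sequence[OfftargetSpec] = (),
    seed: int = 0,
    cut_offset: int = CUT_OFFSET_FROM_PAM,
) -> ToyGenome:
    """Random background genome with protospacer elements planted verbatim.

    Contigs are named ``chr1..chrN``.  Specs are validated for contig bounds
    and mutual overlap before any sequence is generated; violations raise with
    the offending spec's name.
    """
    if n_contigs < 1 or contig_len < ELEMENT_LEN:
        raise ValueError("need at least one contig of >= 23 bp")
    names = [f"chr{i + 1}" for i in range(n_contigs)]
    all_specs: list[tuple[str, str, int]] = [
        (sp.name, sp.contig, sp.start) for sp in list(site_specs) + list(offtarget_specs)
    ]
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for name, contig, start in all_specs:
        if contig not in names:
            raise ValueError(f"spec '{name}': unknown contig {contig!r}")
        if start < 0 or start + ELEMENT_LEN > contig_len:
            raise ValueError(f"spec '{name}': element [{start}, {start + ELEMENT_LEN}) "
                             f"outside contig bounds [0, {contig_len})")
        for lo, hi, other in intervals.get(contig, []):
            if start < hi and start + ELEMENT_LEN > lo:
                raise ValueError(f"spec '{name}' overlaps spec '{other}' on {contig}")
        intervals.setdefault(contig, []).append((start, start + ELEMENT_LEN, name))

    arrays: dict[str, bytearray] = {}
    for name in names:
        codes = child_rng(seed, "contig", name).integers(0, 4, size=contig_len, dtype=np.uint8)
        arrays[name] = bytearray(_BASE_BYTES[codes].tobytes())

    genome = ToyGenome(contigs={}, planted_sites=[], planted_offtargets=[], elements={})
    by_name: dict[str, TargetSite] = {}

    def plant(name: str, contig: str, start: int, strand: str, proto: str, rng) -> TargetSite:
        pam = _BASES[int(rng.integers(0, 4))] + "GG"
        element = proto + pam if strand == "+" else revcomp(proto + pam)
        arrays[contig][start : start + ELEMENT_LEN] = element.encode()
        genome.elements[name] = (contig, start, strand)
        return site_from_element(name, contig, start, strand, element, cut_offset)

    for sp in site_specs:
        rng = child_rng(seed, "site", sp.name)
        proto = sp.protospacer if sp.protospacer is not None else _random_protospacer(rng)
        site = plant(sp.name, sp.contig, sp.start, sp.strand, proto, rng)
        genome.planted_sites.append(site)
        by_name[sp.name] = site

    for sp in offtarget_specs:
        if sp.source not in by_name:
            raise ValueError(f"off-target spec '{sp.name}': unknown source site {sp.source!r}")
        if not 0 <= sp.mismatches <= 8:
            raise ValueError(f"off-target spec '{sp.name}': mismatches must be 0-8")
        rng = child_rng(seed, "offtarget", sp.name)
        proto = _mutate_protospacer(by_name[sp.source].protospacer, sp.mismatches, rng)
        site = plant(sp.name, sp.contig, sp.start, sp.strand, proto, rng)
        genome.planted_offtargets.append((site, sp.mismatches))

    genome.contigs = {n: arrays[n].decode("ascii") for n in names}
    return genome


def planted_site_layout(
    contig: str,
    contig_len: int,
    n_dsb: int,
    n_nick_forward: int,
    n_nick_reverse: int,
    margin: int = 5000,
) -> tuple[list[SiteSpec], dict[str, DigestionModel]]:
    """Evenly spaced site specs with the digestion models producing each
    cleavage class: DSB (both strands), forward-strand nick ('+' sites, ideal
    non-target nickase), reverse-strand nick ('-' sites, same enzyme)."""
    n = n_dsb + n_nick_forward + n_nick_reverse
    if n == 0:
        return [], {}
    span = contig_len - 2 * margin
    if span < n * ELEMENT_LEN:
        raise ValueError("contig too short for requested layout")
    starts = [margin + int(round(i * span / n)) for i in range(n)]
    specs: list[SiteSpec] = []
    models: dict[str, DigestionModel] = {}
    for i, start in enumerate(starts):
        if i < n_dsb:
            name, strand, model = f"dsb_{i + 1}", "+", DigestionModel.wt()
        elif i < n_dsb + n_nick_forward:
            name, strand, model = f"nickf_{i - n_dsb + 1}", "+", DigestionModel.nickase()
        else:
            name, strand, model = f"nickr_{i - n_dsb - n_nick_forward + 1}", "-", DigestionModel.nickase()
        specs.append(SiteSpec(name=name, contig=contig, start=start, strand=strand))
        models[name] = model
    return specs, models


# ---------------------------------------------------------------------------
# digestion WGS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentationParams:
    """Shearing and sequencing parameters for the digestion-WGS emulation.

    Defaults follow the assay this package models: random fragmentation to
    400-500 bp, 150-bp reads, 30x total depth.
    """

    frag_len_min: int = 400
    frag_len_max: int = 500
    read_len: int = 150
    depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.read_len <= self.frag_len_min <= self.frag_len_max):
            raise ValueError("require 0 < read_len <= frag_len_min <= frag_len_max")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def mean_frag_len(self) -> float:
        return (self.frag_len_min + self.frag_len_max) / 2.0


def n_molecules(contig_len: int, frag: FragmentationParams) -> int:
    """Double-stranded molecule copies per contig so realized total depth
    (both strands) matches ``frag.depth``: each strand of each copy yields one
    ``read_len`` read per ~``mean_frag_len`` of sequence."""
    return max(1, int(round(frag.depth * frag.mean_frag_len / (2.0 * frag.read_len))))


def simulate_digested_reads(
    genome: ToyGenome,
    models_by_site: Mapping[str, DigestionModel],
    frag: FragmentationParams,
) -> ReadSet:
    """Simulate in-vitro digestion + shearing + sequencing of ``genome``.

    Every planted site (on- and off-target) must appear in ``models_by_site``.
    Per double-stranded molecule copy: shear breakpoints (fragment lengths
    uniform on [frag_len_min, frag_len_max], random phase) are shared by both
    strands; each site whose strand is severed (independent Bernoulli draws
    per strand per molecule) adds the blunt cut breakpoint on that strand
    only.  One error-free read of up to ``read_len`` bp is emitted from each
    fragment 5' end on its strand.  Output is coordinate-sorted and
    deterministic for a fixed seed.
    """
    for site in genome.all_sites():
        if site.name not in models_by_site:
            raise ValueError(f"no digestion model for site '{site.name}'")

    out_contig: list[np.ndarray] = []
    starts_all: list[np.ndarray] = []
    lens_all: list[np.ndarray] = []
    rev_all: list[np.ndarray] = []

    for cname, seq in genome.contigs.items():
        L = len(seq)
        sites_here = [
            (s, models_by_site[s.name]) for s in genome.all_sites() if s.contig == cname
        ]
        nm = n_molecules(L, frag)
        for m in range(nm):
            rng = child_rng(frag.seed, "digest", cname, m)
            phase = int(rng.integers(0, frag.frag_len_max))
            n_draw = L // frag.frag_len_min + 2
            pts = np.cumsum(
                rng.integers(frag.frag_len_min, frag.frag_len_max + 1, size=n_draw)
            ) - phase
            shear = pts[(pts > 0) & (pts < L)]
            fwd_cuts = [
                s.cut_pos
                for s, mdl in sites_here
                if 0 < s.cut_pos < L and rng.random() < mdl.prob_for_genomic_strand(s, "+")
            ]
            rev_cuts = [
                s.cut_pos
                for s, mdl in sites_here
                if 0 < s.cut_pos < L and rng.random() < mdl.prob_for_genomic_strand(s, "-")
            ]
            for cuts, is_rev in ((fwd_cuts, False), (rev_cuts, True)):
                bp = np.unique(
                    np.concatenate([[0], shear, np.asarray(cuts, dtype=np.int64), [L]])
                )
                frag_lo, frag_hi = bp[:-1], bp[1:]
                if is_rev:
                    # reverse-strand 5' end = rightmost base of the fragment
                    r_start = np.maximum(frag_lo, frag_hi - frag.read_len)
                    r_len = frag_hi - r_start
                else:
                    r_start = frag_lo
                    r_len = np.minimum(frag.read_len, frag_hi - frag_lo)
                starts_all.append(r_start)
                lens_all.append(r_len)
                rev_all.append(np.full(len(r_start), is_rev))
                out_contig.append(np.full(len(r_start), cname, dtype=object))

    starts = np.concatenate(starts_all)
    lengths = np.concatenate(lens_all)
    revs = np.concatenate(rev_all)
    contigs = np.concatenate(out_contig)
    table = pd.DataFrame(
        {
            "contig": contigs,
            "start": starts.astype(np.int64),
            "length": lengths.astype(np.int64),
            "is_reverse": revs.astype(bool),
        }
    )
    table = table.sort_values(["contig", "start", "is_reverse"], kind="stable").reset_index(
        drop=True
    )
    return ReadSet(
        contig_lengths={n: len(s) for n, s in genome.contigs.items()}, table=table
    )


def digestion_truth_table(
    genome: ToyGenome, models_by_site: Mapping[str, DigestionModel]
) -> pd.DataFrame:
    """Per-site ground truth: coordinates, strand, per-strand probabilities."""
    t = genome.truth_table()
    t["p_nontarget"] = [models_by_site[n].p_nontarget for n in t["name"]]
    t["p_target"] = [models_by_site[n].p_target for n in t["name"]]
    return t


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconTruth:
    """Ground-truth outcome mixture for an amplicon sequencing simulation.

    Default frequencies echo a PE3-with-H840A-scale experiment: 30% correct
    edits, 4.3% unwanted indels, the rest wild type.  ``subst_error_rate`` is
    a uniform per-base substitution probability (Illumina-like scale).
    """

    f_correct: float = 0.30
    f_indel: float = 0.043
    f_two_nick_del: float = 0.0
    f_wt: float = 0.657
    indel_len_range: int = 10
    two_nick_del_jitter: int = 10
    subst_error_rate: float = 0.001
    n_reads: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = (self.f_correct, self.f_indel, self.f_two_nick_del, self.f_wt)
        if any(f < 0 for f in freqs):
            raise ValueError("outcome frequencies must be >= 0")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(f"outcome frequencies must sum to 1, got {sum(freqs)}")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.indel_len_range < 1:
            raise ValueError("indel_len_range must be >= 1")
        if not 0.0 <= self.subst_error_rate < 1.0:
            raise ValueError("subst_error_rate must be in [0, 1)")


LABEL_WT = "wt"
LABEL_CORRECT = "correct"
LABEL_INDEL = "indel"
LABEL_TWO_NICK = "two_nick_del"


def _apply_subst_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASE_BYTES[_BASE_BYTES != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode("ascii")


def simulate_amplicon_reads(spec: EditSpec, truth: AmpliconTruth) -> pd.DataFrame:
    """Draw labelled amplicon reads from the outcome mixture.

    Returns a DataFrame with columns ``read_id``, ``sequence``, ``label`` and
    ``del_length`` (planted deletion length, NA elsewhere).  Deterministic for
    a fixed ``truth.seed``.
    """
    if truth.f_two_nick_del > 0 and spec.nicking_sgrna_pos is None:
        raise ValueError(
            "two-nick deletion fraction > 0 requires nicking_sgrna_pos on the EditSpec"
        )
    rng = child_rng(truth.seed, "amplicon")
    probs = [truth.f_wt, truth.f_correct, truth.f_indel, truth.f_two_nick_del]
    labels = (LABEL_WT, LABEL_CORRECT, LABEL_INDEL, LABEL_TWO_NICK)
    draw = rng.choice(4, size=truth.n_reads, p=probs)
    ref = spec.ref_seq
    nick = spec.peg_nick_pos

    rows = []
    for i, d in enumerate(draw):
        label = labels[d]
        del_len: float = np.nan
        if label == LABEL_WT:
            seq = ref
        elif label == LABEL_CORRECT:
            seq = spec.edited_seq
        elif label == LABEL_INDEL:
            length = int(rng.integers(1, truth.indel_len_range + 1))
            if rng.random() < 0.5:  # insertion at the pegRNA nick
                ins = "".join(_BASES[j] for j in rng.integers(0, 4, size=length))
                seq = ref[:nick] + ins + ref[nick:]
            else:  # deletion starting at the nick
                length = min(length, len(ref) - nick - 1)
                seq = ref[:nick] + ref[nick + length :]
                del_len = length
        else:  # two-nick deletion spanning the pegRNA and nicking-sgRNA nicks
            dist = abs(spec.nicking_sgrna_pos - nick)
            j = truth.two_nick_del_jitter
            length = dist + int(rng.integers(-j, j + 1))
            start = min(nick, spec.nicking_sgrna_pos)
            length = max(1, min(length, len(ref) - start - 1))
            seq = ref[:start] + ref[start + length :]
            del_len = length
        seq = _apply_subst_errors(seq, truth.subst_error_rate, rng)
        rows.append((f"read{i:06d}", seq, label, del_len))
    return pd.DataFrame(rows, columns=["read_id", "sequence", "label", "del_length"])


def write_fastq(reads: pd.DataFrame, path: str | Path, qual_char: str = "I") -> None:
    with open(path, "w") as out:
        for rid, seq in zip(reads["read_id"], reads["sequence"]):
            out.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_read_truth(reads: pd.DataFrame, path: str | Path) -> None:
    reads[["read_id", "label", "del_length"]].to_csv(path, sep="\t", index=False)


def make_demo_edit_spec(
    seed: int = 0,
    length: int = 240,
    peg_nick_pos: int = 100,
    nick_distance: int = 48,
    edit: str = "sub",
) -> EditSpec:
    """A seeded, self-consistent amplicon editing design for demos and tests.

    ``edit`` is ``sub`` (single-base substitution 2 bp after the nick),
    ``ins`` (24-bp tag insertion at the nick) or ``del`` (15-bp deletion).
    The PE3 nicking-sgRNA nick sits ``nick_distance`` bp downstream.
    """
    rng = child_rng(seed, "demo-amplicon")
    ref = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    if edit == "sub":
        p = peg_nick_pos + 2
        new = _BASES[(_BASES.index(ref[p]) + 1) % 4]
        edited = ref[:p] + new + ref[p + 1 :]
    elif edit == "ins":
        tag = "GACTACAAGGACGACGACGACAAG"  # 24-bp Flag tag
        edited = ref[: peg_nick_pos + 2] + tag + ref[peg_nick_pos + 2 :]
    elif edit == "del":
        edited = ref[: peg_nick_pos + 2] + ref[peg_nick_pos + 17 :]
    else:
        raise ValueError(f"edit must be sub/ins/del, got {edit!r}")
    return EditSpec(
        ref_seq=ref,
        edited_seq=edited,
        peg_nick_pos=peg_nick_pos,
        nicking_sgrna_pos=peg_nick_pos + nick_distance,
    )
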