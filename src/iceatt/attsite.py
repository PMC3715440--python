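"""Attachment-site cores for site-specific integrative and conjugative elements.

The primary bacterial attachment site of ICEBs1 (attB) is a 17 bp stem-loop:
a 5 bp inverted repeat (the "arms") flanking a 7 bp spacer. Integrase-mediated
strand exchange happens inside the spacer, the crossover region, so sequence
differences there — and only there — between a chromosomal target site and the
element's own attachment site produce a heteroduplex on the excised circle.

This module holds the site data model and the operations built on it:
decomposition of a 17-mer into arms and spacer, Hamming mismatch scoring
against a reference core, heteroduplex prediction, integration/excision
junction bookkeeping, occurrence-catalog tallying, and mismatch-tolerant
genome scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "CORE_LENGTH",
    "ARM_LENGTH",
    "SPACER_LENGTH",
    "AttSiteCore",
    "SiteContext",
    "InsertionRecord",
    "JunctionPair",
    "ExcisionProduct",
    "ScanHit",
    "SiteTally",
    "CatalogSummary",
    "decompose_core",
    "mismatch_count",
    "predict_heteroduplex",
    "integrate",
    "excise",
    "tally_sites",
    "scan_genome",
    "reverse_complement",
]

#: Structural constants of the stem-loop attachment core: 5 + 7 + 5 = 17 bp.
CORE_LENGTH = 17
ARM_LENGTH = 5
SPACER_LENGTH = 7

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Orientation = Literal["co-directional", "head-on"]
ORIENTATIONS = ("co-directional", "head-on")


class SiteStructureError(ValueError):
    """Raised when a sequence does not fit the 17 bp (5+7+5) site structure."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/T."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, *, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise AlphabetError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True)
class AttSiteCore:
    """A 17 bp attachment-site core: 5 bp left arm, 7 bp spacer, 5 bp right arm.

    The spacer is the crossover region where strand exchange occurs. The arms
    of the primary site form an inverted repeat (``perfect_stem``); secondary
    sites need not satisfy that, so the stem check is informational only.
    """

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != CORE_LENGTH:
            raise SiteStructureError(
                f"attachment core must be {CORE_LENGTH} bp, got {len(seq)}"
            )
        _check_alphabet(seq, what="attachment core")
        object.__setattr__(self, "sequence", seq)

    @property
    def left_arm(self) -> str:
        return self.sequence[:ARM_LENGTH]

    @property
    def spacer(self) -> str:
        return self.sequence[ARM_LENGTH : ARM_LENGTH + SPACER_LENGTH]

    @property
    def right_arm(self) -> str:
        return self.sequence[ARM_LENGTH + SPACER_LENGTH :]

    @property
    def perfect_stem(self) -> bool:
        """True iff the right arm is the reverse complement of the left arm."""
        return self.right_arm == reverse_complement(self.left_arm)

    @classmethod
    def from_parts(cls, left_arm: str, spacer: str, right_arm: str) -> "AttSiteCore":
        return cls(left_arm + spacer + right_arm)

    def reverse_complement(self) -> "AttSiteCore":
        return AttSiteCore(reverse_complement(self.sequence))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.sequence


def decompose_core(seq: str) -> AttSiteCore:
    """Decompose a 17-mer into the fixed 5+7+5 arm/spacer/arm partition.

    Raises
    ------
    SiteStructureError
        If the sequence is not exactly 17 bases long.
    AlphabetError
        If the sequence contains ambiguity codes or other non-ACGT characters.
    """
    return AttSiteCore(seq)


@dataclass(frozen=True)
class SiteContext:
    """A 26 bp window around an attachment core, used for logo building.

    ``core_offset`` is the 0-based index of the 17 bp core within the window;
    the split of the 9 flanking bases between the two sides is kept explicit
    because it is a property of how the window was extracted, not of the site.
    """

    sequence: str
    core_offset: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != 26:
            raise SiteStructureError(
                f"site context must be 26 bp, got {len(seq)}"
            )
        _check_alphabet(seq, what="site context")
        if not 0 <= self.core_offset <= 26 - CORE_LENGTH:
            raise SiteStructureError(
                f"core_offset must be in [0, {26 - CORE_LENGTH}], got {self.core_offset}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def core(self) -> AttSiteCore:
        return AttSiteCore(
            self.sequence[self.core_offset : self.core_offset + CORE_LENGTH]
        )


@dataclass(frozen=True)
class InsertionRecord:
    """One independent insertion event at a secondary attachment site.

    Identity for deduplication is the (locus, orientation) pair: the same
    locus hit in opposite orientations presents two different target
    sequences to the integrase and counts as two distinct sites.
    """

    locus: str
    orientation: Orientation
    occurrences: int = 1
    core: AttSiteCore | None = None
    mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if self.occurrences < 1:
            raise ValueError("occurrences must be >= 1")
        if self.mismatches is not None and not 0 <= self.mismatches <= CORE_LENGTH:
            raise ValueError(f"mismatches must be in [0, {CORE_LENGTH}]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.locus, self.orientation)


@dataclass(frozen=True)
class JunctionPair:
    """The attL/attR chromosome-element junction cores after integration."""

    attL: AttSiteCore
    attR: AttSiteCore


@dataclass(frozen=True)
class ExcisionProduct:
    """Products of excision: the element circle's att core and the restored
    (empty) chromosomal site, plus whether the circle carries a heteroduplex
    in its spacer."""

    circle_att: AttSiteCore
    empty_site: AttSiteCore
    heteroduplex: bool
    #: (attL spacer, attR spacer) when they differ, else None.
    heteroduplex_spacers: tuple[str, str] | None = None


def mismatch_count(site: AttSiteCore, reference: AttSiteCore) -> int:
    """Hamming distance between two 17 bp cores.

    Symmetric; zero iff the cores are identical. Both inputs being
    ``AttSiteCore`` guarantees equal length and a clean alphabet.
    """
    return sum(a != b for a, b in zip(site.sequence, reference.sequence))


def predict_heteroduplex(target: AttSiteCore, element_att: AttSiteCore) -> bool:
    """Will integration into ``target`` followed by excision yield a circle
    with a heteroduplex attachment site?

    True iff the crossover (spacer) regions differ. Arm mismatches alone do
    not create a heteroduplex: strand exchange happens only in the spacer, so
    arm sequence segregates cleanly to one junction or the other.
    """
    return target.spacer != element_att.spacer


def integrate(
    target: AttSiteCore,
    element_att: AttSiteCore,
    *,
    spacer_assignment: Literal["target-left", "element-left"] = "target-left",
) -> JunctionPair:
    """Form the attL/attR junctions created by integration into ``target``.

    Arms follow their physical provenance: attL is chromosomal left arm +
    element right arm, attR is element left arm + chromosomal right arm. A
    spacer mismatch initially forms a heteroduplex at both junctions; host
    replication resolves it so that one junction carries the chromosomal
    spacer and the other the element spacer. Which inherits which is not
    observable from junction inequality alone, so it is a convention:
    ``"target-left"`` (default) gives attL the chromosomal target spacer and
    attR the element spacer; ``"element-left"`` swaps them. All downstream
    logic depends only on whether the two spacers differ.
    """
    if spacer_assignment == "target-left":
        left_spacer, right_spacer = target.spacer, element_att.spacer
    elif spacer_assignment == "element-left":
        left_spacer, right_spacer = element_att.spacer, target.spacer
    else:
        raise ValueError(f"unknown spacer_assignment {spacer_assignment!r}")
    attL = AttSiteCore.from_parts(target.left_arm, left_spacer, element_att.right_arm)
    attR = AttSiteCore.from_parts(element_att.left_arm, right_spacer, target.right_arm)
    return JunctionPair(attL=attL, attR=attR)


def excise(junctions: JunctionPair) -> ExcisionProduct:
    """Excise the element from its attL/attR junctions.

    The circle's attachment site reassembles the element arms (attR left arm +
    attL right arm); the empty chromosomal site reassembles the chromosomal
    arms. The heteroduplex flag is true iff the two junction spacers differ —
    in that case the circle att site carries one spacer strand from each
    junction, recorded in ``heteroduplex_spacers``; the single-sequence
    ``circle_att`` representation keeps the attR spacer and the empty site
    the attL spacer, which makes excision the exact inverse of integration
    under the default spacer assignment.
    """
    attL, attR = junctions.attL, junctions.attR
    het = attL.spacer != attR.spacer
    circle = AttSiteCore.from_parts(attR.left_arm, attR.spacer, attL.right_arm)
    empty = AttSiteCore.from_parts(attL.left_arm, attL.spacer, attR.right_arm)
    return ExcisionProduct(
        circle_att=circle,
        empty_site=empty,
        heteroduplex=het,
        heteroduplex_spacers=(attL.spacer, attR.spacer) if het else None,
    )


# ---------------------------------------------------------------------------
# Catalog tallying
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteTally:
    locus: str
    orientation: str
    occurrences: int
    percent: int  # of total insertions, rounded to nearest integer


@dataclass(frozen=True)
class CatalogSummary:
    """Summary of an insertion catalog: distinct sites, shares, modal site."""

    n_insertions: int
    n_sites: int
    sites: tuple[SiteTally, ...]  # sorted by descending occurrences

    @property
    def modal_site(self) -> SiteTally:
        return self.sites[0]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (11/27 -> 41%)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def tally_sites(records: Iterable[InsertionRecord]) -> CatalogSummary:
    """Tally an insertion catalog into distinct-site counts and percentages.

    Sites are keyed by (locus, orientation) — the same locus in opposite
    orientations is two distinct sites. Percentages are of total insertions,
    rounded to the nearest integer (ties away from zero); the sum of raw
    occurrences is conserved exactly.

    Raises
    ------
    ValueError
        If the record list is empty.
    """
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        counts[rec.key] = counts.get(rec.key, 0) + rec.occurrences
    if not counts:
        raise ValueError("cannot tally an empty insertion catalog")
    total = sum(counts.values())
    tallies = tuple(
        SiteTally(
            locus=locus,
            orientation=orientation,
            occurrences=n,
            percent=_round_half_away(100.0 * n / total),
        )
        for (locus, orientation), n in sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
    )
    return CatalogSummary(n_insertions=total, n_sites=len(tallies), sites=tallies)


# ---------------------------------------------------------------------------
# Genome scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanHit:
    """A candidate attachment site found by genome scanning.

    Coordinates are 0-based, half-open on the reference strand (BED
    convention). ``core`` is the site sequence as the integrase would read
    it: for strand "-", the reverse complement of the reference-strand slice.
    """

    contig: str
    start: int
    end: int
    strand: Literal["+", "-"]
    core: AttSiteCore
    mismatches: int


_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_strand(codes: np.ndarray, ref_codes: np.ndarray, max_mismatch: int):
    """Mismatch counts of every valid 17-mer window against the reference.

    Returns (starts, mismatches) for windows within the threshold, excluding
    windows containing any non-ACGT base.
    """
    n = codes.size
    if n < CORE_LENGTH:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(codes, CORE_LENGTH)
    valid = ~(windows == 255).any(axis=1)
    mm = (windows != ref_codes).sum(axis=1)
    keep = valid & (mm <= max_mismatch)
    return np.nonzero(keep)[0], mm[keep]


def scan_genome(
    genome: Mapping[str, str] | str,
    reference: AttSiteCore,
    max_mismatch: int,
    *,
    both_strands: bool = True,
) -> list[ScanHit]:
    """Find all 17-mers within ``max_mismatch`` of a reference core.

    Parameters
    ----------
    genome
        A contig-name -> sequence mapping, or a bare sequence (named
        ``"seq"``). Bases outside A/C/G/T/N are rejected; windows containing
        N are skipped rather than raising, since draft genomes contain N runs.
    reference
        The attachment core to scan for (typically attB).
    max_mismatch
        Hamming-distance threshold, 0–17.
    both_strands
        Scan the reverse strand too (default). A minus-strand hit's interval
        still refers to the reference strand; its core is the reverse
        complement of that slice.

    Returns
    -------
    list of ScanHit sorted by (contig, start, strand).
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if not 0 <= max_mismatch <= CORE_LENGTH:
        raise ValueError(f"max_mismatch must be in [0, {CORE_LENGTH}]")

    ref_codes = _encode(reference.sequence)
    hits: list[ScanHit] = []
    for contig in genome:
        seq = genome[contig].upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise AlphabetError(
                f"contig {contig!r} contains unexpected characters: {sorted(bad)!r}"
            )
        codes = _encode(seq)
        starts, mms = _scan_strand(codes, ref_codes, max_mismatch)
        for s, m in zip(starts.tolist(), mms.tolist()):
            hits.append(
                ScanHit(
                    contig=contig,
                    start=s,
                    end=s + CORE_LENGTH,
                    strand="+",
                    core=AttSiteCore(seq[s : s + CORE_LENGTH]),
                    mismatches=m,
                )
            )
        if both_strands:
            rc = reverse_complement(seq)
            rc_codes = _encode(rc)
            starts, mms = _scan_strand(rc_codes, ref_codes, max_mismatch)
            L = len(seq)
            for s, m in zip(starts.tolist(), mms.tolist()):
                start = L - s - CORE_LENGTH
                hits.append(
                    ScanHit(
                        contig=contig,
                        start=start,
                        end=start + CORE_LENGTH,
                        strand="-",
                        core=AttSiteCore(rc[s : s + CORE_LENGTH]),
                        mismatches=m,
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits
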