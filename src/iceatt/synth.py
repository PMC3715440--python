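"""Synthetic data with known ground truth for every input class.

Generators here emulate the study conditions the rest of the package
analyzes, at desk scale and with the truth recorded:

- genomes with attachment-site cores planted at chosen mismatch counts and
  spacer-divergence states, on an i.i.d. background of chosen GC content;
- qPCR Cq panels produced from known true copy numbers through a log-linear
  standard curve with Gaussian Cq noise;
- multinomial transconjugant draws over a site-probability vector.

All generators are pure functions of (spec, seed): the same inputs give
byte-identical outputs. The built-in ``secondary_site_catalog`` holds the
published occurrence counts of ICEBs1 insertions across its 15 secondary
attachment sites (27 independent transconjugants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .attsite import (
    ARM_LENGTH,
    CORE_LENGTH,
    SPACER_LENGTH,
    AttSiteCore,
    InsertionRecord,
    reverse_complement,
    scan_genome,
)
from .qpcr import StandardCurve

__all__ = [
    "DEFAULT_REFERENCE_CORE",
    "PlantedSite",
    "GenomeTruth",
    "make_genome",
    "make_qpcr_panel",
    "make_transconjugants",
    "secondary_site_catalog",
]

#: Synthetic stand-in for the primary attachment core used throughout the
#: generators: a 17 bp stem-loop with a perfect 5 bp inverted repeat
#: (ACCTT / AAGGT) around a 7 bp spacer. It is NOT the genomic attB sequence;
#: it reproduces the structural constraints (length, arm/spacer layout,
#: perfect stem) so that planted-site truth tables are exact.
DEFAULT_REFERENCE_CORE = AttSiteCore("ACCTTCATTACAAAGGT")

_SPACER_SLICE = slice(ARM_LENGTH, ARM_LENGTH + SPACER_LENGTH)
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one planted attachment core."""

    contig: str
    start: int  # 0-based, half-open interval [start, start + 17)
    end: int
    strand: Literal["+", "-"]
    core: AttSiteCore  # as read in integrase orientation (revcomp for "-")
    mismatches: int
    spacer_divergent: bool


@dataclass(frozen=True)
class GenomeTruth:
    """A synthetic genome plus its planted-site truth table."""

    contigs: dict[str, str]
    sites: tuple[PlantedSite, ...]
    reference: AttSiteCore
    seed: int


def _mutate_core(
    reference: AttSiteCore,
    n_mismatches: int,
    spacer_divergent: bool,
    rng: np.random.Generator,
) -> AttSiteCore:
    """Mutate the reference at exactly ``n_mismatches`` positions.

    Spacer positions are allowed iff ``spacer_divergent``; in that case at
    least one mutated position falls in the spacer, so the heteroduplex truth
    label is exact. Mutations substitute a uniformly chosen different base.
    """
    if not 0 <= n_mismatches <= CORE_LENGTH:
        raise ValueError(f"mismatch count must be in [0, {CORE_LENGTH}]")
    arm_positions = list(range(ARM_LENGTH)) + list(
        range(ARM_LENGTH + SPACER_LENGTH, CORE_LENGTH)
    )
    spacer_positions = list(range(ARM_LENGTH, ARM_LENGTH + SPACER_LENGTH))
    if spacer_divergent:
        if n_mismatches < 1:
            raise ValueError("a spacer-divergent site needs at least 1 mismatch")
        n_spacer = int(rng.integers(1, min(n_mismatches, SPACER_LENGTH) + 1))
        n_arms = n_mismatches - n_spacer
        if n_arms > len(arm_positions):
            raise ValueError("mismatch count exceeds available positions")
        positions = list(rng.choice(spacer_positions, size=n_spacer, replace=False))
        positions += list(rng.choice(arm_positions, size=n_arms, replace=False))
    else:
        if n_mismatches > len(arm_positions):
            raise ValueError(
                f"a spacer-conserved site allows at most {len(arm_positions)} mismatches"
            )
        positions = list(rng.choice(arm_positions, size=n_mismatches, replace=False))
    seq = list(reference.sequence)
    for p in positions:
        p = int(p)
        alternatives = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alternatives[int(rng.integers(3))]
    return AttSiteCore("".join(seq))


def _random_background(length: int, gc_fraction: float, rng: np.random.Generator) -> np.ndarray:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])


def make_genome(
    length: int,
    planted_specs: Sequence[tuple[int, bool, str]],
    reference: AttSiteCore = DEFAULT_REFERENCE_CORE,
    *,
    gc_fraction: float = 0.435,
    contig: str = "chr",
    seed: int = 0,
) -> GenomeTruth:
    """Generate a random genome with attachment cores planted at known
    mismatch counts.

    Parameters
    ----------
    length
        Genome length (>= 1000 bp); default GC fraction 0.435 matches a
        typical B. subtilis-like chromosome.
    planted_specs
        One (mismatch count, spacer-divergent flag, strand) triple per site
        to plant. Sites are placed at evenly spaced, non-overlapping
        positions with random jitter. Minus-strand sites are planted as the
        reverse complement of the mutated core.
    reference
        The core the mismatch counts are measured against.

    The background is i.i.d.; after planting, any accidental exact copy of
    the reference core in the background (either strand) is destroyed by a
    point substitution so that a 0-mismatch scan finds planted sites only.
    """
    if length < 1_000:
        raise ValueError("genome length must be >= 1000")
    n_sites = len(planted_specs)
    if n_sites * (CORE_LENGTH + 10) > length:
        raise ValueError("planted sites do not fit without overlap")
    rng = np.random.default_rng(seed)
    arr = _random_background(length, gc_fraction, rng)

    # evenly spaced slots with jitter, guaranteed non-overlapping
    sites: list[PlantedSite] = []
    if n_sites:
        slot = length // n_sites
        jitter_room = max(slot - CORE_LENGTH - 2, 1)
        for i, (mm, divergent, strand) in enumerate(planted_specs):
            if strand not in "+-":
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
            start = i * slot + 1 + int(rng.integers(jitter_room))
            core = _mutate_core(reference, mm, divergent, rng)
            planted_seq = core.sequence if strand == "+" else reverse_complement(core.sequence)
            arr[start : start + CORE_LENGTH] = list(planted_seq)
            sites.append(
                PlantedSite(
                    contig=contig,
                    start=start,
                    end=start + CORE_LENGTH,
                    strand=strand,  # type: ignore[arg-type]
                    core=core,
                    mismatches=mm,
                    spacer_divergent=divergent,
                )
            )

    # rejection pass: no accidental second exact copy of the reference core
    genome = {contig: "".join(arr)}
    planted_exact = {
        (s.start, s.strand) for s in sites if s.mismatches == 0
    }
    for _ in range(20):
        extra = [
            h
            for h in scan_genome(genome, reference, 0)
            if (h.start, h.strand) not in planted_exact
            and not any(s.start <= h.start < s.end or s.start < h.end <= s.end for s in sites)
        ]
        if not extra:
            break
        arr = np.array(list(genome[contig]))
        for h in extra:
            pos = h.start + int(rng.integers(CORE_LENGTH))
            current = arr[pos]
            arr[pos] = [b for b in "ACGT" if b != current][int(rng.integers(3))]
        genome = {contig: "".join(arr)}
    return GenomeTruth(
        contigs=genome, sites=tuple(sites), reference=reference, seed=seed
    )


def make_qpcr_panel(
    truths: Iterable[tuple[str, str, float]],
    curve: StandardCurve,
    *,
    noise_sd_cq: float = 0.15,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[list[tuple[str, str, int, float]], dict[tuple[str, str], float]]:
    """Generate replicate Cq values from known true copy numbers.

    Parameters
    ----------
    truths
        (sample_id, target, true copies) triples; copies must be positive.
    curve
        The standard curve through which Cq values are generated:
        Cq = slope * log10(copies) + intercept + Normal(0, noise_sd_cq).

    Returns
    -------
    rows, truth
        ``rows`` is a list of (sample_id, target, replicate, cq) suitable for
        a Cq table; ``truth`` maps (sample_id, target) to true copies.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, int, float]] = []
    truth: dict[tuple[str, str], float] = {}
    for sample_id, target, copies in truths:
        if not copies > 0:
            raise ValueError(f"true copies must be positive for {(sample_id, target)}")
        truth[(sample_id, target)] = float(copies)
        base_cq = curve.slope * np.log10(copies) + curve.intercept
        for rep in range(1, replicates + 1):
            cq = base_cq + (rng.normal(0.0, noise_sd_cq) if noise_sd_cq > 0 else 0.0)
            rows.append((sample_id, target, rep, float(cq)))
    return rows, truth


def make_transconjugants(
    site_probabilities: Mapping[tuple[str, str], float],
    n_isolates: int,
    seed: int = 0,
) -> list[InsertionRecord]:
    """Draw independent transconjugants over sites by a multinomial.

    ``site_probabilities`` maps (locus, orientation) to a probability; the
    vector must sum to 1. Occurrence counts across the returned records sum
    to ``n_isolates``; sites drawn zero times are omitted. This emulates the
    isolate-by-isolate sampling of a large transconjugant pool at the
    proportion level.
    """
    if n_isolates < 1:
        raise ValueError("n_isolates must be >= 1")
    keys = list(site_probabilities)
    probs = np.array([site_probabilities[k] for k in keys], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError("site probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_isolates, probs)
    return [
        InsertionRecord(locus=locus, orientation=orientation, occurrences=int(n))  # type: ignore[arg-type]
        for (locus, orientation), n in zip(keys, draws)
        if n > 0
    ]


def secondary_site_catalog() -> list[InsertionRecord]:
    """The published ICEBs1 secondary-attachment-site occurrence catalog:
    27 independent transconjugants across 15 distinct sites.

    yrkM was hit 11 times (41%), mmsA 3 times (11%), yqhG once in each
    orientation (two distinct sites), and 11 further sites once each.
    Mismatch counts versus attB are recorded where published (yrkM 2,
    mmsA 3, srfAA 3, yycJ 7, spoVD 8, yvbT 11, ykrP 12). The locus labels
    ``singleton_1..4`` are placeholders for four once-seen sites whose gene
    names are not carried in this catalog; only counts and orientations
    enter the statistics. Orientations are a convention consistent with the
    reported 10-of-15 co-directional split (the two yqhG records are
    genuinely opposite).
    """
    co, ho = "co-directional", "head-on"
    rows: list[tuple[str, str, int, int | None]] = [
        ("yrkM", co, 11, 2),
        ("mmsA", co, 3, 3),
        ("yqhG", co, 1, None),
        ("yqhG", ho, 1, None),
        ("srfAA", co, 1, 3),
        ("yycJ", co, 1, 7),
        ("spoVD", co, 1, 8),
        ("yvbT", co, 1, 11),
        ("ykrP", co, 1, 12),
        ("yghL", co, 1, None),
        ("ygxA", co, 1, None),
        ("singleton_1", ho, 1, None),
        ("singleton_2", ho, 1, None),
        ("singleton_3", ho, 1, None),
        ("singleton_4", ho, 1, None),
    ]
    return [
        InsertionRecord(locus=l, orientation=o, occurrences=n, mismatches=mm)  # type: ignore[arg-type]
        for l, o, n, mm in rows
    ]
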