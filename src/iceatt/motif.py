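"""Position frequency matrices and information-content logos for site windows.

Secondary attachment sites are compared by aligning a fixed 26 bp window
around each insertion point and summarizing per-position base usage as a
sequence logo. Per position i, with observed base frequencies f_ib:

    H_i = -sum_b f_ib * log2(f_ib)        (Shannon entropy, bits; 0*log 0 = 0)
    R_i = 2 - H_i                          (information content, bits)

An optional small-sample correction subtracts e(n) = 3 / (2 * ln(2) * n)
from R_i (floored at 0), the standard first-order bias correction for a
4-letter alphabet at n sequences. Letter heights in a logo are f_ib * R_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .attsite import SiteContext, AlphabetError, SiteStructureError

__all__ = ["BASES", "LogoMatrix", "build_logo", "consensus", "small_sample_correction"]

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
WINDOW = 26


def small_sample_correction(n: int) -> float:
    """First-order information-content bias e(n) = 3/(2 ln2 n) for 4 letters."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 3.0 / (2.0 * np.log(2.0) * n)


@dataclass(frozen=True)
class LogoMatrix:
    """Per-position base statistics over an alignment of 26 bp site windows.

    Attributes
    ----------
    counts : (26, 4) int array
        Base counts per position, columns ordered A, C, G, T.
    frequencies : (26, 4) float array
        counts / n_sequences; each row sums to 1.
    entropy : (26,) float array
        Shannon entropy H_i in bits, in [0, 2].
    information : (26,) float array
        R_i in bits: 2 - H_i, minus e(n) (floored at 0) if the small-sample
        correction was applied.
    """

    counts: np.ndarray
    frequencies: np.ndarray
    entropy: np.ndarray
    information: np.ndarray
    n_sequences: int
    correction_applied: bool

    @property
    def letter_heights(self) -> np.ndarray:
        """(26, 4) array of f_ib * R_i, the stack heights drawn in a logo."""
        return self.frequencies * self.information[:, None]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: position (1-based), A/C/G/T frequencies, H_i, R_i."""
        df = pd.DataFrame(self.frequencies, columns=list(BASES))
        df.insert(0, "position", np.arange(1, len(df) + 1))
        df["entropy_bits"] = self.entropy
        df["information_bits"] = self.information
        return df

    def plot(self, ax=None):
        """Draw a simple sequence logo (letters scaled to f_ib * R_i)."""
        import matplotlib.pyplot as plt
        from matplotlib.font_manager import FontProperties
        from matplotlib.patches import PathPatch
        from matplotlib.textpath import TextPath
        from matplotlib.transforms import Affine2D

        colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
        if ax is None:
            _, ax = plt.subplots(figsize=(0.45 * len(self.entropy), 2.2))
        fp = FontProperties(family="DejaVu Sans", weight="bold")
        heights = self.letter_heights
        for pos in range(heights.shape[0]):
            y = 0.0
            order = np.argsort(heights[pos])  # tallest letter on top
            for bi in order:
                h = heights[pos, bi]
                if h <= 0:
                    continue
                letter = BASES[bi]
                tp = TextPath((0, 0), letter, size=1.0, prop=fp)
                bbox = tp.get_extents()
                scale = Affine2D().translate(-bbox.x0, -bbox.y0).scale(
                    0.9 / bbox.width, h / bbox.height
                ).translate(pos + 0.05, y)
                ax.add_patch(
                    PathPatch(scale.transform_path(tp), color=colors[letter], lw=0)
                )
                y += h
        ax.set_xlim(0, heights.shape[0])
        ax.set_ylim(0, 2)
        ax.set_xticks(np.arange(heights.shape[0]) + 0.5)
        ax.set_xticklabels(np.arange(1, heights.shape[0] + 1), fontsize=7)
        ax.set_ylabel("bits")
        return ax


def _as_window(obj: SiteContext | str) -> str:
    if isinstance(obj, SiteContext):
        return obj.sequence
    seq = obj.upper()
    if len(seq) != WINDOW:
        raise SiteStructureError(f"logo input must be {WINDOW} bp, got {len(seq)}")
    bad = set(seq) - set(BASES)
    if bad:
        raise AlphabetError(f"logo input contains non-ACGT characters: {sorted(bad)!r}")
    return seq


def build_logo(
    contexts: Iterable[SiteContext | str],
    apply_small_sample_correction: bool = False,
) -> LogoMatrix:
    """Build per-position frequencies and information content from aligned
    26 bp site windows.

    Parameters
    ----------
    contexts
        Aligned, ungapped 26 bp windows (SiteContext objects or bare strings).
    apply_small_sample_correction
        If True, subtract e(n) = 3/(2 ln2 n) from every R_i (floored at 0).
        Off by default: with the ~15-sequence alignments typical here the
        correction is visually material, and both conventions are in common
        use by logo tools, so the choice is explicit.
    """
    seqs = [_as_window(c) for c in contexts]
    if not seqs:
        raise ValueError("cannot build a logo from an empty alignment")
    n = len(seqs)
    counts = np.zeros((WINDOW, 4), dtype=int)
    for seq in seqs:
        for i, b in enumerate(seq):
            counts[i, _BASE_INDEX[b]] += 1
    freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = 2.0 - entropy
    if apply_small_sample_correction:
        info = np.maximum(info - small_sample_correction(n), 0.0)
    return LogoMatrix(
        counts=counts,
        frequencies=freqs,
        entropy=entropy,
        information=info,
        n_sequences=n,
        correction_applied=apply_small_sample_correction,
    )


def consensus(logo: LogoMatrix, threshold: float) -> str:
    """Degenerate consensus: per position the most frequent base, uppercase if
    its frequency reaches ``threshold``, lowercase otherwise. Ties break
    alphabetically (A < C < G < T)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = []
    for row in logo.frequencies:
        best = int(np.argmax(row))  # argmax takes the first = alphabetical tie-break
        base = BASES[best]
        out.append(base if row[best] >= threshold else base.lower())
    return "".join(out)
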