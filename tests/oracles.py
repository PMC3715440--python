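"""Independent brute-force oracles shared across test modules."""

from iceatt.attsite import AttSiteCore, reverse_complement


def brute_force_scan(genome: dict, reference: AttSiteCore, max_mismatch: int):
    """Naive sliding-window scan oracle: pure-Python position-by-position
    comparison on both strands, N-containing windows skipped, sorted by
    (contig, start, strand)."""
    out = []
    ref = reference.sequence
    for contig, seq in genome.items():
        seq = seq.upper()
        rc = reverse_complement(seq)
        for start in range(len(seq) - 16):
            window = seq[start : start + 17]
            if set(window) <= set("ACGT"):
                mm = sum(1 for a, b in zip(window, ref) if a != b)
                if mm <= max_mismatch:
                    out.append((contig, start, "+", window, mm))
            rwindow = rc[len(seq) - start - 17 : len(seq) - start]
            if set(rwindow) <= set("ACGT"):
                mm = sum(1 for a, b in zip(rwindow, ref) if a != b)
                if mm <= max_mismatch:
                    out.append((contig, start, "-", rwindow, mm))
    out.sort(key=lambda h: (h[0], h[1], h[2]))
    return out
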