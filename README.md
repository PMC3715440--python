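# iceatt

Attachment-site analysis and population modeling for site-specific
integrative and conjugative elements (ICEs), built around ICEBs1 of
*Bacillus subtilis*.

Site-specific ICEs integrate into one primary chromosomal attachment site
— for ICEBs1 a 17 bp stem-loop, *attB*, with 5 bp inverted-repeat arms
around a 7 bp spacer where integrase-mediated strand exchange (the
crossover) occurs. When the primary site is unavailable the element uses
secondary sites that match the stem-loop imperfectly. That choice has
consequences: excision from secondary sites is reduced or abolished; sites
whose spacer differs from the element's produce a heteroduplex on the
excised circle and lose it; and cells whose element cannot excise are
killed by its rolling-circle replication when element gene expression
activates spontaneously. `iceatt` is for microbiologists and mobile-element
researchers who want to quantify these effects: it provides the
attachment-site sequence model, occurrence-catalog statistics and sequence
logos, the qPCR relative-quantification chain for excision and integration,
and the population model for the selective pressure that maintains site
specificity.

## What is implemented

- **`iceatt.attsite`** — 17 bp (5+7+5) core model; Hamming mismatch
  scoring; attL/attR junction formation and excision with heteroduplex
  prediction (`target.spacer != element.spacer`); orientation-aware catalog
  tallying; mismatch-tolerant genome scanning (both strands, BED-style
  coordinates).
- **`iceatt.motif`** — per-position frequencies and information content
  R_i = 2 − H_i (bits) over aligned 26 bp site windows, optional
  small-sample correction, consensus calling, logo rendering.
- **`iceatt.qpcr`** — standard curves Cq = slope·log10(copies) + intercept,
  efficiency 10^(−1/slope) − 1, replicate geometric means, excision
  frequency normalized to a cured strain, circle:empty ratios normalized to
  wild type, pooled integration ratios, limit-of-detection flagging, and
  the excision-vs-mating fold comparison.
- **`iceatt.popdyn`** — the competition model between primary- and
  secondary-site populations: P = P0·2^G·(1−D)^G, R = 1/(1−D)^G,
  G = log(1/R)/log(1−D), the decomposition D = a·(1−v) of death into
  activation × lethality, and a seeded stochastic simulator whose
  expectation matches the closed form.
- **`iceatt.synth`** — ground-truth generators: genomes with planted sites
  at exact mismatch counts, Cq panels from known copy numbers, multinomial
  transconjugant draws, and the published 27-isolate/15-site occurrence
  catalog.
- **`iceatt` CLI** — subcommands `scan`, `tally`, `logo`, `excision`,
  `compete`, `simulate`, `synth`, and `run` for a configured multi-stage
  pipeline with a JSON manifest.

## Worked example

```python
from iceatt import tally_sites, generations_to_ratio, mating_excision_fold
from iceatt.popdyn import round_sig
from iceatt.synth import secondary_site_catalog

s = tally_sites(secondary_site_catalog())
print(f"{s.n_sites} distinct sites over {s.n_insertions} insertions")
print(f"modal: {s.modal_site.locus} {s.modal_site.occurrences}x ({s.modal_site.percent}%)")
print(f"second: {s.sites[1].locus} {s.sites[1].occurrences}x ({s.sites[1].percent}%)")
print(f"fold: {mating_excision_fold(0.15, 0.002):.0f}")
for D in (1e-4, 1e-3):
    G = generations_to_ratio(10, D)
    print(f"D={D:g}: G={G:.1f} (~{round_sig(G, 2):.0f})")
```

prints

```
15 distinct sites over 27 insertions
modal: yrkM 11x (41%)
second: mmsA 3x (11%)
fold: 75
D=0.0001: G=23024.7 (~23000)
D=0.001: G=2301.4 (~2300)
```

Reading: the insertion catalog resolves into 15 distinct secondary sites
(same locus, opposite orientation counts twice), dominated by *yrkM* at
41% of the 27 isolates. A strain with 15% relative excision but only 0.2%
relative mating efficiency shows a 75-fold gap — the signature of circle
loss in heteroduplex-forming insertions. And under the competition model,
a per-generation death fraction of 10⁻⁴ among secondary-site cells means
the primary-site population outnumbers them 10-fold after ~23,000
generations; at 10⁻³, after ~2,300.

The same numbers are available from the shell:

```bash
iceatt synth --preset paper-catalog --outdir out/
iceatt tally out/catalog.tsv
iceatt compete -r 10 -d 1e-4
```

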