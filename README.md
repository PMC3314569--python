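# mircos

Comparative discovery of conserved plant miRNA precursors and miRNA targets
in paired EST datasets from two related species.

Plant miRNAs bind their mRNA targets with near-perfect complementarity,
which makes both the miRNAs and their targets predictable directly from
transcript sequence. When no genome is available — as for many crops whose
public data consist of expressed sequence tags (ESTs) — a comparative
screen over two related species' EST collections can separate real,
functional miRNA targets from the large background of chance matches: a
real target should recur, at the corresponding position, inside a region
conserved between the two transcriptomes.

`mircos` implements that screen end to end, for people who want to mine
EST (or transcript) collections of non-model plants:

1. **Precursor search** — inverted repeats (candidate stem-loops) are
   detected within each EST by gapped local self/reverse-complement
   alignment (einverted-style scoring: match +3, mismatch −4, gap −12,
   score ≥ 50). Inside each repeat, a known mature miRNA and its star
   counterpart are located by ungapped matching; the mature-to-star span
   must agree (±20%) with the length of an orthologous pre-miRNA of the
   same family; finally a 200-nt window around the hairpin is folded
   (energy-weighted Nussinov DP) and validated: the mature must sit on one
   arm of a coherent stem.
2. **Target scan** — every non-redundant mature miRNA is hybridised
   against every EST, both strands, under plant-target constraints: at
   most 1 mismatch, at most 1 single-nucleotide bulge, miRNA terminal
   overhangs of at most 2 nt per end, and duplex energy ≥ 70% of that
   miRNA's perfect-match energy (`|E| ≥ 0.70·|E_perfect|`). G:U wobble
   counts as a pair.
3. **COS regions** — conserved orthologous sequence regions between the
   two datasets are found by word seeding plus banded gapped extension
   with Karlin–Altschul E-values; a region qualifies when it spans ≥ 400
   alignment columns with identity > 75% and E < 10⁻¹⁰.
4. **Conserved targets** — a target is called *functionally conserved*
   when the same mature miRNA has predicted sites inside one COS region in
   both species, at corresponding positions through the alignment
   (projected overlap ≥ 10 nt).
5. **Statistics** — per miRNA, observed predictions (`TP + FP`) are
   compared with shuffled controls: 10 dinucleotide-preserving shuffles of
   the miRNA against real ESTs, and the real miRNA against 10
   nucleotide-preserving shuffles of the ESTs; `FP` is the mean of the two
   scheme means. Then

   ```
   SNR = (TP + FP) / FP        S = TP / (TP + FP) = 1 − 1 / SNR
   ```

   and a miRNA is kept when `SNR > 2` and `S ≥ 0.85`.

A seeded synthetic-data generator plants precursors, conserved and
non-conserved target sites, and diverged orthologous segments — with a
JSON truth manifest — so the whole pipeline is testable with no downloads.

## Worked example

A small synthetic study: two species × 60 ESTs, 6 planted precursors,
6 conserved + 4 non-conserved planted targets, panel of 6 mature miRNAs.

```yaml
# config.yaml
outdir: out
seed: 11
synth:
  n_ests: 60
  n_planted_precursors: 6
  n_conserved_targets: 6
  n_nonconserved_targets: 4
  n_panel: 6
  seed: 11
```

```bash
mircos run-all -c config.yaml
```

Each stage logs its headline counts and writes its tables under
`out/<stage>/`; this run prints (stderr log, abridged):

```
precursors: {'n_inverted_repeats': 5, 'n_candidates': 10, 'n_validated': 10, 'n_ests_with_validated': 5}
targets:    {'n_hits_a': 370, 'n_targeted_ests_a': 14, ..., 'n_hits_b': 160, 'n_targeted_ests_b': 10}
cos:        {'n_cos_regions': 6, 'n_ests_a_in_cos': 6, 'n_ests_b_in_cos': 6}
conserved:  {'n_conserved_site_pairs': 120, 'n_mature_targets': 4, 'n_families': 4}
stats:      {'n_mirnas': 6, 'n_evaluable': 5, 'n_passing': 4, 'n_cos_ests': 12}
```

Reading these numbers: 5 of the 6 planted precursors were recovered as
validated hairpin ESTs (the sixth carries two star-arm substitutions that
push its inverted-repeat alignment below the score threshold of 50 —
expected behaviour at that divergence, not a bug). All 6 planted COS segment pairs were
found; the conserved-target stage reports 4 distinct mature miRNAs
conserved in COS regions (the 6 planted conserved sites were drawn from 4
panel members; 120 site *pairs* because overlapping structural variants of
one site are all reported). Per-miRNA statistics land in
`out/stats/mirna_stats.tsv`:

```
mirna     observed  fp_scheme1  fp_scheme2  fp    snr      specificity  evaluable  passes
syn-miR1  38        0.00        0.00        0.00  inf      1.000        1          1
syn-miR2  84        0.00        0.50        0.25  336.000  0.997        1          1
syn-miR3  0         0.60        0.00        0.30  0.000    0.000        1          0
```

miRNAs with planted conserved sites pass (`snr > 2`, `S ≥ 0.85`); a miRNA
with no real signal but a little shuffle noise fails with specificity 0.

The individual stages are also available as `mircos simulate | precursors |
targets | cos | conserved | stats`, and everything is importable as a
library (`mircos.duplexscan.scan_targets`, `mircos.cosalign.find_cos`, …).

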