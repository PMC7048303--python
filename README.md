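# wgdkit

Toolkit for studying the fate of duplicated genes in plant genomes:
codon-level divergence estimation, whole-genome-duplication (WGD) detection
and dating from paralog-age distributions, sliding-window selection scans,
paralog expression-divergence classification, and read-coverage-based
classification of Y-chromosome regions with X–Y divergence decay.  It was
built around the analyses used to characterize the *Diospyros*-lineage WGD
and the sex-determination locus of persimmon-type dioecious plants, and is
equally usable as a library (one module per pipeline stage) or through the
`wgdkit` command.

## What it computes

**Divergence.** For a pair of coding sequences in codon register, the
Nei–Gojobori (NG86) method counts synonymous (S) and nonsynonymous (N)
sites per codon (the fraction of single-base neighbours preserving the
amino acid, stop-creating neighbours excluded) and classifies observed
differences by averaging over all substitution pathways.  The raw
proportions p = sd/S and pn = nd/N are Jukes–Cantor corrected,

d = −(3/4) · ln(1 − 4p/3),

giving dS, dN and the selection index ω = dN/dS (ω < 1 purifying, ≈ 1
neutral, > 1 positive selection).  The 4DTv statistic — the transversion
proportion at fourfold-degenerate third codon positions — provides an
alternative divergence clock.

**WGD inference.** A WGD leaves a coherent burst in the dS distribution of
surviving paralog pairs over the continuous small-scale-duplication
background.  The distribution is estimated by Gaussian KDE (Silverman
bandwidth, grid step 0.005 on [0, 3]); the mode is located inside a search
range (default [0.2, 2.0]) that excludes the recent-duplication spike; pairs
with dS in a closed window (default [0.5, 0.9]) are flagged WGD-derived; the
event age is T = dS / (2r) with r = 2.81 × 10⁻⁹ synonymous substitutions
per site per year.

**Selection scans.** Sliding 150 bp windows at 30 bp steps along the codon
alignment, pairwise or branch-specific (substitutions assigned to each
paralog's branch by outgroup parsimony), plus an exact binomial screen for
departure from ω = 1 on the substitution counts.

**Expression divergence.** Per paralog pair over an annual flower series
(8 stages × 2 sexes): Pearson r with divergence called at r² < 0.3; a 2×2
Fisher exact test (paralogs × sexes) on pooled read counts per stage group;
and log₁₀ male/female ratios with a > 5-fold inter-paralog difference flag.

**Sex chromosomes.** Pooled male/female read depth over a Y-linked contig is
summarized in windows and classified: male-specific (female read fraction
< 0.05 at ≥ half the single-copy depth, expected ≈ 20×), hyper-repetitive
(mean depth > 2× single-copy), and PAR-like (female fraction > 0.30 over a
merged run > 3 kb).  For genes retaining X and Y alleles, X–Y dS is related
to the distance from the sex-determining anchor gene (Spearman rank
correlation) and compared with interspecific X-allele baselines.

**Synthetic data.** Every input can be generated with known ground truth:
codon pairs/triples evolved under a K80-mutation × ω-acceptance process with
branch lengths calibrated so the *expected NG86-estimated* dS equals the
requested target; WGD-burst + background pair sets; negative-binomial
expression matrices with a planted divergent fraction and sex biases; and
Poisson depth tracks over a planted region layout.

## Worked example

Simulate a full input set and run the whole pipeline on it:

```
wgdkit simulate --n-wgd 400 --n-ssd 600 --n-codons 300 \
    --n-expr-pairs 200 --seed 1 --out demo/sim
wgdkit all --cds demo/sim/cds.fasta --hits demo/sim/hits.tsv \
    --expression demo/sim/expression.tsv \
    --expression-pairs demo/sim/expression_pairs.tsv \
    --depth demo/sim/depth.tsv --depth-truth demo/sim/depth.truth.json \
    --seed 1 --out demo/run
```

which prints

```
{
 "n_pairs": 1000,
 "mode_ds": 0.675,
 "n_pairs_in_window": 402,
 "date_years": 120106761.56583631,
 "expr_divergent_fraction": 0.44,
 "n_region_calls": 3,
 "region_accuracy": 1.0
}
```

Reading: the 1,000 simulated pairs (400 planted as a WGD burst at dS 0.69,
600 as exponential background) give a KDE modal dS of 0.675 — within
estimator noise of the planted burst — dating the event to ≈ 120 Myr at the
default synonymous rate; 402 pairs fall in the dS 0.5–0.9 window; 44% of
the expression pairs are called divergent (45.5% were planted); and the
depth-based classifier recovers the planted male-specific / repetitive /
PAR-like layout of the simulated contig exactly.  Stage outputs
(`pairs_annotated.tsv`, `ds_density.tsv`, `regions.bed`,
`expression_divergence.tsv`, logs and the effective `config.yaml`) are in
`demo/run/`.

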