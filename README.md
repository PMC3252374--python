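# alucensus

A census pipeline for transcription-factor binding sequences in Alu-like
repeat elements.

Alu elements are ~300-nt primate SINE retrotransposons present in roughly
1.2 million copies in the human genome. Nuclear receptors such as HNF4α
bind DR1-type direct repeats (AGGTCA**x**AGGTCA), and degenerate versions of
such sites occur throughout Alu copies. Taking a census of those sites —
which exact 13-mers a factor binds, how often each occurs genome-wide, what
fraction of each repeat family carries one, where in the repeat consensus
they sit, and how many land in promoters or open chromatin — requires a
chain of well-defined steps. `alucensus` implements that chain as a tested,
reusable library for regulatory-genomics researchers, with a thin CLI and a
synthetic-data generator so every stage can be exercised end to end without
external downloads.

## What it computes

1. **Probe library** (`alucensus.probes`): every unique k-mer of a repeat
   consensus set (default k = 13), ranked by exact genome frequency;
   systematic permutation probes of the DR1/DR2 consensus — for a consensus
   of length *L* and window *w*, exactly (*L* − *w* + 1)·4^*w* probes
   (13-nt DR1, *w* = 3 → 704; 14-nt DR2 → 768); and random-control k-mers.
2. **Binder calling** (`alucensus.pbm`): probe score = unweighted mean over
   all replicate spots; binder threshold = control mean + 2 sample SD
   (strict `>`); empirical p-value against the control distribution with an
   add-one correction, p = (#controls ≥ s + 1)/(n + 1); position weight
   matrices with per-position information content 2 + Σ_b f_b log₂ f_b.
3. **Genome scan** (`alucensus.scan`): every exact occurrence of every
   binder k-mer, overlapping occurrences included, both strands by default,
   verified against a naive sliding-window oracle.
4. **Repeat stratification** (`alucensus.repeats`): RepeatMasker `.out`
   parsing (including the minus-strand `(left) end begin` dialect), family
   classification (AluY/AluS/AluJ prefixes, FLAM/FRAM/FAM monomers), hit →
   element assignment by full containment, and 1-based consensus-relative
   site positions.
5. **Census tables** (`alucensus.census`): per-k-mer in-family vs
   genome-wide frequency, sites-per-element multiplicity, percent of
   elements per family/subfamily with ≥ 1 site, and consensus-position
   histograms. Percentages use half-up rounding so each cell is exactly
   recomputable from its own integer columns.
6. **Promoters and accessibility** (`alucensus.promoters`): strand-aware
   5-kb upstream windows, per-gene element counts (≥ 1-nt overlap), the
   ceil(mean + 2 SD) enrichment cutoff that selects genes for ontology
   analysis, and ≥ 1-nt overlap with accessible-chromatin intervals.
7. **Synthetic data** (`alucensus.simulate`): genomes with planted,
   point-mutated, optionally 5'-truncated repeat copies over an iid
   background, with exact ground truth, plus simulated PBM score tables
   (binder probes shifted above a normal control null).

## Worked example

```python
from alucensus import (SimulationConfig, assign_hits, family_summary,
                       plant_copies, random_background, scan,
                       simulate_consensus_set)

cfg = SimulationConfig(seed=7)          # 3 families, divergence 2%/10%/25%
consensus = simulate_consensus_set(cfg)
genome, plants, features = plant_copies(random_background(cfg), consensus, cfg)

kmers = set()
for seq in consensus.values():          # five binder 13-mers per family
    kmers |= {seq[i:i + 13] for i in (30, 61, 120, 199, 250)}
annotated = assign_hits(scan({"chrS1": genome}, sorted(kmers)), features)
print(family_summary(annotated, features, level="family").to_string(index=False))
```

prints

```
family_or_subfamily  n_with_site  n_total  percent
               AluY           49       50     98.0
               AluS           41       50     82.0
               AluJ            5       50     10.0
```

— of the 50 planted copies per family, nearly every copy of the young (2%
diverged) family still carries an intact binder 13-mer, while only 10% of
the old (25% diverged) family's copies do: the monotone young > old census
shape that falls out of per-base divergence acting on 13-base sites.
The `examples/` directory has one short script per capability; the full
pipeline is also available from a shell:

```bash
alucensus run-all --outdir demo --seed 1
```

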