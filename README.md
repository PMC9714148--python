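# epicrosstalk

Coordinated analysis of DNA 5-methylcytosine (5mC) and RNA
N6-methyladenosine (m6A) in multi-omics developmental studies —
built for datasets like postnatal skeletal-muscle time courses where
RNA-seq expression, WGBS methylomes and MeRIP-seq m6A peaks are
available for the same tissues.

The package implements five connected analyses:

1. **Epigenetic module eigengene (EME).** A curated set of 41 5mC/m6A
   regulator genes (21 + 20 writers/readers/erasers, packaged and
   overridable) is treated as one co-expression module. Its eigengene
   E is the first right-singular vector of the standardized
   log2(FPKM+1) submatrix; module membership kME(g) = cor(x_g, E); hub
   regulators are those with |kME| > 0.7, and the EME is the eigengene
   recomputed from the hubs.
2. **EME-correlated co-expression modules.** Genes in the top 25 % by
   expression variance are clustered on topological-overlap
   dissimilarity of the unsigned |r|⁶ network; module eigengenes are
   screened against the EME with |r| > 0.8, p < 0.05 (two-sided
   Pearson t test), keeping the direction of correlation.
3. **CpG methylation around m6A peaks.** Replicate peak sets are merged
   to reproducible peaks (≥ 1 bp overlap between biological
   replicates); upstream 5 kb / peak body / downstream 5 kb are split
   into 20 / 10 / 20 bins and bins covered by ≥ 20 CpGs are averaged
   into a metagene co-occurrence profile.
4. **m6A enrichment.** Per peak, RPM = A·10⁶/ΣA and
   Escore = RPM_IP / RPM_Input from paired IP/input libraries.
5. **5mC×m6A interaction screening.** Per m6A region, OLS fits
   log2(FPKM+1) = S + X + Y + X·Y + ε (S postnatal days, X Escore,
   Y peak CpG methylation); regions with interaction p < 0.05 and
   their genes are reported.

A synthetic-data module generates all inputs with planted,
recoverable structure (regulator blocks, EME-linked modules, in-peak
methylation elevation, enrichment multipliers, interaction
coefficients), so the whole pipeline is testable without downloads.
See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import numpy as np
from epicrosstalk.simulate import SimulationConfig, simulate_expression
from epicrosstalk.eigengene import compute_eme
from epicrosstalk.coexpression import (variance_filter, detect_modules,
                                       screen_modules_vs_eme)

cfg = SimulationConfig(seed=7, n_genes=600, module_sizes=(60, 50, 40),
                       module_cor=0.9, regulator_cor=0.9,
                       module_eme_link=("neg", "none", "none"))
expr, truth = simulate_expression(cfg)

res = compute_eme(expr, truth.regulator_ids, threshold=0.7)
print(f"hubs: {len(res.hubs)}/41 regulators with |kME| > 0.7")
print(f"EME vs planted latent r = "
      f"{np.corrcoef(res.eme.values, truth.regulator_latent)[0, 1]:.3f}")

filtered = variance_filter(expr, quantile=0.25)
nonreg = filtered.subset_genes(
    [g for g in filtered.gene_ids if not g.startswith("reg")])
screen = screen_modules_vs_eme(detect_modules(nonreg), nonreg, res.eme)
print(screen.table[["module", "n_genes", "r", "p", "selected",
                    "direction"]].to_string(index=False))
```

prints

```
hubs: 41/41 regulators with |kME| > 0.7
EME vs planted latent r = 0.999
 module  n_genes         r            p  selected direction
      1       45 -0.997897 1.194407e-95      True  negative
      2       40  0.007389 9.477996e-01     False  positive
      3       34 -0.003696 9.738784e-01     False  negative
```

All 41 regulators were generated as one coherent block, so all pass
the 0.7 hub cut and the EME tracks the planted latent profile almost
exactly. Module 1 was planted *anticorrelated* to the regulator
latent: the screen selects it with r ≈ −1 and reports the negative
direction; the two unlinked modules are correctly rejected. (The
module sizes are smaller than the planted 60/50/40 because the top-25 %
variance filter runs first.)

The interaction screen on the matched postnatal study works the same
way:

```python
from epicrosstalk.simulate import simulate_interaction_study
from epicrosstalk.interaction import escore_table, screen_interaction_regions
from epicrosstalk.cooccurrence import peak_methylation

study = simulate_interaction_study(SimulationConfig(seed=7))
esc = escore_table(study.counts, study.sample_sheet, mode=study.escore_mode)
pm = peak_methylation(study.peaks, study.methylation)
scr = screen_interaction_regions(study.expression, study.peaks, esc, pm,
                                 study.sample_sheet)
print(f"{scr.n_significant_regions} significant regions in "
      f"{scr.n_significant_genes} genes")
```

prints `9 significant regions in 9 genes`: the 5 genes planted with an
interaction coefficient bXY = 2 are all recovered, plus 4 false
positives among the 100 null genes — consistent with the raw α = 0.05
screen (≈ 5 expected).

## Command line

```bash
epicrosstalk run --seed 1 --out-dir out/            # full synthetic pipeline
epicrosstalk simulate --seed 1 --out-dir sim/       # inputs only
epicrosstalk eme --expression expr.tsv --sample-sheet sheet.tsv
epicrosstalk merge-peaks --rep1 r1.bed --rep2 r2.bed --out merged.bed
epicrosstalk profile --peaks merged.bed --methylation meth.tsv --out prof.tsv
epicrosstalk escore --counts c.tsv --totals t.tsv --sample-sheet sheet.tsv --out esc.tsv
epicrosstalk interact --expression expr.tsv --sample-sheet sheet.tsv \
    --peaks merged.bed --counts c.tsv --totals t.tsv --methylation meth.tsv
```

Exit codes: 0 success, 2 configuration error, 3 data/format error.

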