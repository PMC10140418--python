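# era3 — 3′ End Regression Analysis of miRNA isomiRs

MicroRNA 3′ ends are heterogeneous: exonucleolytic **trimming** removes
nucleotides from the canonical (miRBase) terminus, and nucleotidyl
transferases append untemplated **tails** (typically A or U).  Small-RNA
sequencing therefore reports each miRNA as a family of isomiRs whose 3′
ends sit at signed offsets from the canonical terminus.  `era3`
quantifies how this 3′-end landscape moves with a covariate of interest
— age, in the motivating application to brain maturation — and carries
the surrounding pipeline: spike-in-anchored abundance trends, positional
read coverage, simplified age-trend differential expression with pattern
clustering, and miRNA:target correlation stratification.  A synthetic-
data generator with full ground truth makes every stage testable without
any sequencing download.

It is written for computational biologists who have isomiR summary
tables (one row per isomiR × sample with trim length, tail sequence,
read count, and within-miRNA frequency), sample metadata, and optional
expression/interaction tables.

## The statistic

For isomiR *i* of miRNA *m* in sample *s*, the 3′ end position is

```
e_i = len(tail_i) − len_trim_i
```

(negative = shorter than canonical, positive = extended).  The **3′ end
score** is the frequency-weighted mean offset

```
score(m, s) = Σ_i  ratio_i(s) · e_i
```

with variants that weigh only the trim length (`trim` mode) or the count
of one nucleotide in the tail (`tail_A` … `tail_U`).  Each miRNA's score
is regressed on age plus nuisance covariates by OLS,

```
score ~ age + batch + sex        (or  ~ log(age) + …)
```

and the age coefficients are classified with Benjamini–Hochberg FDR:
**shortened** (estimate < 0, FDR < 0.05), **extended** (estimate > 0,
FDR < 0.05), else **ns**.  Because `e = Σ_N tail_N − trim` and OLS is
linear in the response, the per-miRNA age estimates satisfy exactly

```
β_total = β_tail_A + β_tail_C + β_tail_G + β_tail_U − β_trim
```

which is how the total shortening signal is decomposed into mechanism
(more trimming vs. less tailing).

## Worked example

The repository is organised as an analysis project: numbered drivers
under `analysis/` run the library in `src/era3/` on a synthetic study
and write their tables under `results/`.

```bash
python analysis/01_simulate_study.py
python analysis/02_end_regression.py
python analysis/03_expression_trends.py
python analysis/04_target_correlations.py
python analysis/05_recovery_evaluation.py
```

The first driver generates a four-age study (postnatal days 22/40/60/120,
8 samples per age, 100 miRNAs of which 30 truly shorten at 0.01–0.02
nt/day).  The second prints:

```
read 16059 isomiR records (0 dropped in validation)
100 miRNAs pass the 10-RPM filter
3'ERA classes (total mode): {'ns': 69, 'shortened': 30, 'extended': 1}
per-modification: 16 significant trim slopes, 15 significant U-tail slopes
```

i.e., all 30 truly shortened miRNAs are recovered (one false extended
call slips through at FDR 0.05), and the per-modification regressions
attribute the shortening to its two injected mechanisms.  The later
drivers report the spike-in-anchored global miRNA gain
(`estimate 0.032 per day, p = 1.1e-12`), differential expression with
age (`101 up, 81 down`), and the targeting pattern: among
differentially expressed targets, 98% of strongly correlated pairs
(|r| > 0.5) involve 3′-shortened miRNAs, while non-DE targets show no
class difference.  The final driver scores everything against the
generator's truth (sensitivity 1.0, empirical FDR 0.032, slope RMSE
0.0004 nt/day against a mean true slope of 0.0146 nt/day).

The same operations are exposed as a CLI for use on real tables:

```bash
era3 simulate --seed 17 --out study/
era3 era --isomirs study/isomirs.tsv --catalog study/catalog.fa \
         --metadata study/metadata.tsv --model age+batch+sex --out era_out/
era3 de  --counts study/counts.tsv --classes study/feature_classes.tsv \
         --metadata study/metadata.tsv --model age+batch+sex --out de_out/
```

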