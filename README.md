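# clrdiff

Compositional differential-abundance analysis for feature-by-sample
sequencing count tables (RNA-seq, 16S rRNA amplicon, selective-growth
libraries, and similar designs).

Counts are treated as compositions: for every sample, Monte Carlo instances
of the underlying proportions are drawn from a Dirichlet posterior with a
uniform 1/2 prior (so zero counts yield small positive proportions instead
of breaking the logarithm), each instance is centred log-ratio (clr)
transformed in base 2, every instance is tested between the two conditions
with Welch's t-test and the Wilcoxon rank-sum test, p-values are
Benjamini–Hochberg corrected across features within each instance, and the
expected values of both statistics are reported per feature, together with
median relative abundances, between/within-condition differences and an
effect size.

## Library use

```python
import clrdiff as cd

table = cd.read_counts("counts.tsv")           # features x samples TSV
design = cd.read_conditions("conditions.tsv")  # sample_id <TAB> condition
results = cd.analyze(cd.filter_features(table), design,
                     n_instances=128, prior=0.5, seed=42)
cd.write_results(results, "results.tsv")
```

`analyze` returns a pandas DataFrame with one row per retained feature:

| column | meaning |
|---|---|
| `rab_all` / `rab_condA` / `rab_condB` | median clr relative abundance (log2), overall and per condition |
| `diff_btw` | median between-condition clr difference (log2; B − A, where A is the condition of the first sample column) |
| `diff_win` | median within-condition clr dispersion (log2) |
| `effect` | median of paired between/within ratios |
| `we_ep`, `we_eBH` | expected Welch p and expected BH value |
| `wi_ep`, `wi_eBH` | expected Wilcoxon p and expected BH value |

Synthetic tables with known truth are available via
`cd.generate_null`, `cd.generate_selex` and `cd.generate_shift`
(see `cd.SyntheticSpec`).

## Command line

```sh
# analyze a count table
clrdiff run --counts counts.tsv --conditions cond.tsv \
            --mc-samples 128 --prior 0.5 --test both --seed 42 \
            --plot both --out myrun

# simulate a selective-growth experiment with known truth
clrdiff simulate --mode selex --features 1600 --per-group 7 \
                 --depth 100000 --enriched-fraction 0.043 --lfc 6 \
                 --sample-sigma 1.0 --seed 1 --out sim

# re-plot a written result table
clrdiff plot --results myrun.tsv --plot mw --fdr-cut 0.05
```

`run` writes `<out>.tsv` (11 columns, tab-separated) plus optional
`<out>_mw.png` / `<out>_ma.png`.  MW plots show the median between-condition
difference against the within-condition dispersion with dashed y = ±x
guide lines; MA plots show the difference against overall relative
abundance.  Points are red when the expected BH value passes the fdr cut,
cyan when only the expected p passes, black for non-significant features
rarer than the sample geometric mean (`rab_all < 0`), gray otherwise.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests, hypothesis property tests
(clr scale invariance, sub-compositional coherence, BH monotonicity) and
`tests/test_acceptance.py`, which checks the numerical acceptance criteria
(worked-example exactness, Dirichlet posterior means vs the closed form,
test p-values vs independent oracles, null false-positive control, and
directionality/convergence behaviour on simulated selective-growth data).

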