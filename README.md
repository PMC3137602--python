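# rfet

Trait-associated gene selection from small-sample expression matrices.

The pipeline combines four stages, each usable on its own:

1. **Prefilter** — per-gene two-sample t-test (pooled by default, Welch by
   flag) with a strict p-value cutoff to shrink the gene universe.
2. **SVM-RFE** — linear-kernel SVM recursive feature elimination: retrain on
   the surviving genes, drop the gene with the smallest squared weight,
   repeat until none remain, yielding a full ranking.
3. **Resampled ensemble** — repeat the ranking over many random n-fold
   subset-leave-out training sets and re-rank genes by an occurrence-gated,
   rank-discounted weight score across the resulting lists. Held-out
   accuracy is logged per fold (reporting only).
4. **Contrast** — intersect the top-K lists of two phenotype-group runs;
   genes shared by both ("tuning genes", generic responders) are removed
   from the target list.

A synthetic-data generator with planted differential genes makes every stage
testable offline, including parameter-recovery experiments.

## CLI

```sh
# simulate a dataset with 5 planted genes
rfet simulate --genes 736 --per-class 6 --informative 5 --effect 3.0 \
    --seed 7 --out simdir/

# full pipeline: t-filter -> 100x 6-fold ensemble -> aggregated ranking
rfet run --matrix simdir/matrix.tsv --samples simdir/samples.tsv \
    --alpha 0.001 --folds 6 --reps 100 --topn 10 --seed 17 --outdir run1/

# individual stages
rfet filter   --matrix M.tsv --samples S.tsv --alpha 0.001 --out filtered.tsv
rfet rank     --matrix M.tsv --samples S.tsv --C 1.0 --standardize --out ranked.tsv
rfet ensemble --matrix M.tsv --samples S.tsv --folds 6 --reps 100 \
    --seed 17 --out final.tsv --lists-dir lists/
rfet aggregate lists/*.tsv --topn 10 --out final.tsv

# remove tuning genes shared between two runs
rfet contrast --list-a runA/final_ranking.tsv --list-b runB/final_ranking.tsv \
    --topk 10 --out tuning_report.tsv --cleaned-out cleaned.tsv
```

`rfet run` accepts `--config config.yaml` (keys mirror the flags), writes a
`manifest.yaml` that reproduces the run exactly, and ingests GEO Series
Matrix files directly via `--geo-series-matrix`. Exit codes: 0 success,
2 configuration error, 3 data error, 4 computation error.

## File formats

All I/O is TSV with a header row. Expression matrices are genes-in-rows
with probe ids in the first column and sample ids in the header. Sample
metadata needs `sample_id` and `class_label` (1/0) columns; `group`,
`condition`, `replicate` are optional. Ranked lists and aggregate rankings
are written one gene per row, best rank first.

Class-label convention throughout: 1 = condition of interest (e.g. well
watered), 0 = contrast condition (e.g. drought); the SVM encodes 1 -> +1,
0 -> -1.

## Notes on defaults

- SVM cost `C` defaults to 1.0 with per-gene z-scoring; both are flags.
  The solver tolerance is pinned at 1e-6 so elimination order is
  reproducible across platforms.
- Criterion ties eliminate the gene occurring later in the current order;
  all other ties break lexicographically on probe id.
- Splits are unstratified by default (`--stratified` available); a training
  fold containing one class is an error, not a silent retry.
- `per_repetition` mode (default) merges each repetition's fold-level lists
  by mean rank into one list per repetition; `pooled` keeps every
  fold-level list.
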