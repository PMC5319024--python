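# tilscore

Marker-gene co-expression QC and immune cell scoring for bulk tumor
expression data.

Quantifying tumor-infiltrating leukocytes (TILs) from bulk RNA is attractive
wherever flow cytometry is unworkable — above all in FFPE clinical material —
but it stands or falls with the quality of the cell-type marker genes.
Genes reported as cell-type-specific in purified-cell experiments often
behave differently in the tumor microenvironment. `tilscore` validates
candidate markers directly in bulk tumor data, scores immune cell abundance
from the validated markers, and quantifies how trustworthy those scores are.

It is aimed at immuno-oncology researchers working with bulk RNA-seq or
targeted expression panels (e.g. NanoString nCounter) who want transparent,
few-gene cell scores rather than full deconvolution.

## The statistic at the core

If genes *x* and *y* are both ideal markers of the same cell type — each
expressed at a fixed number of copies per cell — their log2 expression
vectors across tumors are perfectly correlated **with slope 1**. Marker QC
therefore uses a slope-sensitive variant of Pearson correlation:

```
similarity(x, y) = Σ (x − x̄)(y − ȳ) / [ (n−1)/2 · (var(x) + var(y)) ]
                 = 2·cov(x, y) / (var(x) + var(y))
                 = r · 2·s_x·s_y / (s_x² + s_y²)
```

It equals 1 iff the genes are perfectly correlated with slope 1, and is
depressed both by low correlation and by unequal variances (non-unit
slopes): for an exact line y = a + b·x it equals 2b/(1+b²), so a slope-2
gene caps at 0.8 however strong its correlation. Candidates are clustered
(average linkage on 1 − similarity) per dataset, similarities averaged
across datasets, and the largest cluster clearing a mean-similarity
threshold (0.6 preferred, 0.4 fallback) is selected, with
correlated-but-wrong-slope genes pruned and domain-knowledge overrides
honoured.

Downstream, a **cell score** is the mean log2 expression of a cell type's
markers (one unit = one abundance doubling), **Total TILs** averages the
scores correlated > 0.6 with CD45 (PTPRC), **enrichment scores** are
residuals of each score regressed on Total TILs, absolute counts come from
a calibrated reference sample, and replicate reproducibility is decomposed
into between-sample and technical variance by a random-effects model (REML).

The bundled **TIL-60** marker set covers 14 immune cell populations with 60
genes (plus CD4 as the T-cell minus CD8 T-cell score).

## Worked example

The canned four-gene walkthrough simulates one cell type with two ideal
markers (`GENE1`, `GENE2`), an unrelated gene (`GENE3`), and a gene tracking
the same cell type with slope 2 (`GENE4`):

```python
import tilscore as ts

ds = ts.four_gene_scenario()                    # 500 samples, fixed seed
model = ts.MarkerSelectionModel(
    [ds.expression], {"CellA": ["GENE1", "GENE2", "GENE3", "GENE4"]}
)
res = model.fit()
print(res.summary().round(3).to_string())
```

```
           n_candidates  n_selected  mean_pairwise_similarity  mean_log2_expression    status selected_markers
cell_type
CellA                 4           2                      0.99                 6.944  accepted     GENE1, GENE2
```

The averaged similarity matrix shows why: the ideal pair sits at 0.99,
`GENE3` near 0, and `GENE4` near the slope-2 ceiling of 0.8 — highly
correlated, so it is rejected as `non_unit_slope_cluster` rather than
`low_similarity`:

```
       GENE1  GENE2  GENE3  GENE4
GENE1  1.000  0.990 -0.015  0.801
GENE2  0.990  1.000 -0.018  0.793
GENE3 -0.015 -0.018  1.000 -0.016
GENE4  0.801  0.793 -0.016  1.000
```

Scores convert to absolute counts once one reference sample is calibrated:
a reference with 500 macrophages and macrophage score 4 implies a score-5
sample carries

```python
>>> ts.calibrate_absolute(score=5, reference_score=4, reference_count=500)
1000.0
```

i.e. one score unit is one doubling of abundance.

The same workflow is scriptable from the shell:

```bash
tilscore simulate --four-gene --out-dir sim
tilscore qc --expression sim/expression.tsv --candidates candidates.yaml \
    --scale log2 --out-dir qc --heatmaps
tilscore score --expression counts.tsv --markers bundled --tils --enrich
```

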