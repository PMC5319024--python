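# Bundled immune cell-type marker set ("TIL-60"): 60 marker genes measuring
# 14 immune cell populations in bulk tumor expression data, selected from
# literature-derived candidates by their pairwise co-expression similarity
# across 24 TCGA RNA-seq datasets. CD4 cells are a derived score (T-cells
# minus CD8 T cells): no CD4-specific candidate survived co-expression QC.
# mean_similarity is the mean pairwise similarity statistic of the selected
# markers in TCGA (null for single-gene cell types, whose quality cannot be
# assessed from co-expression alone).
version: 1
cell_types:
  - name: B-cells
    n_candidates: 34
    mean_similarity: 0.59
    genes: [BLK, CD19, FCRL2, MS4A1, KIAA0125, TNFRSF17, TCL1A, SPIB, PNOC]
  - name: CD45
    n_candidates: 1
    mean_similarity: null
    single_gene: true
    note: CD45+ cells via PTPRC; unvalidated single-gene marker, likely expressed at different levels by different cell types
    genes: [PTPRC]
  - name: Cytotoxic cells
    n_candidates: 18
    mean_similarity: 0.69
    genes: [PRF1, GZMA, GZMB, NKG7, GZMH, KLRK1, KLRB1, KLRD1, CTSW, GNLY]
  - name: DC
    n_candidates: 7
    mean_similarity: 0.46
    genes: [CCL13, CD209, HSD11B1]
  - name: Exhausted CD8
    n_candidates: 5
    mean_similarity: 0.44
    genes: [LAG3, CD244, EOMES, PTGER4]
  - name: Macrophages
    n_candidates: 33
    mean_similarity: 0.71
    genes: [CD68, CD84, CD163, MS4A4A]
  - name: Mast cells
    n_candidates: 31
    mean_similarity: 0.74
    genes: [TPSB2, TPSAB1, CPA3, MS4A2, HDC]
  - name: Neutrophils
    n_candidates: 32
    mean_similarity: 0.48
    genes: [FPR1, SIGLEC5, CSF3R, FCAR, FCGR3B, CEACAM3, S100A12]
  - name: NK CD56dim cells
    n_candidates: 14
    mean_similarity: 0.40
    genes: [KIR2DL3, KIR3DL1, KIR3DL2, IL21R]
  - name: NK cells
    n_candidates: 36
    mean_similarity: 0.47
    genes: [XCL1, XCL2, NCR1]
  - name: T-cells
    n_candidates: 13
    mean_similarity: 0.81
    genes: [CD6, CD3D, CD3E, SH2D1A, TRAT1, CD3G]
  - name: Th1 cells
    n_candidates: 27
    mean_similarity: null
    single_gene: true
    note: TBX21 (T-bet), canonical Th1 transcription factor; also reported in B-cells
    genes: [TBX21]
  - name: Treg
    n_candidates: 18
    mean_similarity: null
    single_gene: true
    note: FOXP3, canonical Treg transcription factor
    genes: [FOXP3]
  - name: CD8 T cells
    n_candidates: 35
    mean_similarity: 0.51
    genes: [CD8A, CD8B]
derived_scores:
  - name: CD4 cells
    n_candidates: 20
    minuend: T-cells
    subtrahend: CD8 T cells
    note: T-cell score minus CD8 T cell score; no CD4-specific markers passed co-expression QC
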