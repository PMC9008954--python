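# diffregnet

Differential co-expression analysis, condition-specific gene regulatory
network (GRN) inference, and differential regulation analysis for
two-phenotype gene-expression studies — e.g. normal mucosa versus tumor
transcriptomes.

Many disease processes rewire *how* genes are regulated without large
changes in average expression. `diffregnet` detects such rewiring in three
stages:

1. **Differential co-expression (DCEA).** Pearson correlations of gene
   pairs are computed separately within each condition. Per gene, the DCp
   statistic summarizes the change of its correlations with its qualified
   partners, `dC_i = sqrt(Σ_j (r_A,ij − r_B,ij)² / n_i)`, with significance
   from a sample-label permutation FDR (differentially co-expressed genes,
   DCGs). Per pair, a modified log-fold-change screen flags links whose
   correlation change exceeds a power-law envelope fitted over the
   correlation magnitude (DCLs).
2. **Condition-specific GRNs.** For each DCG target, candidate regulators
   from a TF→target prior are prefiltered by marginal correlation, then
   bidirectional stepwise linear regression (partial-F entry/removal)
   selects the crucial regulators per condition. Coefficients on z-scored
   data are the *regulation efficacies* `X_ij` (condition A) and `Y_ij`
   (condition B).
3. **Differential regulation (DRA).** Genes are ranked by
   `DR_i = sqrt(Σ_{j=1}^{n} (X_ij − Y_ij)² / n)` over the union of their
   incident links (absent links contribute efficacy 0); links by their
   absolute efficacy change `DRL = |X − Y|` with an envelope filter; and
   each regulator by its target diversity `TDR = 1 − |T_A ∩ T_B| / |T_A ∪ T_B|`.
   Network topology (degrees, betweenness, clustering, closeness) is
   compared by Wilcoxon rank-sum tests.

A fully seeded synthetic-data generator plants a partially rewired linear
regulatory network and emits the matching ground truth, so every stage is
testable end to end without any downloads.

## Worked example

The case study ships with the package: the regulation efficacies of the
transcription factor CREB1 on seven targets in normal gastric mucosa
versus gastric cancer regulatory networks.

```bash
python analysis/06_case_study_creb1.py
```

prints

```
CREB1 regulation efficacies (normal vs cancer), ranked by |change|:
  CREB1 -> TRIM15   +2.596   -0.483   DRL = 3.079
  CREB1 -> TCEAL2   -2.315   +0.000   DRL = 2.315
  CREB1 -> NHERF1   +1.796   -0.437   DRL = 2.233
  CREB1 -> RBPMS2   -1.897   +0.000   DRL = 1.897
  CREB1 -> FERMT2   -0.673   +1.049   DRL = 1.722
  CREB1 -> FAM20C   -1.616   +0.000   DRL = 1.616
  CREB1 -> MBNL1    +0.000   +0.894   DRL = 0.894
restricted DR over these 7 links: 2.0633
target diversity (TDR): 0.571 (6 targets in normal, 4 in cancer)
```

Reading the output: CREB1's positive regulation of TRIM15 in normal tissue
(efficacy +2.596) reverses in cancer (−0.483), the largest per-link change
(DRL = 3.079); its negative regulation of TCEAL2 disappears; MBNL1 is
regulated only in cancer. The restricted DR value (2.0633) is the
root-mean-square of the seven changes; the TDR of 0.571 says more than
half of the union of CREB1's targets differ between the two networks.

## The analysis, end to end

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted ground truth, writing their tables under `results/`:

```bash
python analysis/01_simulate.py                  # 300 genes, 15 TFs, 60+60 samples
python analysis/02_differential_coexpression.py # SAM QC, DCp FDR, LFC links
python analysis/03_fit_networks.py              # stepwise GRN per condition
python analysis/04_differential_regulation.py   # DRG / DRL / TDR + recovery
python analysis/05_topology_comparison.py       # Table of topology metrics
python analysis/06_case_study_creb1.py          # the worked example above
```

Step 04 reports how well the rankings recover the planted rewiring; at the
default settings it prints `DRL precision@20 = 1.000, DRG AUROC = 0.999`.

The same pipeline is scriptable from one config:

```bash
diffregnet simulate --out sim/                    # or: --config sim.yaml
diffregnet run --config cfg.yaml --out out/
diffregnet drl --grn-a out/grn_a.tsv --grn-b out/grn_b.tsv
```

All input/output formats are plain TSV (expression matrix, two-column
condition labels, two-column TF→target prior, three-column edge lists);
see `docs/methods.md` for the model, parameter defaults and limitations.

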