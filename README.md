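# hicomp

Comparative Hi-C genome-architecture analysis in Python: from mapped
read-pair records to a two-condition comparison of A/B compartments, TADs,
contact enrichment and their association with differential gene expression.

The package targets the common experimental design in which the same cell
type is profiled by in situ Hi-C under two conditions (for example 2D
monolayer vs 3D spheroid culture) together with RNA-seq, and the question is
*which layers of genome organization change, and do the changes line up with
transcription?*  It implements the full analysis chain such a study needs,
plus a synthetic-data generator that plants a known architecture so every
stage can be validated by parameter recovery.

## What it computes

- **Valid-pair filtering and binning** — keep read pairs with MAPQ > 30 on
  both mates, drop same-restriction-fragment pairs and dangling ends
  (cis pairs < 500 bp apart), report the trans fraction, and bin cis pairs
  into per-chromosome contact matrices at 1 Mb / 100 kb / 40 kb.
- **ICE balancing** — iterative correction of multiplicative per-bin biases
  `M_ij = b_i b_j T_ij`, with gap-bin masking and cross-condition depth
  equalization.
- **Reproducibility (SCC)** — the stratum-adjusted correlation coefficient,
  `SCC = Σ_k w_k r_k / Σ_k w_k` with `w_k = N_k sd(X_k) sd(Y_k)` over
  distance strata k, with optional 2D mean-filter smoothing.
- **A/B compartments** — per chromosome: observed/expected transform,
  Pearson correlation matrix, leading eigenvector (PC1) oriented by RNA-seq
  expression density; A iff PC1 > 0.  Switches between conditions are
  classified per bin (A-common / B-common / A→B / B→A) and tested against
  replicate noise with a 2×2 chi-squared test.
- **TADs** — the γ-scaled-density dynamic program: a domain [k, l) scores
  `q(k,l) = Σ M_ij / (l−k)^γ − μ(l−k)`, and the DP returns the provably
  optimal segmentation (γ = 0.8 default); border overlap between conditions
  is counted within ±1 bin.
- **Contact enrichment** — gap-aware mean contact over interval pairs
  (compartment–compartment, TAD–TAD, within-interval), dropping pairs with
  more than 50% gap bin pairs, with per-category log2 ratios and Wilcoxon
  rank-sum comparison between conditions.
- **Expression association** — TPM quantification, a documented stand-in
  differential-expression caller (|log2FC| > 2 and p < 0.05), and the
  per-switch-category comparison of gene expression between conditions.
- **Synthetic experiments** — two-condition maps with power-law distance
  decay `d^(−α)`, compartment plaid, TAD blocks, planted bin biases,
  Poisson noise, contiguous compartment switches (default 6%, 72% A→B),
  strengthened B–B contacts in condition 2, pair streams with planted
  artifact fractions, and matched negative-binomial expression tables —
  all with full ground truth for recovery testing.

## Worked example

```python
import hicomp as h

truth = h.plant_architecture({"chr1": 500}, bin_size=100_000, seed=11)
params = h.SimulationParams(depth=1e6)
map_2d = h.simulate_contact_map(truth, params, condition=1, replicate_seed=1)["chr1"]
map_3d = h.simulate_contact_map(truth, params, condition=2, replicate_seed=2)["chr1"]

counts, genes = h.simulate_expression(truth, params, effect_log2fc=3.0, seed=3)
tpm = h.tpm(counts, genes.set_index("gene_id").loc[counts.index, "length"])

def call(cm, cols):
    iced, bias, n_iter = h.ice_contact_matrix(cm)
    oe = h.observed_over_expected(iced.matrix, iced.gap_mask)
    pc1 = h.compartment_pc1(oe, iced.gap_mask)
    dens = h.expression_density_per_bin(tpm, genes, "chr1", 500, 100_000, cols)
    return h.classify_bins(h.orient_pc1(pc1, dens))

track_2d = call(map_2d, [c for c in tpm.columns if c.startswith("c1")])
track_3d = call(map_3d, [c for c in tpm.columns if c.startswith("c2")])
switches = h.switch_classification(track_2d, track_3d)
print("switched fraction: %.3f" % switches.switched_fraction)
print("A->B share of switched: %.2f" % switches.ab_share_of_switched)

assoc = h.expression_by_category(
    tpm, genes, {"chr1": switches.categories}, 100_000, [1, 1, 2, 2])
for cat in ("A-common", "B-common", "AtoB", "BtoA"):
    r = assoc[cat]
    print(f"{cat:9s} n={r.n_genes:4d} median TPM {r.median_tpm_c1:7.1f} -> "
          f"{r.median_tpm_c2:7.1f} p={r.p_value:.3g}")
```

prints

```
switched fraction: 0.062
A->B share of switched: 0.74
A-common  n= 953 median TPM   479.6 ->   460.3 p=0.53
B-common  n= 922 median TPM   123.7 ->   113.9 p=0.223
AtoB      n=  92 median TPM   458.6 ->   461.3 p=0.959
BtoA      n=  33 median TPM    94.2 ->   995.5 p=1.43e-10
```

The planted 6% compartment switching (72% of it A→B) is recovered from the
noisy maps, and only the genes in B→A-switching bins — the ones the
generator up-regulated eightfold in condition 2 — show a significant
expression shift.

A command-line interface exposes the same stages
(`hicomp simulate | filter | bin | ice | scc | compartments | tads | enrich
| associate | compare`); `hicomp compare` runs the whole two-condition
report with a reproducible manifest.

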