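# eigas

Spectral protein structure alignment with a robustness toolkit.

`eigas` compares protein folds by aligning *eigenvalue fingerprints* of
their Cα contact matrices.  It is aimed at structural bioinformaticians who
need fast all-against-all comparisons (database-scale family recognition)
and want to know how much the answers depend on the knobs: the contact
cutoff, the gap penalties, and the experimental uncertainty of the
coordinates themselves.

## The method

For a chain of *n* residues with Cα–Cα distances `d_kt`, the smooth
contact matrix at cutoff κ is

    C_kt = 1 − d_kt/κ  (d_kt ≤ κ),   0 otherwise,

with unit diagonal.  From `C = U D Uᵀ` form `R = √D Uᵀ`; residue *i* is
assigned the eigenvalue λ_p whose row of `R` dominates column *i*
(`|R_pi| = max_q |R_qi|`, positive eigenvalues only).  Two chains are then
aligned globally over the normalized dissimilarities

    S_ij = |λ_i − λ_j| / |λ_i + λ_j|

by affine-gap dynamic programming (gap run of length L costs
`ρ_o + (L−1)ρ_c`; `ρ_o = ρ_c = ρ` recovers
`V_ij = min(V_{i−1,j}+ρ, V_{i,j−1}+ρ, V_{i−1,j−1}+S_ij)`), and the
alignment's raw value divided by its column count is the comparison score
(0 = identical fingerprints; lower = more similar).

Around that core the package provides:

* **exact stability intervals** — the open range of ρ, or of any single
  S_ij entry, over which a computed optimal alignment stays optimal,
  derived from a complete path enumeration (costs are linear in each
  parameter, so breakpoints are exact);
* **ROC / AUROC evaluation** of all-against-all scores against family
  labels, with best operating points and a trimmed 40-sample bootstrap
  interval;
* **coordinate-uncertainty simulation** — redraw every Cα from normals
  with per-axis variance `s²·B/(24π²)` (B-factor mode) or `s²·σ̂²` (NMR
  ensemble mode) and measure how AUROC degrades with the scale `s`;
* **experiment drivers** — full (κ, ρ_o, ρ_c) grid sweeps, sub-group
  tuning/validation, and s-sweeps, all seeded and bit-reproducible;
* **synthetic families** — labelled self-avoiding Cα traces with
  controllable within-family jitter, so everything above runs offline.

## A worked example

The stability machinery on a small 4×5 alignment instance
(`examples/stability_analysis.py`):

```text
optimal path: [(0, 0), (None, 1), (1, 2), (2, 3), (3, 4)]
column costs: [0.1, 0.3, 0.2, 0.2, 0.1]
optimal value: 0.900

the path stays optimal for rho in (0.150, inf)

per-entry stability intervals (entry varies, everything else fixed):
(0, 0.2)         (0.1, inf)       (0, inf)         (0, inf)         (0, inf)
(0, inf)         (0.3, inf)       (0, 0.3)         (0, inf)         (0, inf)
(0, inf)         (0, inf)         (1.11e-16, inf)  (0, 0.3)         (0, inf)
(0, inf)         (0, inf)         (0, inf)         (0, inf)         (0, 0.2)
```

The optimal alignment pairs four residues and opens one gap, for a total
cost of 0.9 at ρ = 0.3.  It survives *any* gap penalty above 0.15, and
each similarity entry can move within its printed interval (on-path
entries are bounded above — raising them eventually reroutes the
alignment; off-path entries are mostly unconstrained).

Coordinate-uncertainty on the two-family synthetic benchmark
(`examples/coordinate_uncertainty.py`, κ = 19, ρ_o = 0.5, ρ_c = 0.3):

```text
      s  mean_auroc  ci_low  ci_high  mean_best_tpr  mean_best_fpr  n_samples
 0.0000      1.0000  1.0000   1.0000         1.0000         0.0000          1
 1.0000      1.0000  1.0000   1.0000         1.0000         0.0000         40
 5.0000      0.9760  0.9010   1.0000         0.9563         0.0406         40
20.0000      0.5911  0.4062   0.7344         0.5938         0.3094         40
50.0000      0.5266  0.3385   0.6615         0.5896         0.4000         40
```

At s = 1 — noise at the level the B-factors themselves report — family
recognition is untouched (AUROC 1.0); recognition only collapses toward
chance once the noise scale dwarfs the 3.8 Å backbone spacing.

The other examples (`align_two_structures.py`, `parameter_sweep.py`) show
pairwise encoding/alignment and grid sweeps with sub-group tuning.  A thin
CLI mirrors the library (`eigas encode|align|score-all|stability|perturb|
sweep|tune|perturb-sweep`), and
`scripts/reproduce_full_benchmark.py` documents the full-scale workflow
over a directory of downloaded PDB chains.

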