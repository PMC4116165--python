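# nemagrn

**From embryo images to a preliminary gene regulatory network for gut
formation.**

Early development of the starlet sea anemone partitions the embryo into an
inner endoderm (the future gut) and an outer ectoderm. Many of the genes
driving this are known and their spatial expression has been imaged by RNA
in-situ hybridization and protein immunolocalization — but the embryo's
curved, changing shape makes those 2-D images hard to quantify, and without
quantification there is no dynamic modeling. `nemagrn` is a workflow for
exactly that chain:

1. **Quantify** — decompose the cell layer of an annotated embryo
   morphology into segments, average stain intensity per segment, edit the
   trace by reproducible rules, and standardize to a 100-point unit-maximum
   profile anchored at the oral pole.
2. **Cluster & select** — Pearson-correlation distance (`1 − r`) with
   unweighted average linkage (UPGMA), cut at linkage distance 0.6;
   partition genes into four temporal/spatial groups and pick one
   representative per group.
3. **Fit a gene circuit** — the connectionist ODE model

   ```
   dP_i/dt = s( Σ_j T_ij P_j + m_i P_mat + h_i ) − λ_i P_i,
   s(f) = ½ + arctan(f)/π
   ```

   over a 1-D chain of cell-layer points, fitted to the selected profiles
   at the target times (25 h and 50 h) by minimizing the RMS mismatch of
   unit-normalized profiles with a scatter-search global optimizer
   (enhanced-scatter-search style, no local search), repeated from ~100
   independent seeds to form an ensemble. The simplified model has
   `n(n+3)` free parameters for `n` interacting genes (18 for 3 genes);
   the full variant with free production and diffusion (`n(n+5)` = 24) is
   available but not fitted by default.
4. **Infer the network** — an activation (inhibition) edge is drawn where a
   parameter `T_ij` or `m_i` is strictly positive (negative) in ≥ 90 % of
   the ensemble's best fits; per-parameter sensitivities (central finite
   differences or forward sensitivity ODEs) rank how much each parameter
   matters.

A synthetic-data module generates every input with known ground truth —
profile templates matching the observed cluster shapes, stained embryo
images rendered onto ideal morphologies, and reference data simulated from
known circuits — so the entire pipeline is testable end to end without any
downloads.

The package is for computational/systems biologists who want a transparent,
scriptable re-implementation of this image-to-network workflow, or a
benchmarked starting point for applying it to other embryos.

## Worked example

Run the fully synthetic end-to-end pipeline (scaled down so it finishes in
a few minutes):

```bash
nemagrn run --out-dir demo_out --seed 7 --runs 8 --budget 800
```

```json
{
  "config_digest": "4f16ea1d7d99",
  "seed": 7,
  "clusters": 3,
  "representatives": ["Bcat", "snail", "foxA", "twi"],
  "best_objective": 0.020151670156111013,
  "n_edges": 3,
  "elapsed_s": 201.38
}
```

Reading this: the 49 synthetic profiles separate into 3 spatial clusters at
the 0.6 cut (central endodermal domain, oral-pole peaks, narrow border
peaks); one gene per temporal/spatial group is selected (`Bcat` as the
constant maternal gradient, plus 3 interacting genes); an ensemble of 8
scatter-search fits reaches a best RMS mismatch of ≈ 0.020 on unit-scaled
profiles; and 3 signed edges are consistent enough (≥ 90 % of fits agreeing
in sign) to enter the network, written to `demo_out/network_edges.tsv`
along with per-parameter statistics, sensitivities, the dendrogram
(Newick) and all intermediates. With the full-scale defaults (100 runs ×
10,000 evaluations) the same command produces the production ensemble.

Every stage is also a library call (`nemagrn.quantify_image`,
`nemagrn.clustering.cluster_profiles`, `nemagrn.simulate`,
`nemagrn.run_ensemble`, `nemagrn.infer_edges`,
`nemagrn.sensitivity_report`) and a standalone subcommand
(`synth`, `quantify`, `cluster`, `simulate`, `fit`, `infer`, `sens`).

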