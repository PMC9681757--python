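# betaconn

Graph-theoretic analysis of task-state functional connectivity from
trial-wise fMRI activation estimates (beta series), built around a
question from the speech-and-reading literature: what role does a
single region of interest — the left ventral occipito-temporal cortex,
the "visual word form area" — play in the whole-brain network while
participants process spoken language under different task demands and
noise levels?

The pipeline:

1. **Network construction** — per participant and condition, the
   trials × ROIs beta matrix becomes a weighted network of
   Fisher-z-transformed Spearman correlations
   (`w_ij = atanh(ρ_s(b_i, b_j))`), binarized by proportional
   thresholding (top *d*% strongest edges). The analysis density range
   is chosen from largest-connected-component behaviour across the
   cohort.
2. **Communities** — Louvain modularity optimization (γ = 1, 1000-run
   ensemble) with consensus partitioning (τ = 0.5) per participant,
   pooled into a group-representative partition per condition and
   labeled against a reference sub-network parcellation by maximal
   Jaccard overlap.
3. **Graph measures** — global efficiency and mean clustering at the
   network level; flow coefficient, betweenness centrality and
   participation coefficient (`P_i = 1 − Σ_m (k_im/k_i)²`) at the nodal
   level.
4. **Hub roles** — nodes ranked by group-mean value per measure; the
   top 5% (13 of 263) are hubs. The target node is a *local bridge*
   (flow hub), *global bridge* (betweenness hub) and/or *connector*
   (participation hub), per condition.
5. **Statistics** — within-participant permutation tests (omnibus
   label permutation, paired sign-flip post hocs), Benjamini–Hochberg
   FDR across densities, and Pearson correlation between the target's
   participation coefficient and reaction time.

Because the study's raw fMRI data are not public, the package ships a
synthetic cohort generator (`betaconn.synthetic`) that plants the
structure the analysis assumes — a 4-module block correlation over 263
ROIs, 24 participants × 80 trials × 5 conditions, a target node whose
cross-module connectivity layout switches with condition, and reaction
times coupled to the target's connectivity spread — so every stage can
be validated by recovery.

## Worked example

The numbered scripts under `analysis/` reproduce the analysis sequence
on the synthetic cohorts. The central one runs the full pipeline on the
role-dissociation cohort:

```bash
python analysis/03_run_pipeline.py --seed 0
```

which prints (abridged):

```
target node ranks (1 = highest group mean):
          flow  betweenness  participation
baseline    25           25             72
PN-        263           57              1
PN+        239           27              1
CN-        263          139              1
CN+         25           25             25

target roles per condition:
   baseline: -  (sub-network: FPN)
        PN-: ['connector']  (sub-network: VN)
        PN+: ['connector']  (sub-network: VN)
        CN-: ['connector']  (sub-network: SAN)
        CN+: -  (sub-network: VN)
```

Reading this: in both perception conditions the target node has the
highest group-mean participation coefficient of all 263 nodes (rank 1 —
a connector between sub-networks) while sitting in the visual
sub-network; during clear comprehension it remains a connector but
switches to the sensorimotor-auditory sub-network; during noisy
comprehension it loses the connector role (rank 25, below the 13-node
hub cutoff) and returns to the visual sub-network — the planted
condition-dependent role switching, recovered end to end. The same run
reports the between-condition partition similarity (NMI ≥ 0.986; the
modular skeleton is stable across conditions) and the omnibus
permutation test on the target's participation coefficient
(p ≈ 0.0005 at 2000 permutations).

The other scripts: `01` summarizes the planted cohorts,
`02` selects the density range from LCC behaviour (the rule lands at
16–22% on the default cohort), `04` prints the condition × role matrix,
`05` examines the participation–reaction-time correlation (planted
r = −0.47; the cohort-level estimate is attenuated by measurement noise
in participation, the direct recovery experiment returns
mean r = −0.477 over 1000 seeds), and `06` re-runs the participation
comparison across densities with FDR.

A `betaconn` command-line interface wraps the same stages
(`betaconn simulate | construct | metrics | community | hubs | stats |
run-all`); see `betaconn --help`.

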