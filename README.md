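# abensemble

Post-simulation analysis of antibody–antigen conformational ensembles:
geometric interaction profiling at the paratope (including explicit
bridging waters), CDR conformational-state quantification in dihedral and
Cartesian space, and correlation of the resulting per-antibody metrics
with binding affinity.

The package is aimed at people studying antibody flexibility and
interface hydration from molecular-dynamics output: it takes apo (Fv
only) and holo (Fv–antigen) ensembles as multi-model PDB files with
explicit hydrogens and waters, plus a small configuration naming chain
roles and CDR residue ranges, and produces per-frame interaction counts,
per-CDR conformational states, cluster/overlap statistics and affinity
correlations. A synthetic-data module generates complete toy panels with
planted, exactly known ground truth, so every stage is testable without
running MD.

## What it computes

**Interface interactions.** Two residues are at the interface when any
two non-hydrogen atoms, one from the Fv and one from the antigen, are
within 4.5 Å. Per frame, the package detects: hydrogen bonds (heavy
donor–acceptor distance ≤ 3.5 Å, donor–H–acceptor angle 120–180°), salt
bridges (side-chain N/O pairs of oppositely charged residues ≤ 4.5 Å),
cation–π (ring centroid–cation ≤ 6 Å, centroid→cation vector within
0–60° or 120–180° of the ring normal), π-stacking (centroid–centroid
≤ 6 Å), hydrophobic contacts (C/S atoms with no bonded N/O, ≤ 4.5 Å,
counted by residue pair), ion contacts (salt-bridge thresholds against
Na⁺/Cl⁻), and hydrogen bonds to water. A water is *bridging* when it is
simultaneously hydrogen-bonded to the Fv and the antigen in the same
frame; all other antibody–water hydrogen bonds are *bulk solvent*. The
headline interface metric is the percentage of intermolecular
interactions not formed with bulk solvent (bridging waters count as
intermolecular).

**Dihedral states.** Each CDR's backbone φ/ψ time series is histogrammed
per dihedral on a 10° circular grid; bins holding ≥ 1.5 % of frames form
peaks, the joint vector of per-dihedral peak labels defines a state, and
states below 1 % population (plus all off-peak frames) pool into a rare
fraction. States are compared by circular similarity,
s = mean_d (1 − Δ_d/180°) with Δ_d the circular difference of the mean
torsions; apo/holo states with s ≥ 0.8 count as the same conformation.

**Cartesian sampling.** Frames are superposed on the V_H/V_L-interface
backbone, a shared mass-weighted PCA basis is fitted on the concatenated
apo+holo CDR backbone coordinates, and each ensemble's frames are
projected onto the first three PCs. Conformations are average-linkage
clusters cut at a Euclidean distance threshold of 11 (mass-weighted PC
units); apo/holo overlap is the Jensen–Shannon divergence between
Gaussian KDEs of the two projections (DRES), ranging 0 (identical) to
ln 2 (disjoint).

**Affinity statistics.** ln(K_d), with K_d in nM, is the affinity proxy
(ΔG° = −RT ln K_eq). Per-antibody metrics are means over the six CDRs;
correlations are squared Pearson coefficients with a leave-one-out scan
that reports the most influential point.

## Worked example

Generate a synthetic 4-antibody panel with a planted linear relationship
between ln(K_d) and the non-solvent interaction percentage, then run the
full pipeline:

```sh
abensemble demo --out demo --seed 7 --n-antibodies 4
abensemble interactions --holo demo/ab01_holo.pdb --config demo/config.yaml --out out/ia
abensemble run --config demo/config.yaml --out out/full
```

The interactions stage prints

```
nonsolvent 56.0% of 25.0 interactions
```

meaning antibody ab01 forms 25 intermolecular interactions per frame on
average, of which 56 % are not hydrogen bonds to bulk water. The
pipeline's `out/full/metrics.csv` holds one row per antibody:

```
antibody_id  nonsolvent_pct     ln_kd  mean_holo_pca_clusters  mean_holo_dash_states  mean_dres
       ab01              56  3.689620                       1                1.00000   0.062045
       ab02              68  1.532820                       1                1.00000   0.059792
       ab03              80 -0.297494                       1                1.16667   0.061985
       ab04              96 -1.997940                       1                1.00000   0.069746
```

and `correlations.csv` recovers the planted relationship — the
non-solvent percentage explains essentially all of the affinity variance
in this noise-limited panel, while the (unplanted) flexibility metrics do
not:

```
                            x     y  n  r_squared       slope  intercept max_delta_point
        mean_holo_dash_states ln_kd  4   0.078903   -8.233990    9.30882            ab04
                    mean_dres ln_kd  4   0.506766 -398.502000   25.99360            ab04
               nonsolvent_pct ln_kd  4   0.984899   -0.141868   11.37190            ab04
```

`report.json` additionally carries the apo/holo sampling-class
percentages per method (PCA clusters vs dihedral states) and every
threshold actually used.

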