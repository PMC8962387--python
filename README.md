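# perfcell

Quantifying how far cerebral perfusion predicts the distribution of
intra-arterially transplanted, iron-oxide-labeled cells in the brain.

When mesenchymal stem cells are infused through a carotid catheter, they lodge
in the cerebral microvasculature in a pattern that partly follows blood
supply. Two MR measurements bracket the infusion: a selective intra-arterial
bolus-passage (DSC) series acquired before transplantation, from which
perfusion parameter maps are computed, and a pre/post pair of
susceptibility-weighted (SWI) volumes, on which the iron-labeled cells appear
as focal hypointense spots. `perfcell` implements the full analysis chain
connecting the two, for MR physicists and preclinical imaging groups:

* **Perfusion maps** from the 4D dynamic series S(x,t): four basemaps —
  time-to-peak (TTP), normalized signal drop (ΔS/S), maximum slope (MS),
  and CBV as the area under the concentration curve (CBV-AUC) — plus four
  maps from truncated standard-SVD (sSVD) deconvolution of the tissue curve
  C = −ln(S/S0)/TE with an arterial input function: CBF-sSVD = max of the
  deconvolved residue, Tmax-sSVD = its peak time, CBV-sSVD = ∫C/∫AIF, and
  MTT-sSVD = CBV/CBF (central volume theorem).
* **Cell-density maps** from the SWI pair: rigid NCC registration, a
  fractional-drop difference mask, connected-component cleaning, and a
  spherical-kernel density (fraction of cell-positive voxels per
  neighborhood, in [0,1]) pooled to the perfusion grid.
* **Statistics**: per-animal voxelwise Spearman ρ and OLS adjusted R²
  between each map and the density, under the whole-brain and the
  cell-accumulation masks; cohort mean ± SD; intact-vs-stroke Mann–Whitney U
  (exact for small groups) with Benjamini–Hochberg FDR.
* **A digital phantom** that simulates all three inputs — smooth CBF/MTT
  fields with CBV = CBF·MTT/60, a gamma-variate arterial input driving the
  T2* signal model, an optional unilateral ischemic lesion, and SWI cell
  spots whose placement has a *calibrated* rank coupling to CBV — so the
  entire chain is testable against known ground truth.

See `docs/methods.md` for the model, discretisation choices, and what the
phantom does and does not emulate.

## Worked example

Generate and analyze a small synthetic cohort (3 intact + 3 stroke animals,
programmed perfusion-cell coupling 0.6) in one command:

```bash
perfcell demo --out demo_out --seed 7
```

This writes, per animal, the eight perfusion maps, the cell mask, the density
map and a 16-row correlation CSV, then the cohort reports. The cohort summary
(`demo_out/analysis/cohort_summary.csv`) from that exact command:

```
map_name,mask_name,n_animals,rho_mean,rho_sd,adj_r2_mean,adj_r2_sd
cbv_auc,whole_brain,6,0.351916564,0.1487001051,0.1431285043,0.1181507594
dsovers,whole_brain,6,0.3648397317,0.1424994984,0.1560926388,0.127448303
cbf_ssvd,whole_brain,5,0.3029687074,0.1739428913,0.1373284255,0.1190119329
ttp,whole_brain,3,0.2021601963,0.03578316074,0.0503605101,0.03351100055
mtt_ssvd,whole_brain,4,-0.1245880923,0.06243854649,0.02553509,0.02451730216
...
```

Reading it: at this noise level (SNR 20) the amplitude-driven maps (ΔS/S,
CBV-AUC, CBV-sSVD, CBF-sSVD) correlate with the final cell density at
ρ ≈ 0.30–0.36 and explain ~14–16% of its variance, while the timing maps
(TTP, MTT-sSVD) are weak or slightly negative — cells follow blood *volume
and flow*, not bolus *timing*. `n_animals` counts animals whose correlation
passed the significance filter (α = 0.05); `group_comparison.csv` shows no
FDR-significant intact-vs-stroke difference in any map, so the groups pool.

The same stages are available individually (`perfcell simulate`,
`perfcell perfusion`, `perfcell cells`, `perfcell correlate`) and as a
manifest-driven batch run:

```bash
perfcell simulate --out study --n-intact 3 --n-stroke 6 --coupling 0.6 --seed 7
perfcell run-all --manifest study/manifest.csv --out study_results
```

or from Python:

```python
from perfcell.phantom import generate_phantom, gamma_variate_aif, \
    AcquisitionParams, simulate_dynamic_series
from perfcell.perfusion import compute_all_maps

phantom = generate_phantom((32, 32, 12), seed=1)
acq = AcquisitionParams()                      # 220 frames, TR/TE 1500/15 ms
series = simulate_dynamic_series(phantom, gamma_variate_aif(acq), acq, seed=2)
maps, meta = compute_all_maps(series)          # eight 3D maps + provenance
```

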