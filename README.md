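# coilmelt

Quantitative biophysics of weak coiled-coil heterodimers — the kind formed
by the stalk domains of heteromeric kinesin-II motors, which melt near room
temperature and carry charged residues in the hydrophobic core positions of
their heptad repeats.

The package covers the four measurements such a study runs, each usable on
its own and wired together behind one CLI:

| stage | module | what it computes |
|---|---|---|
| far-UV CD | `coilmelt.cd` | mean residue molar ellipticity `[Θ] = θ/(10·C·l·N)`, the `[Θ]222/[Θ]208` coiled-coil index (helix ≈ 0.83, coiled coil ≈ 1.03), helix content from the chain-length formula `[Θ]222 = −40000·(1 − 4.6/n)` or by NNLS basis deconvolution |
| thermal unfolding | `coilmelt.melt` | two-state fit `Y₀(T) = (1−f_U)·N(T) + f_U·U(T)` with linear baselines, `ΔG(T) = −RT ln[f_U/(1−f_U)]`, and the Gibbs-Helmholtz stability curve `ΔG(T) = ΔH_m(1 − T/T_m) + ΔC_p[(T − T_m) − T ln(T/T_m)]`, giving T_m, ΔH_m, ΔC_p, the maximum-stability temperature `T_s = T_m·exp(−ΔH_m/(ΔC_p·T_m))` and ΔG at a reference temperature |
| sequence | `coilmelt.heptad` | heptad register (a–g) assignment and scanning, counts of charged residues at the a/d core positions, named stalk-segment slicing |
| ensembles | `coilmelt.ensemble` | Kabsch RMSD, per-residue RMSF, radius of gyration, Shrake-Rupley SASA split into hydrophobic/hydrophilic classes, salt bridges, interchain hydrophobic contacts, Cα-geometry helicity, distance timelines — from multi-model PDB files |

`coilmelt.simulate` generates every input with known ground truth (melts,
spectra, heptad sequences, ideal helices, Crick-parameterized coiled coils,
fluctuating ensembles), so the full pipeline is testable without any
external data.

## Worked example

Fit a melting curve (simulated here, so the truth is known: T_m = 297.6 K,
ΔH_m = 102.1 kJ/mol, ΔC_p = 0.5624 kJ/mol/K):

```python
from coilmelt import simulate as sim
from coilmelt.melt import TwoStateMeltModel

curve = sim.gen_melt_curve(sim.MeltGenerator())   # noiseless forward model
res = TwoStateMeltModel(curve).fit()
print(res.summary())
```

```
Two-state thermal unfolding fit
==============================================
Tm (K)                       297.600  +/- 0.017
dHm (kJ/mol)                 102.100  +/- 0.068
dCp (kJ/mol/K)                 0.562  +/- 0.007
Ts (K)                       161.691
dG(295 K) (kJ/mol)             0.886
----------------------------------------------
points: 171   clipped: 0   rmse: 0.0003258
```

T_m is the midpoint of the unfolding transition; ΔH_m the van't Hoff
enthalpy there; ΔC_p the heat-capacity change that curves the stability
parabola; T_s the temperature where the protein is most stable; and
ΔG(295 K) ≈ 0.9 kJ/mol says this heterodimer is only marginally folded just
below room temperature — the signature of a weak coiled coil. The same
analysis runs from the shell:

```bash
coilmelt simulate melt --seed 1 -o melt.csv
coilmelt melt melt.csv --tref 295 --window 288:334 -o report.json
```

Other entry points: `coilmelt spectrum`, `coilmelt heptad annotate|scan`,
`coilmelt ensemble report|bridges`, and `coilmelt run --config run.yaml` for
a multi-stage run whose JSON report embeds the full resolved configuration.

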