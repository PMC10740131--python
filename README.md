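# quenchbind

Analysis toolkit for protein–ligand interaction studies built on intrinsic
fluorescence quenching — the kind of experiment used to characterise how a
small flavour or drug molecule (e.g. hydroxy-α-sanshool, the numbing
compound of Sichuan pepper) binds to a protein such as the myofibrillar
muscle proteins. It is written for spectroscopists who have titration CSVs
and want the binding constants, thermodynamics and mechanism calls without
re-deriving the regressions in a spreadsheet.

## What it computes

Given fluorescence titrations F([Q]) at several temperatures:

* **Stern–Volmer** — F₀/F = 1 + K_sv[Q]; the bimolecular quenching rate
  constant K_q = K_sv/τ₀ (τ₀ ≈ 10⁻⁸ s for tryptophan);
* **Double-log** — log₁₀((F₀−F)/F) = log₁₀ K_a + n·log₁₀[Q], giving the
  apparent binding constant K_a and site number n;
* **Van't Hoff** — ln K_a = −ΔH/(RT) + ΔS/R, and ΔG = ΔH − TΔS per
  temperature;
* **Mechanism call** — K_sv rising with temperature ⇒ dynamic quenching;
  K_q above the diffusion-controlled limit 2×10¹⁰ M⁻¹s⁻¹ ⇒ static
  complexation; both ⇒ combined quenching;
* **Driving force** — Ross–Subramanian sign rules on (ΔH, ΔS):
  both negative ⇒ hydrogen bond / van der Waals, both positive ⇒
  hydrophobic, ΔH ≈ 0 ⇒ electrostatic.

Companion modules cover the assays that usually surround such a study:
emission-peak detection with red/blue-shift calls (`quenchbind.spectra`),
bromophenol-blue hydrophobicity, Ellman sulfhydryl and standard-curve
calculators plus the urea/thiourea force partition (`quenchbind.assays`),
far-UV CD secondary-structure deconvolution by constrained least squares
(`quenchbind.cd`), and trajectory geometry metrics — Kabsch RMSD, RMSF,
Shrake–Rupley SASA with hydrophobic/hydrophilic split, geometric
hydrogen-bond counts (`quenchbind.trajectory`). `quenchbind.synthetic`
generates every input with known ground truth, which is how the test
suite validates each stage.

## Worked example

Generate a synthetic dataset (K_sv = 750/1120/1460 M⁻¹ at 293/303/310 K,
1 % intensity noise) and fit it:

```
quenchbind synth -d demo --seed 7 --noise-sigma 0.01
quenchbind fit -m demo/manifest.yaml -o demo/report.json
```

prints

```
Quenching binding analysis
============================================================
                    293 K     303 K     310 K
Ksv (M^-1)          793.6      1086      1474
Kq (M^-1 s^-1)  7.936e+10 1.086e+11 1.474e+11
R1^2               0.9946    0.9961     0.997
...
Mechanism: combined (Ksv trend increasing; Kq exceeds diffusion limit 2.00e+10 M^-1 s^-1)
Driving force: hydrogen_bond_vdw (dH = -24.612 kJ/mol, dS = -0.0261 kJ/(mol K), Van't Hoff r^2 = 0.1197)
```

The fitted K_sv track the generating values to ~5 %; K_q sits above the
diffusion limit (static contribution) while K_sv still rises with
temperature (dynamic contribution), hence the *combined* call. With only
three temperatures the Van't Hoff line is poorly determined under noise —
the low r² here is the diagnostic telling you so.

The same workflow in Python:

```python
from quenchbind import QuenchingBindingModel, compute_gibbs
from quenchbind.io import model_from_manifest

res = model_from_manifest("demo/manifest.yaml").fit()
print(res.summary())
res.to_frame().to_csv("constants.csv")

compute_gibbs(-164.076, -0.501, [293, 303, 310])
# {293.0: -17.283, 303.0: -12.273, 310.0: -8.766}
```

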