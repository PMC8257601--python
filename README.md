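# littertrace

Analysis toolkit for **¹³C litter-tracing experiments in soil
microcosms**. When ¹³C-enriched plant litter (δ¹³C ≈ +2129 ‰ V-PDB) is
added to soil at natural abundance (δ¹³C ≈ −28 ‰), every downstream
carbon pool becomes a two-end-member isotope mixture, and the label can
be followed from respired CO₂ through physical organic-matter fractions
into microbial biomarkers and down to micrometre-scale ion images. This
package implements that whole chain for soil biogeochemists:

- **Respiration partitioning** — headspace CO₂ accumulations convert to
  hourly CO₂-C fluxes via the ideal-gas law; the δ¹³C of respired CO₂
  splits each flux into litter-derived and soil-derived shares

  $$\mathrm{CO_2\text{-}C_{litter}\,[\%]} =
    \frac{\delta^{13}C_{resp}-\delta^{13}C_{control}}
         {\delta^{13}C_{litter}-\delta^{13}C_{control}}\times 100$$

  and the **priming effect** is the extra native-soil CO₂-C released in
  litter treatments relative to paired controls.
- **Fraction accounting** — litter-derived C percentage and mass for
  each density/size fraction (fPOM, oPOM, oPOM_small, sand + coarse
  silt, MAOM), normalised per g bulk C, with mass/C recovery QA.
- **PLFA** — methanol-correction of FAME δ¹³C
  (δ¹³C_FA = ((Cₙ+1)·δ¹³C_FAME − δ¹³C_MeOH)/Cₙ), marker-group
  assignment (gram-negative, gram-positive, fungi, general bacteria),
  and two ¹³C-incorporation metrics: each group's share of total label
  uptake, and the labeled share within each group.
- **¹³C CP-MAS NMR** — chemical-shift region integration, the
  alkyl : O/N-alkyl aliphaticity ratio, and a **molecular mixing
  model** that unmixes region intensities into compound classes
  (carbohydrate, protein, lignin, lipid, carbonyl, char) by constrained
  least squares on the composition simplex.
- **NanoSIMS** — dead-time correction (non-paralyzable, τ = 44 ns),
  integer-pixel drift alignment, plane accumulation, and ROI isotope
  ratios ¹³C⁻/(¹²C⁻+¹³C⁻) and ¹²C¹⁴N⁻/(¹²C⁻+¹²C¹⁴N⁻) with Poisson
  standard errors.
- **Synthetic experiment generator** — forward-models every one of
  these inputs with recorded ground truth, so the full pipeline is
  testable without laboratory data.

## Worked example

Simulate the default 95-day, two-texture microcosm experiment and
partition the coarse-texture respiration:

```python
from littertrace import respiration, synthetic

cfg = synthetic.ScenarioConfig(master_seed=0)
gas, _ = synthetic.gen_respiration(cfg)
rc = synthetic.respiration_config(cfg, "coarse")

series = respiration.cumulate(
    respiration.process_gas_table(gas[gas.texture == "coarse"], rc), rc
)
litter = series[series.treatment == "litter"]
control = series[series.treatment == "control"]
end = litter.groupby("day")[
    ["cum_total_mg_gC", "cum_litter_mg_gC", "cum_soil_mg_gC"]
].mean().iloc[-1]
prime = respiration.priming(litter, control)
```

This prints:

```
total respired:   129.6 mg CO2-C / g C_bulk
litter-derived:   40.6  (31.3 %)
soil-derived:     89.0
priming effect:   23.1 mg CO2-C / g C_bulk
```

Over 95 days the litter contributed ~31 % of total respiration, and its
presence primed an extra 23 mg CO₂-C per g bulk C out of native soil
organic matter — the kind of numbers a real incubation of this design
produces. A molecular-mixing-model fit looks like:

```python
from littertrace import nmr, synthetic
comp = {"carbohydrate": 0.45, "protein": 0.12, "lignin": 0.28,
        "lipid": 0.08, "carbonyl": 0.05, "char": 0.02}
ppm, inten, _ = synthetic.gen_nmr(comp, seed=3, noise=0.01)
print(nmr.MolecularMixingModel.from_spectrum(ppm, inten).fit().summary())
```

```
Molecular mixing model fit
========================================
class           fraction   percent
carbohydrate      0.4500     45.0%
protein           0.1202     12.0%
lignin            0.2800     28.0%
lipid             0.0800      8.0%
carbonyl          0.0499      5.0%
char              0.0199      2.0%
----------------------------------------
residual norm (region fractions): 2.858e-05
```

The same operations are available from the shell:

```bash
littertrace simulate --seed 0 --out demo/
littertrace respire   --gas demo/gas.csv        --out out/resp/
littertrace fractions --table demo/fractions.csv --out out/frac/
littertrace plfa      --table demo/fame.csv      --out out/plfa/
littertrace nmr       --spectrum demo/nmr_fPOM_litter.txt --out out/nmr/
littertrace sims      --stacks demo/sims/ --rois demo/sims/ --out out/sims/
```

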