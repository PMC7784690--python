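# gpptkin

In-situ CH4 oxidation kinetics from gas push–pull tests (GPPTs), built
for the study design used on North Australian termite mounds: mounds
host methane-oxidising bacteria (methanotrophs, mostly upland soil
cluster α) that consume a large share of termite-produced CH4, and the
GPPT measures how fast — and with what substrate affinity — they do so
*in place*, without disturbing the mound.

A GPPT injects air spiked with ~900 µl l⁻¹ CH4 and ~0.1 l l⁻¹ argon
into the mound centre (24 min, ~0.5 l min⁻¹), then extracts from the
same point (36 min). Argon is a conservative tracer: it dilutes exactly
like CH4 but is not consumed, so the CH4 deficit beyond tracer dilution
is microbial oxidation. The package implements the full inference
chain, plus a synthetic-data generator with known ground truth so every
stage is verifiable by parameter recovery:

* **first-order activity coefficient** k (h⁻¹) from the slope of
  ln(C\*_CH4/C\*_Ar) against the plug-flow transformed reaction time t\*;
* **segment rates**: sliding 3-sample windows give local activities and
  running-average concentrations C̄, hence rates R_ox = k_local·C̄;
* **Michaelis–Menten fit** R_ox = V_max·C/(K_m + C) with AIC selection
  against a linear (no-saturation) null, per mound and pooled across
  mounds;
* **abundance conversions**: qPCR standard curves → gene copies g⁻¹ →
  cells g⁻¹ (2 *pmoA* copies per cell, 4.2 16S copies per cell),
  metagenomic RPKM fractions against 14 single-copy ribosomal markers,
  ASV-table fractions, and cell-specific rates (mol CH4 cell⁻¹ h⁻¹);
* **statistics**: transformed regressions with Cook's-distance outlier
  screening, AIC backward stepwise elimination, Kruskal–Wallis + Dunn
  tests with compact letter displays.

See `docs/methods.md` for the model, its assumptions and known
numerical properties.

## Worked example

Simulate one mound whose community has the pooled field kinetics
(K_m = 13.2 µmol l⁻¹, V_max = 55.4 µmol l⁻¹ h⁻¹) with realistic
measurement noise, then run the estimator:

```python
import gpptkin as g

cfg = g.SimConfig(kinetics=g.MichaelisMenten(km=13.2, vmax=55.4),
                  noise_ch4=0.02, noise_ar=0.02, n_ar_ext=12,
                  seed=1, mound_id="demo")
res = g.GpptKinetics(g.simulate_gppt(cfg)).fit()
print(res.summary())
```

```
GPPT kinetic fit — mound demo
======================================================
activity k            3.1630 ± 0.1282 h⁻¹  (r²=0.9838, n=12)
segments                  10
selected model    michaelis_menten  (AIC MM=12.39, linear=30.44)
Km                    14.728 ± 3.10 µmol l⁻¹
Vmax                  59.310 ± 6.78 µmol l⁻¹ h⁻¹
```

Reading the output: the log-ratio regression over the 12 tracer-matched
extraction samples gives an overall first-order activity of ~3.2 h⁻¹
(r² = 0.98 — CH4 is clearly being consumed beyond dilution). The ten
sliding-window segments span ~1–22 µmol l⁻¹, enough concentration range
for the AIC to prefer saturation kinetics over a straight line, and the
recovered (K_m, V_max) = (14.7, 59.3) sit within one standard error of
the simulated truth (13.2, 55.4). Converting units: the 900 µl l⁻¹
injectate is 36.8 µmol (l air)⁻¹ at 25 °C, so this community
half-saturates at roughly a third of the injected concentration — the
"medium affinity" regime, well above the nanomolar affinities of upland
soils.

Downstream, `g.pooled_fit([...])` combines segment pairs across mounds,
and `g.cell_specific_rate(rate, dry_mass, copies_per_g)` turns a
whole-mound rate plus a *pmoA* inventory into mol CH4 cell⁻¹ h⁻¹, e.g.
10 µmol h⁻¹ over 10⁴ g at 2×10⁶ copies g⁻¹ → 1×10⁻¹⁵ mol cell⁻¹ h⁻¹.

The same pipeline is scriptable from the shell:

```bash
gpptkin simulate --out data/ --n-mounds 6 --kinetics population --seed 3
gpptkin fit      --data-dir data/ --out fits/
gpptkin pool     --data-dir data/ --out pooled/
gpptkin all      --out run/ --n-mounds 8 --seed 5   # simulate→fit→pool→correlate
```

Every output directory carries a `manifest.json` with the config hash
and seed; identical inputs reproduce byte-identical results.

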