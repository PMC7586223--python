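# cbhkin

Single-molecule kinetics of cellobiohydrolases on crystalline cellulose:
a simulation and analysis toolkit.

Cellobiohydrolases (CBHs) bind to crystalline cellulose microfibrils,
thread a chain end into their substrate-binding tunnel and slide along the
fibril, releasing one cellobiose (~1 nm of chain) per catalytic step.
Single-molecule TIRF movies of fluorescently labeled enzyme resolve the
elementary steps that bulk assays average away: the binding rate constant
per fibril, two distinct dissociation modes (attributed to the hydrophilic
vs hydrophobic crystal faces), the translational rate of processive
sliders vs surface diffusers, and — combining them — processivity and the
fraction of molecules that are productively bound. `cbhkin` implements
that analysis chain for event tables and localized trajectories (CSV),
together with a synthetic-experiment simulator with known ground truth so
every estimator has a parameter-recovery test.

## The quantities

* **Binding rate constant** per fibril:
  `k_on = N / (C · L · T · r)` with `N` bound molecules, `C` enzyme
  concentration (M), `L` fibril length (μm), `T` observation time (s) and
  `r` the dye-labeling ratio; units M⁻¹ μm⁻¹ s⁻¹. Microfibrils are bundles,
  so the per-fibril `k_on` histogram shows one Gaussian peak per bundle
  count; the smallest peak is the single-bundle `k_on`.
* **Dissociation**: binding-time histograms are fitted with
  `y(t) = A_f e^(−k_f t) + A_s e^(−k_s t)`; each mode's share of events is
  its area fraction `f_i ∝ A_i / k_i`. Photobleaching (rate `k_b`) competes
  with dissociation and can optionally be subtracted.
* **Split rate constants and affinities**: `k_on,i = k_on · f_i` and
  `K_d,i = k_off,i / k_on,i` (M μm).
* **Motility**: per track, `k_tr` = first-to-last displacement / moving
  time; the `k_tr` histogram separates slow processive sliding from fast
  apparent surface diffusion. Moving times follow a single-exponential
  decay with time constant τ.
* **Processivity** `= k_tr,slow · τ / 1.0 nm` cellobiose units per run, and
  the per-molecule hydrolytic rate `k_tr,slow / 1.0 nm` (s⁻¹); comparing
  the latter with the bulk `k_cat` (Michaelis–Menten fit) gives the
  productively bound fraction.

## Worked example

Derived kinetics for the full-length enzyme (Intact) and its catalytic
domain (CD), from the measured totals and mode fractions:

```python
from cbhkin import presets, summary, motility

rows, rendered = summary.build_kinetic_table(
    {k: presets.TABLE1[k] for k in ("Intact", "CD")}
)
print(rendered.to_string(index=False))
```

```
construct component   kon_total  koff  fraction_pct  kon_component           Kd
   Intact      fast 430000000.0 0.850            33    140000000.0 6.000000e-09
   Intact      slow 430000000.0 0.086            67    290000000.0 3.000000e-10
       CD      fast  17000000.0 1.700            81     14000000.0 1.200000e-07
       CD      slow  17000000.0 0.130            19      3200000.0 4.000000e-08
```

The slow (productive-face) mode of the intact enzyme has the highest
affinity, `K_d,slow = 3.0e-10 M μm`; the isolated catalytic domain loses
binding almost entirely (`K_d,slow` 133× higher, computed from the
2-significant-figure rendered values).

```python
p = motility.processivity(11.6, 4.6)        # slow k_tr peak x moving time
print(p.value, p.rounded)                   # 53.36 53
frac = summary.productive_fraction(2.4, 11.6)
print(round(frac, 3))                       # 0.207
```

A processive run of ~53 cellobiose units, and a bulk turnover of 2.4 s⁻¹
against a single-molecule rate of 11.6 s⁻¹, i.e. only ~20% of molecules
are productively bound.

Synthetic experiments run from the CLI:

```
cbhkin simulate --config sim.yaml --seed 1 --out-dir data/
cbhkin kon  --events data/events.csv --fibrils data/fibrils.csv \
            --enzyme-conc 2e-10 --duration 400
cbhkin koff --events data/events.csv --duration 400 --components auto
cbhkin motion --trajectories data/trajectories.csv
cbhkin run --config pipeline.yaml --out-dir report/
```

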