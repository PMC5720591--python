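# mcmflow

Quantitative analysis of DNA-replication **origin licensing** from fixed-cell
flow cytometry.  Before a human cell can replicate its genome it must load
MCM2-7 helicase complexes onto DNA during G1 ("licensing").  Chromatin flow
cytometry — detergent extraction of soluble protein followed by anti-MCM
immunostaining, EdU labelling and DAPI — yields a single-cell snapshot of
loaded MCM across an asynchronous population.  `mcmflow` turns such snapshots
into *loading rates*: it gates the events, estimates population growth, and
applies ergodic rate analysis to the G1 subpopulation.  It is aimed at cell
cycle and stem-cell labs comparing licensing dynamics between cell states
(pluripotent vs differentiated, perturbed vs control).

## The method

For an asynchronous population in steady-state exponential growth
(α = ln 2 / T_d), cell age has density 2αe^(−αa): newborns are twice as
frequent as dividing cells.  Loaded MCM increases unidirectionally through
G1, so the density of G1 cells along the MCM axis is inversely proportional
to the speed at which they pass each level — a traffic-jam argument: few
cars at a spot on the road means traffic is moving fast there.  Binning the
G1-MCM⁺ intensities into 10 equal-width bins spanning the sample's own
min–max range, the per-bin loading rate is

```
w_n = α (2 − F) / f_n
```

where `F` is the G1-MCM⁺ fraction of all cells in the sample and `f_n` the
fraction of G1-MCM⁺ cells in bin *n*; the per-sample statistic is the mean
of the ten `w_n` (per hour, on the normalised 10-bin axis).  Because bins
are re-derived per sample, the statistic is invariant to gain/offset changes
of the intensity axis — rates are **relative** quantities, comparable only
between samples stained and acquired together.  A `cumulative_era` mode
implements the textbook flux-conservation form (v(x) = α(2 − Φ(x))/p(x),
intensity-units per hour) for methodological comparison.

The package also provides:

* **simdata** — a generative simulator: steady-state ages, linear G1
  loading to a licensing target M_max (with or without a licensing
  checkpoint), linear S-phase unloading, EdU tied to licensing at S entry,
  log-normal channel noise, antibody background, doublets, growth-curve
  counts, and preset populations (hESC-, NPC-, iPSC-, RPE-like, and a
  Cyclin-E-overproduction scenario pair).
* **gating** — negative-control quantile thresholds, G1 DAPI peak finding,
  the scatter/singlet gate hierarchy, the three-class phase taxonomy
  (G1-MCM⁺ / S-MCM⁺ / MCM⁻ G1-G2-M), early-S calls and the S-phase
  MCM-high/low split.
* **growth** — log-linear doubling-time regression and phase-duration
  arithmetic.
* **diffscore** — per-cell Cdx2/Oct4 differentiation scores from
  image-quantification tables, capped histograms, Mann-Whitney comparisons.
* **flow_io** — CSV and FCS 3.0/3.1 event tables with semantic channel
  mapping.
* a CLI (`mcmflow`) and a YAML-config pipeline with provenance logging.

## Worked example

Simulate a fast-loading pluripotent-like line (17 h cycle, 2.55 h G1) and a
slow-loading differentiated-like line (30 h cycle, 13.5 h G1), each with its
matched no-primary-antibody control, then run ergodic rate analysis:

```bash
mcmflow simulate --preset hesc --n 20000 --seed 1 --out hesc.csv --control-out hesc_ctrl.csv
mcmflow simulate --preset npc  --n 20000 --seed 2 --out npc.csv  --control-out npc_ctrl.csv
mcmflow era run --events hesc.csv --control hesc_ctrl.csv --doubling-time 17
mcmflow era run --events npc.csv  --control npc_ctrl.csv  --doubling-time 30
```

prints

```
mean MCM loading rate: 29.4453 per hour (F=0.1837, n_G1=3454)
mean MCM loading rate: 2.5717 per hour (F=0.4927, n_G1=9263)
```

The fast loader's G1 cells are concentrated at high loaded-MCM levels, so
its low-MCM bins are sparse and the mean w_n is large; the slow loader's G1
cells spread across the whole axis and its rate is low.  The ratio (here
~11 on one simulated draw) is the relative licensing rate; with the min–max
binning convention it is sensitive to sparse outlying bins, so replicate
samples and group means (`mcmflow era compare`) are the unit of inference.
`F` is the G1-MCM⁺ fraction of each sample and `n_G1` the number of G1-MCM⁺
cells the histogram is built from.

The same analysis runs as a library:

```python
import mcmflow as mf

model = mf.model_hesc()
sample = mf.simulate_sample(model, mf.NoiseModel(), 20_000, seed=1)
control = mf.simulate_negative_control(model, mf.NoiseModel(), 10_000, seed=2)
calls = mf.classify_phases(sample.events, mf.derive_thresholds(control))
result = mf.run_era(sample.events, calls, model.alpha)
print(result.mean_rate, result.F)
```

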