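# ritpipe

Analysis pipeline for preclinical tissue-targeted radioimmunotherapy studies:

1. **Biodistribution** (`ritpipe.biodist`) — ingest per-animal %ID/g tables,
   normalize to a 20 g reference body weight, and summarize per-(group, organ)
   time–activity curves (mean ± sample SD, n per time point).
2. **Dosimetry** (`ritpipe.dosimetry`) — convert an imaging-surrogate
   time–activity curve into predicted absorbed dose (Gy) per organ for a
   substituted therapy nuclide: each linear segment of f(t)·e^(−λt) is
   integrated in closed form, Ã = A₀·10·∫f(t)e^(−λt)dt, and D = Δ·Ã with Δ
   the mean energy emitted per transition. Tail and t = 0 behaviour are
   explicit options (`tail_mode`: physical / terminal_slope / truncate;
   `t0_mode`: zero / hold_first / auto).
3. **Nuclides** (`ritpipe.nuclides`) — registry of physical constants
   (In-111: t½ = 67.4 h; Y-90: t½ = 64.1 h, Δ = 1.495e-13 Gy·kg/(Bq·s)),
   extensible from configuration.
4. **Therapy outcomes** (`ritpipe.therapy`) — caliper volumes
   (length × width²/2 after canonicalization), normalized growth curves,
   humane-endpoint detection (12 mm diameter default), product-limit
   survival curves, body-weight changes.
5. **Synthetic cohorts** (`ritpipe.synthetic`) — generators for
   biodistribution (peaked uptake–clearance kinetics per organ, bi-exponential
   blood, lognormal inter-animal variability, transient early-uptake
   multiplier arm) and therapy (exponential regrowth after a dose-proportional
   growth delay), plus a bi-exponential curve fitter. Everything downstream is
   testable without external data.
6. **CLI / orchestration** (`ritpipe.cli`, `ritpipe.pipeline`,
   `ritpipe.config`) — reproducible end-to-end runs driven by a YAML config
   and a master seed; identical (config, seed) runs are byte-identical.

## CLI

```bash
# synthetic biodistribution cohort
ritpipe simulate-biodist --out runs/bd --seed 1

# dose table from a measured table (columns: animal_id, group, organ,
# time_h, percent_id_per_g, body_weight_g)
ritpipe dose-table --input biodist.csv --out runs/dose \
    --activity-mbq 0.925 --activity-mbq 1.85 --activity-mbq 3.7

# therapy outcomes from a caliper table (animal_id, group, day,
# length_mm, width_mm), optional body-weight table
ritpipe therapy-analyze --input calipers.csv --weights weights.csv --out runs/tx

# full simulated study: biodistribution -> dose table -> therapy arms
# driven by the predicted tumor doses
ritpipe full-run --config run.yaml --seed 1 --out runs/full
```

Each run writes delimited-text artifacts plus a `manifest.json` recording the
config hash, seed, package version and every dosimetry assumption used.

Example `run.yaml`:

```yaml
seed: 1
activities_bq: [0.925e6, 1.85e6, 3.7e6]
tail_mode: physical      # physical | terminal_slope | truncate
t0_mode: auto            # zero | hold_first | auto
synthetic:
  n_per_group: 5
  noise_cv: 0.3
  sqap_multiplier: 1.4
```

## Notes on dosimetry assumptions

Measured %ID/g values are assumed decay-corrected, so the therapy nuclide's
physical decay is applied inside the integral; biological kinetics of the
imaging conjugate are assumed to transfer to the therapy conjugate. Dose is
self-dose only (no crossfire / remainder-body term). Group-level doses
integrate the group-mean curve; a per-animal mode is available. Report tables
are rounded to 0.1 Gy at serialization only; the long-format table keeps full
precision and round-trips.
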