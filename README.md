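# tfusim

Multiscale simulation of transcranial focused-ultrasound (tFUS)
neurostimulation: a 2D linear-acoustics model of a simplified human head
(water / skull annulus / brain disc, curved 250 kHz transducer) coupled to an
intramembrane-cavitation point neuron (bilayer-sonophore mechanics +
regular-spiking Hodgkin–Huxley membrane driven through cycle-averaged
effective variables).

The pipeline sweeps skull thickness (5.4 / 7.6 / 10.5 mm) and duty cycle
(40–90 %), produces maximum-pressure and time-averaged-intensity field maps,
samples the focal region at 15 positions, and reports spike latency and firing
rate of a point neuron placed at each position.

## Layout

| module | contents |
| --- | --- |
| `tfusim.head_model` | head geometry, media property rasters, transducer source |
| `tfusim.acoustic_solver` | staggered-grid FDTD with split-field PML, power-law absorption, field maps, free-water safety calibration |
| `tfusim.sonophore_neuron` | sonophore mechanics (modified Rayleigh–Plesset + gas exchange), deflection-dependent capacitance, effective-variable lookup tables, fast (SONIC-style) and brute-force (full co-integration) neuron simulators, spike metrics |
| `tfusim.coupling_pipeline` | macro→micro orchestration, ROI sampling, response records and summaries |
| `tfusim.io_cli` | YAML config, fixtures, CSV/HDF5 outputs, manifest, CLI |

## CLI

```bash
# one acoustic solve (field maps + per-region summary)
tfusim simulate-macro --skull-mm 5.4 --dc 0.9 --out results/

# free-water calibration run
tfusim simulate-macro --free-water --dc 0.9 --out results/

# build and persist the effective-variable lookup table
tfusim build-table --pa-max-kpa 150 --out lookup.h5

# drive the point neuron at one pressure amplitude
tfusim simulate-neuron --pa-kpa 80 --dc 0.6 --prf-hz 500 --duration-ms 100 --table lookup.h5

# the full multiscale sweep (records.csv, summary.csv, manifest.json)
tfusim run-multiscale --config configs/default.yaml --out results/

# figures from a records file
tfusim report --records results/records.csv --out figures/
```

Every subcommand accepts `--dry-run` (validate configuration only) and
`--config FILE`; `configs/default.yaml` is the annotated default and an empty
config file behaves identically. Units are encoded in key names
(`dx_mm`, `amplitude_kpa`, …).

At full resolution (561×561 at 0.5 mm) one acoustic solve takes ~10–15 s and
the complete 18-condition sweep, including the lookup-table build, runs in
roughly 10 minutes on one CPU.

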