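# holomass

Detecting a ~4 h ultradian rhythm in single-cell dry mass, the way a
lens-free holographic microscope does it — implemented end to end on
synthetic data with known ground truth.

Label-free quantitative phase imaging can weigh single adherent cells:
the optical phase delay φ(x, y) of light crossing a cell is proportional
to the dry matter along the path,

    OPD(x, y) = λ · φ_shift(x, y) / 2π          (optical path difference, µm)
    OVD       = ∫_S OPD dx dy                   (optical volume, µm³)
    CDM       = OVD / α,  α = 0.18 µm³ pg⁻¹     (cell dry mass, pg)

Following thousands of unsynchronized cells every 5 minutes for days
reveals that the dry mass of each cell carries, on top of its linear
growth, a weak pulse train: symmetric ~30 min (FWHM) pulses of ~100 pg
every ~4.17 h (0.004 min⁻¹). Per cell the pulses drown in 1/f
biological noise and ~35 pg measurement noise; they emerge only in
cohort statistics — the averaged absolute Fourier amplitude over
hundreds of cells.

`holomass` implements the full chain and the synthetic ground truth to
exercise it:

* **synthetic** — dry-mass trace generator (linear growth + pulse train
  + 1/f noise + white noise), asynchronous cohorts with lognormal cycle
  lengths and division events, optical cell phantoms and simulated
  inline holograms, time-lapse scenes with moving, dividing cells, and
  negative controls (residual shuffling, fixed cells).
* **holography** — Fresnel propagation (angular-spectrum transfer
  function) and phase retrieval from intensity-only holograms by
  minimizing a smoothed total-variation criterion with nonlinear
  conjugate gradients (Hestenes–Stiefel, 15 iterations, ε = 10⁻⁴),
  plus the negative-region unwrapping heuristic.
* **segtrack** — Laplacian-of-Gaussian cell detection (blob diameter
  15 px, threshold 0.7), seeded region growing with watershed splitting,
  LAP frame-to-frame linking with gap closing (15 px, ≤ 5 frames,
  ≥ 10 spots), and division calling from abrupt mass drops coinciding
  with new-track births.
* **drymass** — phase → OPD → OVD → dry mass conversion, including the
  ~1/0.65 correction for the signal reduction of the sparsity-
  constrained retrieval, and per-track interphase trace assembly.
* **spectral** — per-cell sine-windowed Fourier transforms on the
  oversampled grid df(j) = 1/(T(j)·M), M = 25; cohort bin averaging on
  the grid of the longest trace; 1/f background fitting; harmonic-comb
  identification of the fundamental; inverse-FT waveform reconstruction
  (two sign solutions); oscillator-strength (AF) dose–response readout.
* **pipeline / CLI** — traces-only and full-imaging orchestration with
  YAML configs, manifests and CSV/TIFF/JSON/PNG artifacts.

## Worked example

Generate a default 300-cell cohort (5-min sampling over one interphase
each, 100 pg pulses every 250 min injected at random phases) and run
the cohort Fourier analysis:

```python
from holomass import spectral, synthetic

traces, truth = synthetic.generate_cohort(synthetic.CohortConfig(n_cells=300, seed=1))
spectra = spectral.compute_cell_spectra(traces)
cohort  = spectral.average_spectra(spectra)
report  = spectral.find_fundamental(cohort)
spikes  = spectral.measure_spikes(spectral.inverse_reconstruct(report))
```

This prints (via the snippet in `scripts/acceptance.py`-style reporting):

```
cells analyzed:      300
fundamental f0:      0.00401 per min  (period 4.16 h)
significance:        5.2  detected: True
harmonic amplitudes: [23.3 18.7 16.3 11.4  7.6  3.4] pg
inter-spike interval 4.15 h
spike FWHM           32 min
spike amplitude      95 pg
```

The detected fundamental sits at 0.004 min⁻¹; the inverse Fourier
reconstruction (harmonics above the 1/f background, cosine-aligned, so
exactly two sign solutions) shows periodic symmetric spikes every
~4.17 h, ~30 min wide, recovering the injected 100 pg amplitude. With
the rhythm amplitude set to zero, or with residual-shuffled controls,
no significant peak is found; the peak emerges only when more than
about a hundred cells are pooled.

The same chain runs from the shell:

```bash
holomass simulate --seed 1 --outdir run/
holomass spectrum run/traces.csv --outdir run/
holomass run --config config.yaml        # incl. full-imaging mode
```

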