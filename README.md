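# cochleametrics

Quantitative machinery for studying metabolic (lateral-wall) hearing loss in
the cochlea: how a failing stria vascularis lowers inner-ear calcium, detaches
the tectorial membrane (TM) from stereocilia, contracts the organ of Corti
(OoC), and degrades sound-evoked responses.  The package implements the full
measurement pipeline on which such a study rests, exercised end to end on
synthetic data with known ground truth:

* **FCS** (`cochleametrics.fcs`) — autocorrelation of photon-count traces from
  a confocal detection volume, fits of the 3-D anomalous-diffusion model

  ```
  G(t) = (1/N) · [1 + (t/τ_D)^α]⁻¹ · [1 + (t/τ_D)^α / S²]^(−1/2)
  ```

  (N molecules in the volume, dwell time τ_D, anomaly exponent α, aspect ratio
  S, optional triplet factor), and molecular brightness — the
  background-corrected count rate per molecule, a proxy for free calcium via a
  calcium-sensitive indicator.
* **Morphometry** (`cochleametrics.morphometry`) — TM/OoC ROI areas by pixel
  counting, the shortest TM-to-reticular-lamina distance (the "gap"), organ
  width, per-cochlea averaging, and detachment flagging.
* **Kinematics** (`cochleametrics.kinematics`) — reconstruction of
  phase-stamped confocal pixel streams into one frame per stimulus phase,
  per-pixel subpixel optical flow, 5×5 region averaging, and stereocilia
  deflection as the tip-minus-base trajectory difference.
* **Evoked potentials** (`cochleametrics.evoked`) — band-pass + averaging of
  tone-burst epochs, input–output functions and thresholds, cochlear
  microphonic (CM) amplitude/phase, summating potential (SP), tuning curves,
  and DPOAE (2f1−f2) extraction.
* **Statistics** (`cochleametrics.stats`) — compound-symmetry GLS for
  brightness ~ dose + site with within-animal correlation, one-way ANOVA with
  Tukey–Kramer post-hocs, rank tests, and OLS of hearing threshold on age and
  gap.
* **Synthetic data** (`cochleametrics.synthgen`) — photon emission from
  (fractional) Brownian tracers in a 3-D Gaussian volume at ~100 kHz count
  rates, section phantoms with controllable gaps, phase-stamped motion
  phantoms, evoked waveforms, and correlated brightness tables.

## Worked example

```python
from cochleametrics import fcs
from cochleametrics.synthgen import FcsSimConfig, simulate_photon_trace

traces = [simulate_photon_trace(FcsSimConfig(seed=r)) for r in range(6)]
res = fcs.fit_preparation(traces)          # correlate, average, fit
fit, bright = res["fit"], res["brightness"]
print(f"N = {fit.N:.2f}, tau_D = {1e3*fit.tau_D:.1f} ms, "
      f"brightness = {bright.brightness:.0f} photons/s/molecule")
```

prints (seed-exact):

```
N = 4.68, tau_D = 20.7 ms, brightness = 1815 photons/s/molecule
```

against a simulated ground truth of N = 4.97 molecules in the detection
volume, τ_D = 22.5 ms and an apparent brightness of 1773 photons/s/molecule —
i.e. the pipeline recovers the number of indicator molecules, their dwell
time, and the per-molecule count rate from nothing but the photon counts.

The numbered drivers under `analysis/` run each stage of the study on
synthetic cohorts and write tidy tables to `results/`:

```bash
python analysis/01_fcs_calcium.py       # site profiles + GLS dose effect
python analysis/02_morphometry.py      # width/gap cohorts, ANOVA + Tukey
python analysis/03_stereocilia_motion.py
python analysis/04_evoked_potentials.py
python analysis/05_human_regression.py
```

For example, stage 2 prints group detachment rates of 0/30 (controls), 1/19
(5%) and 8/22 (36%), and a control-vs-high organ-width difference of ~30 µm
(programmed 29 µm, Tukey–Kramer CI ≈ 24–37 µm); stage 3 recovers a 32-nm
bundle deflection from a base moving 64 nm (healthy pattern) and shows that a
130-nm base with a near-parallel 110-nm tip produces only a ~23-nm deflection
(contracted-organ pattern).

There is also a thin CLI over the same functions
(`cochleametrics simulate|fcs|morph|motion|ephys|stats|run`, see `--help`).

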