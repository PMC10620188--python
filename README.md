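# smsers

Single-molecule SERS spectral analysis toolkit: synthetic spectrum
generation, Savitzky–Golay preprocessing, 3σ rare-event detection with
bi-analyte (two-dye) event classification, amide-I second-derivative
secondary-structure markers for amylin (hIAPP) conformational species, and
the supporting acid–base / optical-trapping calculations.

## What it does

* **`smsers.core`** — spectral domain types (uniform ascending wavenumber
  axis, spectrum, spectrum set) and plain-text I/O: two-column spectra,
  multi-spectrum matrices (first column = wavenumber), JSON reports.
* **`smsers.synth` / `smsers.templates`** — analytic band templates
  (Lorentzian / Gaussian / pseudo-Voigt) for the reporter dyes (NBA, MB),
  tyrosine charge states, and hIAPP species; renders spectra with additive
  white noise, polynomial baseline and shot-to-shot intensity variation;
  simulates sparse bi-analyte event sets, trap on/off switching series and
  conformational-species sets. Fully seeded, no global random state.
* **`smsers.preprocess`** — background subtraction, Savitzky–Golay
  smoothing and second derivatives, quiet-region noise estimation.
* **`smsers.events`** — band detection against the k·σ rule (default 3σ
  with a 3-consecutive-point multiplicity control), bi-analyte event
  classification (single-MB / single-NBA / dual), event statistics and
  on/off switching reproducibility (RSD).
* **`smsers.markers`** — amide-I band centres from −d²I/dν² (1550–1750
  cm⁻¹), tyrosine Fermi-doublet ratio I830/I854, ν8a position, disulfide
  conformation markers (523 vs 490 cm⁻¹), and the conformational-species
  decision table with census/mapping.
* **`smsers.chemphys`** — Henderson–Hasselbalch net charge and microstate
  weights, strong acid/base mixing pH, vibrational frequency scaling
  (least-squares factor fit and application), Clausius–Mossotti
  polarizability and Rayleigh-regime gradient force/trapping potential with
  a 10 k_BT stability criterion.
* **`smsers.pipeline` / `smsers.cli`** — reproducible end-to-end scenario
  runs with YAML configs and scenario presets.

## Command line

```sh
smsers simulate --scenario biasers --seed 1 --n 3600 --out out/
smsers classify out/spectra.tsv --out labels.csv
smsers hiapp-classify out/spectra.tsv --out calls.csv --census census.json
smsers preprocess out/spectra.tsv --out processed.tsv --noise-report noise.json
smsers charge --ph 7.4
smsers titrate --v-acid 13 --ph-acid 1.0 --v-base 0.65 --c-base 2.0
smsers scale-freqs 1656 830 --factor 0.977
smsers trap --e0-sq 7.5e13 --radius-nm 35
smsers run --scenario hiapp --seed 1 --out out/
```

Exit codes: 0 success, 2 configuration error, 3 data error.

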