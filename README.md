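# revcor

Simulated yes/no detection experiments in truncated Gaussian pixel noise and
the full reverse-correlation (classification-image) analysis pipeline:

* **stimuli** — contrast-image rendering of a central dot plus surrounding
  inducer disks, display geometry (pixel ↔ degree), contrast-energy
  bookkeeping, ±2 sd truncated noise.
* **observers** — ideal (likelihood-ratio) observer, CSF-limited ideal
  observer (band-pass filtering of signal and templates in the frequency
  domain), and a linear-template observer with internal noise as a synthetic
  human stand-in.
* **experiment** — 2-down/1-up staircase over contrast energy, Weibull
  psychometric fits, 71%-correct threshold interpolation, bootstrap errors,
  Monte-Carlo ideal thresholds, efficiency.
* **classification** — stimulus–response cell-mean classification images,
  7×7 smoothing, inducer in-fill for display, 99-bin radial profiles,
  annularly binned power spectra, bootstrap bands, random-noise null bands.
* **hotelling** — one- and two-sample Hotelling T² on response-signed radial
  trial vectors with exact F conversions.
* **synthetic** — one-command generation of complete reproducible runs
  (HDF5 + CSV archives) and the canonical benchmark suite.
* **reporting** — tables and figures (thresholds, efficiency, image panels,
  profile plots with ±2 sd bands, Hotelling tables) from run archives.

## CLI

```sh
revcor simulate --observer ideal --condition small --trials 10000 --seed 7 --out runs/ideal_small.h5
revcor simulate --observer csf_ideal --condition large --trials 10000 --seed 8 --out runs/csf_large.h5
revcor classify --run runs/ideal_small.h5 --boot 500 --null 200 --out results/
revcor stats --run runs/ideal_small.h5 --vs runs/csf_large.h5 --out results/table.csv
revcor synth --scenario benchmark --trials 10000 --seed 7 --out runs/
revcor report --runs runs/ --out report/
```

## Notes

* Run archives always store per-trial radial noise vectors and per-cell
  pixel sums, so radial/spectral/Hotelling analyses never need the full
  noise fields; pass `store_fields=True` (or `--store-fields`) to keep the
  raw fields for image-level resampling of arbitrary trial subsets.
* All randomness is driven by explicit seeds; re-running any configured
  simulation reproduces its archive bit-for-bit.
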