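# imsair

GC-IMS (gas chromatography – ion mobility spectrometry) analysis pipeline
for indoor-air VOC profiling: synthetic spectrum and study simulation, 2D
peak detection, reference-library compound identification, ion-mobility
constants, and outdoor-normalized relative-intensity profiles.

A GC-IMS measurement is an intensity grid over drift time (ms) and
retention time (s).  The reactant ion peak (RIP) forms a ridge at a fixed
drift time (4.889 ms on the default device); analyte coordinates are
expressed as RIP-relative drift times so identification is robust to
instrument drift.  The package ships a 31-entry reference library
(20 compound groups, 23 identified entries covering 13 distinct VOCs)
and a study design of 16 sampling locations (15 indoor + 1 outdoor
baseline) with 31 replicate measurements each.

## Layout

| module               | role                                                    |
|----------------------|---------------------------------------------------------|
| `imsair.core`        | domain types, mobility arithmetic (v_d, K, K0), CSV I/O |
| `imsair.library`     | reference library entries + packaged TSV                |
| `imsair.simulate`    | synthetic spectra and multi-location studies            |
| `imsair.detect`      | 2D peak picking, RIP handling, replicate consensus      |
| `imsair.identify`    | tolerance matching against the library                  |
| `imsair.profiles`    | outdoor-normalized profiles, stability, radar charts    |
| `imsair.cli`         | `imsair` command-line pipeline                          |

## CLI

```sh
# simulate a study (writes location__repNN.csv + ground-truth manifest)
imsair simulate --outdir scratch/study --seed 1

# full pipeline: peaks -> identities -> profiles -> summary.json
imsair report --spectra-dir scratch/study --outdir scratch/out --figures

# individual stages
imsair detect   --spectra-dir scratch/study --outdir scratch/peaks
imsair identify --peaks scratch/peaks/outdoor__rep00__peaks.csv --out idents.csv
imsair profile  --spectra-dir scratch/study --outdir scratch/out
```

All stages accept `--config config.yaml` (device, grid, design, detection,
matching sections; everything defaults) and `--library` to override the
packaged reference TSV.  A fixed seed makes every output byte-identical
across runs.

## Python API sketch

```python
from imsair import (
    ReferenceLibrary, generate_spectrum, detect_peaks,
    match_peaks, summarize_identifications, specs_from_library,
)

library = ReferenceLibrary.load_default()
spectrum = generate_spectrum(specs_from_library(library), noise_sd=0.01, seed=0)
peaks = [p for p in detect_peaks(spectrum) if not p.is_rip]
idents = match_peaks(peaks, library.named())
print(summarize_identifications(idents))   # 31 detected, 23 identified, 13 VOCs
```

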