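# retinatune

Analysis pipeline for graded opsin co-expression across a butterfly
retina. The package converts intracellular voltage recordings into
spectral and polarization sensitivities (reverse Hill transformation),
decomposes red-inhibited photoreceptor sensitivities into a non-negative
sum of two rhodopsin absorbance templates (445 + 545 nm) with ratio-based
cell classification and dorso-ventral gradient statistics, types
ommatidia from immunolabel tables into the 15-type mosaic space with
strip-density profiles, and classifies hyperspectral eyeshine stacks into
red / non-red / dark ommatidia with dorso-ventral fraction profiles. A
seeded synthetic-data generator emulates all three data modalities with
known ground truth, so every stage is testable offline.

## Modules

| module | purpose |
| --- | --- |
| `retinatune.templates` | Govardovskii-family A1 absorbance templates, spectral-sensitivity composition |
| `retinatune.ephys` | Hill (Naka–Rushton) fits, reverse-Hill inversion, polarization typing, opponent-unit isolation under chromatic adaptation |
| `retinatune.decomposition` | two-template NNLS fit, A445/A545 ratio classification, UV-peak exclusion, elevation gradient statistics |
| `retinatune.mosaic` | cell-state calling, ommatidial typing/categorisation, strip densities |
| `retinatune.eyeshine` | background subtraction, RGB mapping, DoG ommatidium detection, red/non-red/dark classification, fraction profiles |
| `retinatune.synth` | seeded generators for recordings, mosaic sections and eyeshine stacks, with ground truth |

## CLI

```bash
# generate synthetic datasets with ground truth
retinatune simulate ephys    --seed 1 --out data/ephys --n-cells 12
retinatune simulate mosaic   --seed 1 --out data/mosaic
retinatune simulate eyeshine --seed 1 --out data/eyeshine

# analyse
retinatune ephys     --scans data/ephys --out out/ephys --adapted
retinatune decompose --sensitivities out/ephys/sensitivity.csv \
                     --out out/classes --bins "-90,-20,10,90" \
                     --elevations data/ephys/ephys_truth.csv
retinatune mosaic    --table data/mosaic/ommatidia.csv --strips 10 --out out/mosaic
retinatune eyeshine  --stacks data/eyeshine --spacing 12 --out out/eyeshine
```

Input/output CSV schemas are documented in `retinatune.io`; eyeshine
stacks are multi-page float32 TIFFs with a JSON sidecar giving the
wavelength page order.

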