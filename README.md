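# halomet

Dereplication toolkit for **halogenated microbial metabolites** in LC-ESI(+)-MS/MS
data: exact-mass/molecular-formula reasoning, isotopologue-pattern simulation,
chlorine/bromine inference from MS1 isotope envelopes, modified-cosine molecular
networking, and detection of **H/Cl/Br/I halogen-substitution series** produced
under OSMAC-style culture conditions (PDA medium ± NaCl/KBr/KI).

Because the raw study data are not deposited, the package ships a fully seeded
synthetic-data generator (`halomet.simulate`) that emulates the study's data
structure — scaffold families with shared fragments, halogen analogs at the
exact substitution mass shifts, Cl/Br isotope envelopes, retention times
increasing with halogen size (H < Cl < Br < I), decoy features — with complete
ground truth, so every stage is testable end to end offline.

## Modules

| Module | Purpose |
| --- | --- |
| `halomet.chem` | formulas, monoisotopic/adduct masses, ppm errors, isotope patterns, formula enumeration (ppm + RDBE filters), halogen mass shifts |
| `halomet.spectra` | feature/spectrum model, MGF + feature-CSV I/O, window filter (top 6 in ±50 Da), precursor exclusion (±17 Da) |
| `halomet.network` | modified cosine (0.02 Da tolerance, ≥2 matched peaks), molecular network, GraphML export |
| `halomet.halogens` | (nCl, nBr) calls from MS1 envelopes via aligned-slot cosine with confidence margins |
| `halomet.series` | H/Cl/Br/I substitution-series assembly with envelope, condition, MS/MS and RT-order evidence |
| `halomet.library` | packaged reference-compound table (22 entries) and exact-mass dereplication |
| `halomet.simulate` | seeded synthetic dataset generator + precision/recall scoring against ground truth |
| `halomet.cli` | `halomet` command with `simulate / network / classify / series / annotate / all` |

## CLI

```bash
# full pipeline on synthetic data: writes features.csv, spectra.mgf, truth.tsv,
# network.graphml, halogen_calls.csv, series.csv, annotations.csv + manifests
halomet all --seed 42 --out runs/demo

# individual stages
halomet simulate --seed 42 --out runs/demo
halomet network  --features runs/demo/features.csv --mgf runs/demo/spectra.mgf --out runs/demo
halomet classify --features runs/demo/features.csv --out runs/demo
halomet series   --features runs/demo/features.csv --mgf runs/demo/spectra.mgf --out runs/demo
halomet annotate --features runs/demo/features.csv --out runs/demo
```

Every stage writes a JSON manifest (config echo, input SHA-256 checksums,
package version). Existing artifacts are never overwritten without `--force`.
Stage parameters (`--ppm-tol`, `--min-score`, `--rt-rule`, ...) default to the
documented analysis settings; `--config config.toml` overrides the simulator
design (see `[simulate]` keys mirroring `GeneratorConfig`).

## Notes

- All mass arithmetic uses the packaged element table
  (`halomet/data/isotopes.tsv`); protonated ions use the proton mass, i.e.
  electron-corrected.
- Iodine is monoisotopic: iodide analogs are never called from envelopes and
  are instead supported by detection in the KI culture condition.
- Network layout/visualization, raw-data feature extraction, genome analysis
  and bioassays are out of scope.
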