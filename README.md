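# chunktag

Artificial-grammar chunk/NAD stimulus designs, synthetic EEG simulation, and
the matching analysis pipeline: frequency-tagging statistics (evoked power,
normalized evoked power, inter-trial phase coherence) for the learning phase,
and a spatio-temporal cluster-permutation ERP test for the test phase, plus a
chunk-aware mean-dependency-distance metric.

The package generates everything it analyzes: streams of 250-ms syllables in
6-syllable chunks separated by 80-ms silences (chunk rate ≈ 0.63 Hz), with a
non-adjacent dependency pair placed either inside a chunk (positions 2 and 5)
or across a chunk boundary (position 5 → position 2 of the next chunk).
Synthetic multichannel recordings superimpose event-locked raised-cosine
kernels and 1/f noise; a gain on each chunk-initial syllable induces the
chunk-rate spectral peak structurally, and a condition-dependent deflection at
the second dependency element produces the within- vs across-chunk ERP
contrast.

## Layout

| module | contents |
| --- | --- |
| `chunktag.agdesign` | syllable inventory, timing, stream/trial generators, event tables |
| `chunktag.synth` | 1/f noise, kernel rendering, `Recording`, channel adjacency |
| `chunktag.spectral` | DFT coefficients, EP, normalized EP, ITPC, neighbour-bin tests |
| `chunktag.erp` | low-pass filter, epoching/baseline, cluster-permutation test |
| `chunktag.mdd` | mean dependency distance over chunked sequences |
| `chunktag.fileio` | events TSV, EDF and flat-binary recordings, result tables |
| `chunktag.pipeline` | YAML config, cohort simulation, `run_all` |
| `chunktag.cli` | `chunktag` command-line entry point |

## CLI

```sh
# learning-phase event timeline (144 chunks, across-chunk condition)
chunktag design --condition across --n 144 --seed 1 --out events.tsv

# render a synthetic recording (flat float32 + JSON sidecar, or .edf)
chunktag simulate --events events.tsv --seed 2 --out rec.f32

# frequency-tagging spectra over consecutive 8-chunk epochs
chunktag spectral --recording rec.f32 --epoch-chunks 8 --out spec

# mean dependency distance of a (element, chunk, head) table
chunktag mdd --structure structure.tsv

# full cohort simulation + analysis (reduced preset)
chunktag run-all --reduced --seed 7 --out out/
```

`chunktag erp` runs the cluster-permutation test from directories of
per-subject trial recordings and event files; `chunktag run-all` accepts a
YAML configuration (`PipelineConfig.to_yaml` writes the schema).

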