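# splintseq

Toolkit for **RNA-splinted ligation in situ sequencing**: padlock probe
design, error-robust DNA barcodes, decoding of multi-round fluorescence
image stacks, and single-cell spatial statistics — plus a seeded synthetic
data generator so the whole pipeline is testable end to end without
microscopy data.

## The problem

Targeted spatial transcriptomics with padlock probes works by hybridizing
a linear oligo so its two termini sit adjacently on the target mRNA,
ligating them with an RNA-splinted DNA ligase, amplifying the circle by
rolling-circle amplification (RCA), and reading an embedded barcode over
several rounds of in situ sequencing. Each computational stage has sharp
contracts this package implements:

- **Probe design.** Each probe covers a 25-nt footprint split into an
  18-nt 5' arm and a 7-nt 3' arm (`armᵢ = revcomp(targetᵢ)`), assembled as
  `arm5 + b₅₋₈ + anchor₂₃ + b₁₋₈ + arm3` = 60 nt, where `b` is the 8-base
  barcode and `b₅₋₈` its duplicated distal half. Candidates are every
  25-mer window without a G or C homotetramer, screened against a
  reference transcriptome (genes with baseMean ≥ 10) requiring a minimum
  Hamming distance ≥ 6 to every non-target window, filtered for ligatable
  junctions (junctions containing G are disfavored), and the 10 probes
  with the least predicted secondary structure are kept per gene.
- **Barcodes.** A greedy lexicode over all 4⁸ words yields 8-base barcodes
  with pairwise Hamming distance d ≥ 3, so every single-base readout error
  is uniquely correctable. Decoding: perfect match, else unique minimum
  distance ≤ 2 → corrected; distance > 2 or tied minimum → discarded.
- **Image decoding.** Rounds are registered by translation (phase
  correlation), background-subtracted (5-px grey opening), summed into a
  composite that is PCHIP-interpolated in Z, DoG-filtered, Otsu-binarized
  and watershed-segmented into amplicons. Per round the four channels are
  quantile-normalized and each amplicon's base is the argmax channel over
  the mean of its top-30 voxels; concatenated calls are decoded against
  the barcode table.
- **Cells & space.** Nuclei (top-hat + Otsu + watershed) grow perinuclear
  zones by sequential dilation; remaining amplicons are attributed by
  affinity propagation on −squared distances with the preference bisected
  to the nucleus count. The cell×gene matrix is filtered (gene detected in
  ≥ 5 cells, cell with ≥ 15 detected genes), and spatial structure is
  quantified on a distance-pruned Delaunay network via a 2000-reshuffle
  interaction-enrichment test, plus a permutation-null gene–gene proximity
  matrix.
- **Summary statistics.** TDR = M/(M+MM)×100, sensitivity vs smFISH,
  between-probe COV, and expression correlation, with a rolling-ball spot
  counter for low-plex images.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

Simulate a desk-scale 96-gene experiment (4 cells, ~240 amplicons, 8
rounds × 4 channels, small per-round stage drifts, exactly one wrong base
planted per amplicon) and run the full decode pipeline:

```python
from splintseq import synthetic as syn, image_decode as idec

truth, stacks, dapi = syn.simulate_96plex_mini(seed=7, errors_per_amplicon=1)
amplicons, table = idec.decode_experiment(stacks, truth.code)
print(f"planted amplicons : {len(truth.amplicons)}")
print(f"detected amplicons: {len(table)}")
print(table["status"].value_counts().to_string())
matched = syn.match_to_truth(table, truth)
print(f"correct gene calls: {(matched['gene'] == matched['true_gene']).mean():.1%}")
```

Output:

```
planted amplicons : 240
detected amplicons: 240
status
corrected    240
correct gene calls: 100.0%
```

Every planted amplicon is found, and because the barcode code has minimum
distance 3, every single planted base error is corrected (status
`corrected`, distance 1) back to the true gene.

The same stages are available from the shell:

```bash
splintseq make-barcodes --n 173 -o barcodes.tsv
splintseq simulate --preset 96plex-mini --seed 7 -o sim/
splintseq decode --stacks sim/ --code sim/barcodes.tsv -o amplicons.csv
splintseq stats tdr --values 99/1        # -> 99.0000
```

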