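# Methods

This note documents the models and procedures implemented in `splintseq`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Probe model

A probe is a 60-nt linear oligo whose two termini hybridize adjacently on a
25-nt footprint of the target mRNA, are ligated by an RNA-splinted DNA
ligase (e.g. SplintR), and circularized for rolling-circle amplification
(RCA). Layout, 5'→3':

```
arm5 (18) + barcode[5..8] (4) + anchor (23) + barcode (8) + arm3 (7) = 60 nt
```

The arms are reverse complements of the two sub-windows of the target
footprint: `arm5 = revcomp(target[0:arm5_len])`,
`arm3 = revcomp(target[arm5_len:25])`. With the probe annealed antiparallel
to the target, the probe's 5'-phosphate (start of `arm5`) and 3'-OH (end of
`arm3`) meet at a nick in the middle of the footprint; the **junction** is
recorded as the ordered pair (3'-arm terminal base, 5'-arm terminal base).
The 4-base element upstream of the anchor duplicates barcode positions 5–8
because ligation-based readout is most reliable within four bases of the
anchor from either direction; duplicating the distal half lets a
5'→3'-only chemistry read the full word. An alternative reading of the
junction orientation costs only a user-supplied junction table — the table
is keyed by ordered pairs and fully overridable.

Default arm split 18/7: in arm-length sweeps (5' arm from 2 to 22 nt at a
fixed 25-nt footprint) this split maximizes amplicon yield while keeping
the true discovery rate high. Probes shorter than 60 nt are produced in
miRNA mode, where the footprint is the whole mature miRNA (18–23 nt), the
3' arm stays ≥ 7 nt and junction quality takes priority over the split.

### Design pipeline and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| enumeration | window length `k` | 25 nt | footprint fixed by the assay |
| enumeration | homotetramer filter | GGGG and CCCC | G-quadruplex-prone and synthesis-hostile runs; `legacy_g_filter` restores G-only |
| reference | `min_base_mean` | 10 | genes below this expression level cannot produce meaningful off-target hybridization signal; removal is strict `<` |
| junction | quality table | TG/CG/GA and all G-containing pairs disfavored; TC/CC/AC favored | junctions containing G show poor ligase activity; the three empirically most/least reliable pairs anchor the classes |
| off-target | `min_mismatches` | 6 | a candidate passes iff every 25-nt window of every non-target reference transcript is ≥ 6 mismatches away |
| ranking | `n_per_gene` | 10 | ten least-structured survivors per target |

**Off-target model.** Ungapped Hamming distance over all 25-nt windows of
the reference (sense strand by default, `scan_reverse` adds the reverse
complement). This is exact and conservative: any gapped alignment with
fewer than 6 mismatches implies a nearby ungapped window also scoring low.
It is verified in the test suite against a brute-force per-window scan.
Mismatches are counted over the full window, not an aligned sub-span.

**Structure score.** The default backend is a Nussinov-style dynamic
program: Watson–Crick pairs only (A·T −1.0, G·C −2.0, in kcal/mol-like
units), an extra −1.0 per stacked pair, minimum hairpin loop of 3. Lower =
more structure; candidates are ranked with the least-structured first, ties
broken by transcript coordinate. The model is deterministic and
dependency-free; an `rnafold` backend (external ViennaRNA executable) is
available but scores from different backends are never mixed in one
ranking. Wobble pairs are excluded so the score is symmetric under reverse
complement.

## Barcodes

Barcodes are 8-base words at minimum pairwise Hamming distance 3, generated
by a **greedy lexicode**: iterate all 4⁸ = 65 536 words in lexicographic
order (A < C < G < T), keep a word iff it is ≥ 3 mismatches from every kept
word. The greedy code exceeds the Gilbert–Varshamov bound
4⁸ / Σ₀² C(8,i)·3ⁱ ≈ 227, comfortably above the 173 barcodes needed for a
96-mRNA + 77-miRNA panel. Generation is deterministic; the seed only
shuffles the gene↔barcode assignment, and the reference table is always
serialized with results. Composition filters (homotetramer, GC bounds)
exist but are off by default, since distance is the only stated contract.

**Decoding.** Exact match → `perfect`. Otherwise the distance to every
reference barcode is computed: minimum > 2 → `discarded_distance`;
non-unique minimum → `discarded_ambiguous`; unique minimum of 1 or 2 →
`corrected`. With distance-3 spacing every single-base error is provably
corrected (triangle inequality), which the suite also checks exhaustively.

## Image decoding

Input: R rounds × 4 channels × (z, y, x), channel↔base map configurable
(default channels 0–3 → A, C, G, T). Axis order (z, y, x), 0-based.

1. **Registration** — per round, the channel-summed volume is aligned to
   the reference round by phase correlation (translation only). Reported
   shifts are round-relative displacements; shifts above `max_shift`
   (default 10 voxels) are clipped and flagged low-confidence. Non-rigid
   warping is out of scope; the simulator plants rigid shifts only.
2. **Background subtraction** — slice-wise grey opening with a 5-pixel
   structuring element, subtracted and clamped at zero. Flat backgrounds
   map to ~0, punctate peaks survive.
3. **Segmentation** — composite = sum over rounds and channels; upsampled
   in Z by monotone piecewise-cubic (PCHIP) interpolation, by default to
   near-isotropy from the voxel size metadata (500 nm z / 250 nm xy →
   factor 2); difference of Gaussians (σ = 1.0, 3.0 voxels in interpolated
   space); Otsu threshold; watershed seeded at local maxima of the filtered
   volume (minimum seed separation ⌈σ_small⌉). Labels are downsampled back
   to the original Z grid and relabeled 1..N. Labels partition the
   foreground; no voxel belongs to two amplicons.
4. **Basecalling** — per round, the four channels are quantile-normalized:
   each channel's intensities are mapped onto the mean of the four sorted
   intensity vectors (ties broken by stable voxel order). Per amplicon and
   channel, the top min(30, n_voxels) normalized intensities are averaged;
   the called base is the argmax channel, exact ties keep the first channel
   in configuration order and are counted in QC. Top-30 is interpreted as
   voxels, and normalization pools the whole volume (not per tile).
5. **Decode** — the R calls concatenate to the observed barcode, decoded as
   above. Discarded statuses carry no gene.

## Cells and spatial statistics

- **Nuclei**: white top-hat (disk radius 25 px) → Otsu → distance-transform
  watershed. The structure-tensor-energy pre-filter is available behind a
  flag but off by default — the simpler default is deterministic and
  sufficient for rendered fixtures.
- **Perinuclear zones**: sequential label dilation with nearest-nucleus
  collision handling (`expand_labels`); zones are disjoint and contain
  their nuclei by construction.
- **Assignment**: amplicons inside a zone take that cell. The rest are
  clustered jointly with nucleus centroids by affinity propagation
  (similarity = −squared distance, damping 0.9, ≤1000 iterations) with the
  shared preference bisected until the exemplar count equals the nucleus
  count; clusters map to the nucleus they contain, and the fallback on
  non-convergence is nearest-nucleus with a warning.
- **Filters**: a gene is detected in a cell iff count ≥ 1
  (`expression_threshold`); genes detected in < 5 cells are dropped, then
  cells with < 15 detected genes are dropped. Order is genes-then-cells
  (the convention of single-cell toolkits); the single pass is idempotent.
- **Delaunay network**: triangulation of cell centroids; edges longer than
  the cutoff (400, in centroid pixel units) are pruned unless they are
  among a node's 2 shortest edges (`min_nn`), so pruning never isolates a
  node. Degenerate inputs (< 3 points, collinear) fall back to the
  complete graph with a warning.
- **Interaction enrichment**: observed edge counts per unordered label
  pair vs the mean of 2000 uniform label reshuffles (counts preserved);
  reports ratio, the null 95% band and a two-sided empirical p with the
  (1 + hits)/(1 + n_sim) correction.
- **Gene–gene proximity**: pairs of amplicons of two genes within a radius
  (default 50 px), normalized by a gene-label-permutation null. This
  permutation-null co-occurrence statistic is this package's
  interpretation of proximity, chosen for symmetry and calibration;
  genes with < 2 amplicons are flagged low-support.

## Summary statistics

- TDR = M/(M+MM) × 100 for a matched/junction-mismatched probe pair.
- Sensitivity = mean(assay spots/cell) / mean(smFISH spots/cell) × 100.
- Between-probe COV = sample (n−1) standard deviation / mean × 100 — the
  sample convention is this package's stated choice.
- Spot counting: max Z-projection, rolling-ball background subtraction
  (radius 10 for amplicons, 2 for smFISH puncta), optional 3×3 box smooth,
  peaks above mean + 3·sd of the residual with ≥ 3 px separation. The
  adaptive mean+k·sd threshold is a documented stand-in for interactive
  particle-tracker settings.

## Synthetic data: what it does and does not emulate

The generator produces: (i) random transcriptomes with near-homolog 25-nt
windows planted at an exact mismatch count, so the off-target boundary
(5 fails / 6 passes) is testable; (ii) amplicon fields — nuclei placed with
≥ 4-radius separation, per-cell amplicon clouds (Gaussian around the
nucleus, σ ≈ 1.3 radii), per-gene lognormal abundances, per-round base
errors planted at a rate or an exact per-amplicon count; (iii) rendered
rounds — each amplicon is a 3D Gaussian (σ = 1.0, 1.5, 1.5 voxels) in the
channel of its barcode base for that round, with integer per-round global
shifts, additive Gaussian noise clamped at zero, and nuclei as smooth
disks in a DAPI image. All randomness flows through one integer-seeded
generator; identical seeds give identical bytes.

The default field (`96plex-mini`: 96 genes, 4 cells × ~60 amplicons in a
32×256×256 volume, 8 rounds) mirrors the per-cell read scale of a
multiplexed co-culture experiment (a few hundred reads/cell) while keeping
a full pipeline run around a minute on one CPU.

Deliberate simplifications: amplicons keep a minimum separation (7 voxels)
so spots are resolvable — real data has optical crowding, merged amplicons
and segmentation errors; the PSF is an isotropic-in-xy Gaussian without
aberration or channel bleed-through (bleed-through exists behind a flag);
shifts are global and integer, not non-rigid; there is no
autofluorescence. Passing end-to-end tests therefore demonstrates the
correctness of the pipeline's logic, not its robustness to real-microscopy
artifacts.

## Known limitations

- Off-target screening is ungapped; a bulged near-homolog scoring well in
  a gapped aligner but poorly ungapped could be missed (conservatively:
  extra mismatches only make the screen stricter).
- The structure model is coarse; rankings agree with thermodynamic folding
  only in tendency. Use the `rnafold` backend where ViennaRNA is installed.
- Affinity-propagation assignment assumes roughly isotropic cells; long
  protrusions are attributed by proximity, not morphology.
- Quantile normalization assumes the four channels image the same field;
  strong channel-specific spatial artifacts violate it.
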