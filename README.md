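# raquant

Quantitative analysis of rheumatoid arthritis (RA) bone erosion and of RNA
G-quadruplex (rG4) structure in inflammation-related genes — two linked
screens packaged as one tested pipeline:

1. **rG4 screening.** RA transcriptomes are screened for differentially
   expressed genes (DEGs) at |log₂FC| ≥ 1.5 and FDR < 0.01, intersected with
   an inflammation core gene set to yield *irDEGs*, and each irDEG mRNA is
   scanned for canonical rG4 motifs — four G-tracts of ≥ 3 guanines separated
   by 1–7 nt loops — with a deterministic G4Hunter-style window score
   (20 nt window, positivity at score ≥ 0.5, sensitivity sweep over
   0.4–0.6). Motifs are assigned to the 5′UTR / CDS / 3′UTR region holding
   the majority of their span, and cohort summaries report positivity rates,
   region distributions, tetrad-layer counts and loop lengths.

2. **Bone-erosion (BE) severity.** Erosion lesions are extracted from 3D CT
   segmentation masks as 26-connected components, filtered by the
   pathological-erosion rule (≥ 2 consecutive axial slices), measured
   (volume, maximum axial/vertical diameter), and combined into a 0–100
   severity score by linear weighting:

   `score = 100 · (0.3·I_count + 0.4·I_diam + 0.3·I_vol)`

   with each indicator min–max normalised. Severity grades, rapid-progression
   (annual score growth ≥ 30 %/yr over ≥ 3 follow-ups ≥ 6 months apart) and
   special-site flags (erosion ≥ 40 % of wrist bone volume) follow from the
   score. Segmentation quality is evaluated with accuracy / Dice / sensitivity
   / specificity and the soft-Dice + cross-entropy loss; clinical consistency
   uses ICC(2,1), Pearson r with Fisher-z CIs, and seeded percentile
   bootstrap.

Because patient CT volumes and sequencing data cannot ship with a package,
a first-class synthetic-data module generates every input with known ground
truth: transcripts with planted motifs on a provably scan-negative
background, negative-binomial count matrices with planted fold changes, bone
phantoms with analytic lesion geometry, and predicted masks degraded to a
requested Dice coefficient.

Intended users: imaging and bioinformatics researchers who want a
reproducible, inspectable reimplementation of this kind of dual screen at
desk scale, with oracle-backed tests for every stage.

## Worked example

Run the full pipeline on synthetic data:

```bash
raq run --out demo
```

This writes a report bundle (`motifs.tsv`, `deg_table.tsv`,
`severity_scores.tsv`, `threshold_sweep.tsv`, summary tables, NIfTI-free
truth tables, and `manifest.json`). With the default configuration and
`seed: 7` in a YAML config, the manifest reads:

```json
"deg":      {"n_deg": 128, "n_irdeg": 67, "n_up": 52, "n_down": 15},
"rg4":      {"n_motifs": 88, "n_positive": 42,
             "overall_rate": 62.69, "up_rate": 59.62, "down_rate": 73.33},
"severity": {"n_patients": 16, "grades": {"moderate": 10, "mild": 6}, "n_rapid": 5},
"seg_eval": {"mean_dsc": 0.860, "mean_accuracy": 0.998},
"clinical": {"icc": 0.954, "pcc": 0.709}
```

Reading: of 2,000 simulated genes, 128 pass the DE screen and 67 intersect
the core inflammation set (52 up-, 15 down-regulated); 42 of the 67 carry
rG4 motifs (62.69 % positivity — 59.62 % among up-, 73.33 % among
down-regulated genes). Across 16 synthetic patients the severity scores
spread over mild/moderate grades with 3–5 rapid progressors depending on
seed; masks perturbed to a target Dice of 0.86 measure 0.860, and the model
score tracks the simulated DAS28 disease-activity score (r ≈ 0.7).

The threshold sweep (`threshold_sweep.tsv`) shows the nested positive sets:

```
threshold  n_positive  rate   n_intersection_default  intersection_rate
0.4        42          62.69  42                      100.0
0.5        42          62.69  42                      100.0
0.6        37          55.22  37                      88.1
```

Individual stages are available as subcommands (`raq synth all`,
`raq rg4 scan|sweep`, `raq deg screen`, `raq score`, `raq eval seg|clinical`)
and as plain library calls; see `docs/methods.md` for the model details.

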