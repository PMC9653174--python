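# oatpquant

Single-cell image quantification of **organic anion transporting
polypeptide (OATP/SLCO)** expression in multiplexed fluorescent
immunohistochemistry of human glioblastoma (GBM) versus non-tumor brain
tissue — with a fully ground-truthed synthetic data generator so that
every stage of the analysis is verifiable without patient images.

## The problem

OATPs (OATP1A2, OATP2B1, OATP1C1, OATP4A1) are solute-carrier uptake
transporters with broad substrate specificity that includes anti-cancer
agents. Their protein-level expression in GBM tissue is quantified from
six-channel panels — Hoechst (nuclei), one OATP isoform, IBA1 (myeloid),
GFAP (astrocyte/tumor), UEA-1 lectin (endothelium), PDGFRβ (stroma) — by:

1. **Tissue-wide quantification.** Integrated intensity
   `I = Σ_{x ∈ OATP⁺ mask} OATP(x)`, its mean form `I / |tissue mask|`
   (normalized to ROI area), and percent area coverage
   `100·|OATP⁺ ∩ tissue|/|tissue|`.
2. **Single-cell quantification.** Segmentation of IBA1⁺ myeloid cells
   and lectin⁺ vessels; per-object average OATP intensity; per-case mean
   of object means; the fraction of IBA1⁺ cells OATP-positive against a
   control-derived threshold.
3. **Group statistics.** GBM:control fold change = ratio of group means,
   tested with a two-sided Mann–Whitney *U*; Spearman correlation
   matrices of OATP intensity against cell-type markers; Benjamini–
   Hochberg FDR control.
4. **Niche expression.** Differential expression between the cellular
   tumor (CT) and the peri-necrotic niches (PPN/PNZ) of a
   region-annotated gene × sample table, followed by Spearman correlation
   of the SLCO genes with the top differentially expressed genes
   (hypoxia program: CA9, VEGFA, BNIP3, PDK1, …).

Because no patient images are distributable, the `simgen` module renders
synthetic cases (disk-shaped cells, tube-shaped vessels, configurable
per-compartment GBM:control OATP folds, camera noise, optional
peri-necrotic OATP4A1 gradients) with exact ground truth, and the test
suite checks that the pipeline measures back what the generator encodes.
See `docs/methods.md` for the model.

## Worked example

```python
from oatpquant import pipeline, simgen

config = pipeline.RunConfig(outdir="results/demo", seed=5)
config.generator = simgen.GeneratorConfig(
    image_shape=(256, 256),
    cohort_sizes={"gbm": 6, "control": 4},
    oatp_fold={"tissue": 1.0, "myeloid": 18.0, "vessel": 6.0,
               "astrocyte_tumor": 6.0, "stromal": 3.0},
)
result = pipeline.run_pipeline(config)
print(result.folds[["measure", "fold", "U", "p"]].round(4).to_string(index=False))
```

prints

```
                         measure    fold    U      p
tissue_mean_integrated_intensity  5.7753 24.0 0.0095
     tissue_integrated_intensity  6.3626 24.0 0.0095
           percent_area_coverage  0.8869  8.0 0.4762
               myeloid_mean_oatp 15.6961 24.0 0.0095
                vessel_mean_oatp  5.9926 24.0 0.0095
```

The generator was configured with an 18-fold myeloid and 6-fold vessel
OATP increase in GBM; the pipeline recovers 15.7× and 6.0× from this
10-case toy cohort (U and p are the two-sided Mann–Whitney comparison of
the per-case values; the fold of tissue-wide intensity, 5.8×, reflects
the cell-type mixture). `results/demo/` now holds the full report bundle:
`cases.csv`, `objects.csv`, `folds.csv`, `correlations.csv`,
`regions.csv` and `run_manifest.json`.

The same pipeline is scriptable from the shell:

```bash
oatpquant run-all --seed 5 --outdir results/demo      # simulate + analyze
oatpquant simulate --seed 5 --outdir results/cohort   # TIFFs + ground truth
oatpquant quantify --indir results/cohort --outdir results/report
oatpquant niche --seed 5 --outdir results/niche       # CT vs PPN/PNZ stage
```

`--config run.yaml` accepts nested `generator:`, `segmentation:` and
`expression:` sections mirroring the dataclass fields.

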