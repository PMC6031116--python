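# sipscope

Quantitative stable-isotope-probing (SIP) metagenomics for density-gradient
experiments: who in a microbial community incorporated a heavy-isotope
substrate, and how much?

In a SIP experiment, organisms that assimilate a ¹³C-labeled substrate build
the heavy isotope into their DNA, which then bands deeper in an isopycnic
CsCl density gradient. `sipscope` implements the quantitative analysis
around such an experiment:

- **Buoyant-density physics.** DNA buoyant density is modelled as
  ρ(GC, AFE) = 1.660 + 0.098·GC + 0.036·AFE (g/mL), where GC is the genome's
  GC fraction and AFE the ¹³C atom-fraction excess (0 = natural abundance,
  1 = fully labeled). Inverting the relation for a genome of known GC turns
  an observed band density into an enrichment estimate
  AFE = (ρ_obs − ρ_unlabeled)/0.036, clamped to [0, 1]. A linear
  refractive-index → density calibration handles refractometer readings.
  All constants are overridable.
- **Gradient fraction tables and binning.** Validated TSV readers for
  ~32-fraction gradient profiles (density, DNA concentration, sequencing
  depth); assignment of fractions to *light* / *middle* / *heavy* density
  bins either from explicit cutoffs or automatically by comparing a labeled
  treatment profile against an unlabeled control; per-fraction genome
  coverage normalization to a common sequencing depth; and the
  coverage-weighted density centroid that locates a genome's band.
- **Replication-skew validation.** Windowed GC skew (G−C)/(G+C) and its
  cumulative curve; origin/terminus prediction from the cumulative minimum
  and maximum; rotation of a circular genome to its predicted origin; and
  terminal-overlap circularization of a linear scaffold.
- **Comparative genome statistics.** Genome size, gene counts, annotation
  status, coding density and CAZy (carbohydrate-active enzyme) content
  computed from FASTA + gene tables, with the comparative percentages
  100·(focal − mean)/focal ("difference from average") and
  100·(focal − max(others))/focal ("percent larger than largest"). A
  reference table of the seven published complete Saccharibacteria genomes
  ships with the package.
- **Synthetic data.** A generator for genomes with controlled GC,
  replication-strand skew and gene content, and for labeled/unlabeled
  community gradients with known ground truth — the package's test bed.

## Worked example

Generate a synthetic study (a labeled low-GC genome at 49.95% GC and
AFE 0.75 among high-GC unlabeled background taxa, treatment vs control
gradients), then estimate the focal genome's enrichment and validate its
assembly:

```bash
$ sipscope simulate --out demo --seed 11
{
  "taxon_id": "focal",
  "gc": 0.4995,
  "afe": 0.75,
  "genome_length": 300000,
  "band_density": 1.7359509999999998,
  "ori_pos": 150001,
  ...
}

$ sipscope enrich --coverage demo/coverage.tsv --profile demo/treatment.tsv \
    --genome-id focal --gc 0.4995
{
  "genome_id": "focal",
  "density_centroid": 1.7359111745764855,
  "unlabeled_density": 1.7089509999999999,
  "afe": 0.7488937382357107
}

$ sipscope skew demo/genomes/focal.fasta --step 100
{
  "genome_id": "focal",
  "length": 300000,
  "gc": 0.49949333333333334,
  "ori_pos": 150001,
  "ter_pos": 299901,
  "amplitude": 358.9237029595798
}
```

The focal genome's coverage-weighted band density (1.7359 g/mL) sits
0.027 g/mL above the 1.7090 g/mL expected for unlabeled DNA of its GC
content, giving a recovered enrichment of 0.749 — within 0.001 of the
generating value 0.75. The GC-skew origin call lands exactly on the
constructed strand-bias switch point (150,001 of 300,000 bp), and the
terminus within 100 bp of the construction's terminus at position 1.

The same steps are available as a library (`sipscope.enrichment_from_density`,
`sipscope.auto_bin`, `sipscope.predict_ori_ter`, ...) and as a single
configured run, `sipscope run --config run.yaml`, which writes per-stage
TSVs plus one JSON report.

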