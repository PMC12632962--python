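# hxms

A Python library and command-line tool for **HXMS**, a standardized,
lightweight, human-readable file format for hydrogen-deuterium exchange mass
spectrometry (HX/MS) data.

HX/MS measures how fast a protein's backbone amide hydrogens exchange for
deuterium in D2O, probing conformation and stability. In practice the data
are scattered across vendor-specific export tables, almost always reduced to
centroid-level summaries, which makes sharing and quantitative reanalysis
hard. The HXMS format keeps the **full isotopic mass envelopes** alongside
peptide identities, the complete time course including fully deuterated
controls, experimental replicates, multimodal (e.g. EX1) sub-populations and
post-translational modifications, in a plain-text file with three sections:

1. **Metadata** — tab-delimited `METADATA`/`REMARK` lines with the protein
   sequence, name, state, temperature (K), pH(read) and D2O saturation.
2. **Timepoint records** — fixed-width `TP` lines with columns
   `INDEX, MOD, START, END, REP, PTM_ID, TIME(SEC), UPTAKE, ENVELOPE`
   (widths 12/8/7/7/7/5/8/16/9, envelope unbounded).
3. **PTM dictionary** — `PTM` lines mapping each 4-digit `PTM_ID` to a
   description such as `Phosphoryl STY (18)`.

## The quantities

For a peptide envelope with normalized peak intensities
p_0, p_1, …, p_{k−1} at 1 Da spacing, the **centroid** is the first moment

&nbsp;&nbsp;&nbsp;&nbsp;m(t) = Σᵢ i · pᵢ(t)   (Da, relative to the first reported peak)

and the **deuterium uptake** at incubation time t is

&nbsp;&nbsp;&nbsp;&nbsp;D(t) = m(t) − m(0),

computed per peptide and replicate, so D(0) ≡ 0.00 by construction. A
replicate with no 0 s sample is referenced to the arithmetic mean of the
other replicates' zero-centroids. Fully deuterated controls are stored with
`TIME(SEC)` = `inf`; envelopes are normalized to unit sum.

## What's in the package

- `hxms.model` — document model (`HXMSFile`, `TimepointRecord`, `Envelope`,
  `Metadata`, `PTMEntry`) and `validate()`, which reports every invariant
  violation with a severity and record locator.
- `hxms.io` — strict fixed-width writer, tolerant reader
  (fixed-width *or* tab-delimited data lines), round-trip safe.
- `hxms.envelopes` — normalization, centroids, uptake, zero-reference rules.
- `hxms.converters` — converters from five export dialects: DynamX-style,
  HDExaminer-style, HDX Workbench-style, BioPharma Finder-style, and this
  package's self-contained custom CSV. DynamX/BioPharma report uptake
  directly; Workbench/HDExaminer uptake is recomputed from centroids;
  full-spectrum output is available for the spectra-carrying dialects.
  Column maps are declarative configuration (`hxms.converters.DIALECTS`).
- `hxms.synthetic` — a generator of synthetic experiments and export files
  in every dialect, with independently computed ground truth (binomial
  exchange model with a closed-form centroid).
- `hxms.cli` — the `hxms` command: `convert`, `validate`, `info`, `demo`.

## Worked example

Generate a tiny synthetic Workbench-style export (two peptides, one
replicate, 0 s / 60 s / fully deuterated) and convert it:

```python
from hxms import synthetic, converters, dumps

exp = synthetic.SyntheticExperiment(
    peptides=((1, 10), (5, 14)), rate_scales=(0.005, 0.02),
    timepoints_sec=(0.0, 60.0, float("inf")), n_replicates=1, rng_seed=42)
csv_text, _ = synthetic.emit_dialect_file(exp, "workbench")
req = converters.ConversionRequest(
    dialect=converters.DIALECTS["workbench"], input=csv_text,
    metadata=exp.metadata(), output_mode="full_spectrum")
print(dumps(converters.convert(req)))
```

prints

```
METADATA	PROTEIN_SEQUENCE	GSHMKTVEVNGADASDDN
METADATA	PROTEIN_NAME	synthetic HX/MS test protein
METADATA	PROTEIN_STATE	APO
METADATA	TEMPERATURE (K)	293.15
METADATA	pH(READ)	6.0
METADATA	D2O_SATURATION	0.91
TP          0       A      1      10     0    0000    0.000000e+00    0.00     0.589,0.265,0.103,0.037,0.003,0.001,0.001,0.000,0.000,0.000,0.000,0.000
TP          1       A      1      10     0    0000    6.000000e+01    1.89     0.063,0.201,0.274,0.228,0.140,0.064,0.020,0.007,0.002,0.000,0.000,0.000
TP          2       A      1      10     0    0000    inf             7.14     0.005,0.002,0.001,0.000,0.009,0.018,0.081,0.253,0.391,0.166,0.058,0.014
TP          3       A      5      14     0    0000    0.000000e+00    0.00     0.573,0.260,0.099,0.042,0.006,0.002,0.001,0.004,0.008,0.003,0.001,0.000
TP          4       A      5      14     0    0000    6.000000e+01    4.91     0.000,0.000,0.011,0.064,0.153,0.238,0.244,0.174,0.083,0.027,0.007,0.001
TP          5       A      5      14     0    0000    inf             6.95     0.001,0.006,0.004,0.006,0.005,0.019,0.088,0.251,0.386,0.164,0.057,0.014
```

Reading the peptide 1–10 rows: its centroid sits 1.89 Da above the 0 s
reference after 60 s of labeling, and 7.14 Da above it in the fully
deuterated control; the 0 s rows carry uptake 0.00 by definition, and each
envelope lists the normalized isotope-peak intensities the centroids came
from. The same document can be produced from the shell:

```sh
hxms demo --outdir demo --seed 42
hxms convert --format workbench --input demo/workbench_export.csv \
     --output demo/out.hxms --mode spectrum \
     --sequence GSHMKTVEVNGADASDDN --temperature-k 293.15 \
     --ph-read 6.0 --d2o-saturation 0.91
hxms validate --input demo/out.hxms
hxms info     --input demo/out.hxms
```

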