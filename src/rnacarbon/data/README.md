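# Bundled data files

## table1_radiocarbon.csv

Transcription of the radiocarbon method-validation table: growth media and
reagent controls, whole *E. coli* cells, and 24 extracted-RNA samples
(including the Rifle LQ107 groundwater RNA), with the extraction-protocol
variables for each row.

Column dictionary:

| column | meaning |
|---|---|
| `sample_id` | stable row identifier (this package's own naming) |
| `medium` | growth medium / material (`LB`, `acetate`, `dextrose`, reagent name, `groundwater`) |
| `sample_kind` | `reagent`, `medium`, `cells`, or `extracted-RNA` |
| `surfactant` | extraction surfactant: `SDS`, `CTAB`, or `none` |
| `phenol_ph` | phenol:chloroform pH (6.6 water-saturated, 7.9 Tris-saturated); empty for non-extractions |
| `tube_size` | phase-lock gel tube size: `small` (1.5 mL), `large` (50 mL), `none` |
| `licl` / `cscl` | whether LiCl precipitation / CsCl ultracentrifugation was used (`yes`/`no`) |
| `fraction_modern`, `fm_sigma` | AMS fraction modern (F14C) ± 1σ |
| `delta14c`, `delta14c_sigma` | decay-corrected Δ14C (‰) ± 1σ, as printed |
| `age_reported`, `age_sigma_reported` | conventional 14C age (yr BP) ± σ as printed; empty for (>)Modern rows |
| `modern_class` | `numeric-age`, `Modern`, or `greater-than-Modern` |
| `a260_280`, `a260_230` | NanoDrop purity ratios (~2.0 = clean nucleic acid) |
| `pct_dna` | percent DNA by Qubit fluorometry; `pct_dna_censored=yes` marks "<x%" entries stored at the bound |
| `rna_ug` | RNA yield estimate (μg) |
| `year_measured` | calendar year assumed for the decay correction (the AMS date is not stated in the source; 2015 is this package's fixture convention — ages are independent of it) |
| `cams_id` | AMS facility accession number |

Known transcription notes: the `cams_id=176276` row is printed
">Modern" although Fm − 1σ < 1; it is kept as printed and flagged by
`rnacarbon.validation` as the single known exception to the 1σ
classification rule. The `cams_id=167574` row's class is `Modern`
(a line-wrapping artifact in the rendered source table places a
">Modern" next to it).

## rifle_endmembers.csv

Δ14C end-member table for the Rifle, CO alluvial aquifer (well LQ107):
dissolved inorganic carbon (DIC), dissolved organic carbon (DOC),
sediment organic carbon (SOC, n = 20) and buried plant material (n = 8).
Columns: `name, delta14c, sigma, n` (‰; σ is the printed spread — for SOC and
plant the between-sample SD, treated as end-member heterogeneity).

## rifle_sample.csv

The groundwater RNA radiocarbon measurement: `name, delta14c, sigma` (‰).

## synthetic_example_community.csv / synthetic_example_annotations.csv

SYNTHETIC demonstration data produced by `rnacarbon.synthetic.gen_community`
(Dirichlet rank-abundance community with known autotroph share); not
measurements. Used by the README worked example and the CLI docs.
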