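# starterscope

Analyses for community-science surveys of fermented-food (sourdough-style)
microbiomes: probabilistic species co-occurrence, biogeographic
distance-decay and regioning, indicator-taxon screening, permutation
multivariate statistics, in-vitro competition/co-persistence analysis with a
Monte-Carlo concordance test, dough-rise kinetics, and VOC-to-community
function linkage. A synthetic-data module generates every input the pipeline
consumes, so the full stack is testable offline.

## Modules

| module | what it does |
|---|---|
| `community` | `CommunityTable` data model, rarefaction, relative abundance, Bray-Curtis, equal-weight kingdom combination, Ward.D2 clustering |
| `cooccurrence` | presence/absence binarization (strict >1% rule), hypergeometric pair model, expected-count filter, Bonferroni sign calls |
| `biogeography` | haversine distances, Mantel distance-decay, k-means geographic regions |
| `indicators` | point-biserial indicator index r (and IndVal), Spearman screens, prevalence filter, per-variable BH-FDR |
| `multivariate` | Mantel (with exact enumeration option), sequential PERMANOVA, non-metric MDS (Kruskal stress-1), Kruskal-Wallis + Dunn |
| `competition` | CFU fractions, persistence calls at a detection limit, persistence index, growth correlation, Monte-Carlo sign concordance |
| `kinetics` | pixel-to-mm normalization (103 mm tubes), collapse truncation, logistic fits with an F-test acceptance gate, rise-rate ANOVA |
| `voc_function` | blank-based background filtering, Kovats retention indices, z-scores, the combined community-to-function report |
| `taxonomy` | patristic distances from newick trees, threshold clustering, curated species-group naming |
| `synthetic_data` | seeded generators for surveys (planted pairs/indicators/decay), competitions (prescribed outcomes), and functional assays |

## CLI

All functionality is exposed through the `starterscope` entry point:

```bash
# generate a synthetic survey and analyze it
starterscope synth survey --seed 1 --out survey/
starterscope cooccur --input survey/table.tsv --annotations survey/annotations.tsv \
    --alpha 0.05 --min-expected 1 --out cooccur.tsv
starterscope geo decay --table survey/table.tsv --annotations survey/annotations.tsv \
    --meta survey/coords.tsv --perms 999 --seed 1
starterscope geo regions --meta survey/coords.tsv --k 4,15 --out regions.tsv
starterscope indicators --table survey/table.tsv --annotations survey/annotations.tsv \
    --meta survey/metadata.tsv --prevalence 0.10 --fdr 0.05 --out indicators.tsv

# competition experiment and concordance with co-occurrence signs
starterscope synth competitions --out comp/
starterscope compete --cfus comp/cfus.tsv --limit 0.01 --transfer 6 --out calls.tsv
starterscope concordance --signs comp/signs.tsv --outcomes calls.tsv \
    --draws 10000 --seed 1 --out concordance.json

# dough-rise kinetics and VOC linkage
starterscope synth function --survey-dir survey/ --out fn/
starterscope rise --series fn/rise.tsv --calib fn/calib.tsv --fall 0.05 --out fits.tsv
starterscope voc link --voc fn/voc.tsv --blanks fn/blanks.tsv \
    --table survey/table.tsv --annotations survey/annotations.tsv --out link.json

# species assignment from a tree
starterscope assign --tree tree.nwk --refs refs.tsv --threshold 0.97 --out assign.tsv
```

Distance matrices, Mantel/PERMANOVA/NMDS/Kruskal subcommands are also
available (`starterscope mantel --help`, etc.).

## Conventions worth knowing

- Abundance thresholds ("present above 1%") use strict `>` everywhere.
- Co-occurrence tails include the observed value; the Bonferroni factor
  counts only pairs passing the expected-co-occurrence filter.
- PERMANOVA terms are sequential (Type-I) in the order given — order
  matters for correlated predictors.
- NMDS output is centered, principal-axis rotated and sign-fixed so axis
  correlations are deterministic.
- All permutation statistics are reproducible bit-for-bit given a seed.
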