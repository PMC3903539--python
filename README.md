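# fmcm — functional-module connectivity mapping for drug repurposing

`fmcm` screens a drug rank-profile library (a Connectivity-Map-style
collection of per-treatment full-gene rankings) for candidate repurposed
drugs against a complex disease — not with one whole differential-expression
signature, but with **multiple functional gene modules**, so that every
candidate is characterised function by function and drugs harmful to any
disease function can be excluded. It was built for cohort microarray studies
of the colorectal-adenoma type (paired tumour/normal expression profiles),
and ships a full synthetic-data generator so the entire pipeline is testable
offline.

## The method

Given a genes × samples expression matrix with control/case labels, a
protein–protein interaction (PPI) network, a gene-ontology annotation, and a
drug library of instance-level gene rankings:

1. **Condition-specific networks (GGINs).** For each condition, a gene pair
   becomes an edge iff its Pearson correlation has *p* ≤ *p₀* (default
   0.001, from *t* = *r*·√((*n*−2)/(1−*r*²))) **and** the pair is a known
   PPI. Each node carries its degree *k* and clustering coefficient *C*.
2. **Differential expression (SAM).** Per gene,
   *d* = (x̄_case − x̄_control)/(*s* + *s₀*) with permutation-based FDR;
   genes with *q* < 0.01 and linear fold change FC > 2 (or < 1/2) are the
   signed DEG set.
3. **Trend filter (GSToP).** A DEG survives iff it appears in ≥1 GGIN and
   its (*k*, *C*) move with its expression direction: non-decreasing from
   control to case for up-regulated genes (≥1 strict), mirrored for
   down-regulated genes.
4. **Functional modules.** Surviving genes are grouped into configured
   ontology-term modules (default eight: apoptosis, cell cycle, cell
   proliferation, DNA replication, immune system process, RNA metabolic
   process, transcription, signal transduction), split into up/down tags.
5. **Connectivity scoring.** Each module queries every library instance with
   a signed KS statistic (s = ks_up − ks_down when signs differ, else 0);
   instances are ranked by *s* and each drug's enrichment score ES is the
   KS statistic of its instances' positions. A drug is **beneficial** to a
   module if ES < −0.5 with randomization *p* < 0.005 (its profiles reverse
   the module signature), **harmful** if ES > 0.3.
6. **Function–drug association map (FDAM).** Bipartite module↔drug map of
   all classified links; only drugs with ≥1 beneficial link are kept.
7. **Compounds.** Therapeutic compounds are **exact covers** of the module
   set by purely beneficial drugs: component coverages are pairwise
   disjoint, their union is all modules, every beneficial link of a
   component has ES ≤ −0.75, and interchangeable drugs (identical coverage
   of ≤2 modules) collapse into one class slot.

A whole-signature baseline (`igcm`) — one up/down DEG query per fold-change
threshold — and evaluation machinery (accuracy/specificity against a
reference anti-tumor list; reproducibility |A∩B|/√(|A|·|B|) under repeated
20+20 subsampling) are included for comparison.

## Worked example

The bundled reference dataset is a published 46-drug function–drug
association screen for colorectal adenoma. Enumerating its therapeutic
compounds:

```bash
fmcm compounds --out compounds.tsv
```

prints `16 compounds -> compounds.tsv`; the table begins

```
compound  n_components  components                degree_ratio
1         2             GW-8510 + IS              7:1
2         2             phenoxybenzamine + IS     7:1
3         4             apigenin + At+CC + IS + ST  4:2:1:1
```

Reading: of the 46 screened drugs, 41 are purely beneficial and 5 carry at
least one harmful link; two drugs (phenoxybenzamine, GW-8510) are beneficial
to seven of the eight disease functions, and each forms a 2-component
compound with the immune-system interchangeability class (triflusal /
morantel / ginkgolide A / cetirizine / imipenem — any one of these covers
the remaining function). Every listed compound covers all eight functions
exactly once, so its degree ratio sums to 8.

An end-to-end run on synthetic data:

```bash
fmcm simulate --seed 3 --out inputs/
fmcm run-all --in inputs/ --out run/ --seed 3
```

writes the condition networks, DEG table, module GMT, per-module
connectivity scores, FDAM and compounds under `run/`, each stamped with the
configuration hash; re-running with the same seed reproduces every file
byte for byte.

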