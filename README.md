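# tippingnet

Early-warning analysis of critical transitions in cancer, on
patient-specific molecular networks.

Complex diseases often deteriorate abruptly: the system drifts through a
reversible *pre-disease* state and then tips into the disease state at a
critical point. The dynamic-network-biomarker (DNB) theory predicts that,
near this tipping point, a small *dominant group* of genes appears whose
members (1) fluctuate strongly, (2) become tightly correlated with each
other, and (3) decouple from the rest of the network. `tippingnet`
implements an end-to-end pipeline that localizes this transition along
each patient's somatic-mutation timeline, for cohorts with paired
tumor/tumor-adjacent expression, somatic mutation calls, and a background
protein–protein interaction (PPI) network. It is aimed at computational
biologists studying tumor progression and at anyone who wants a fully
testable, synthetic-data-backed reference implementation of the
mutation-ordering + DNB methodology.

## Method

1. **Patient-specific networks.** The global PPI network (preprocessed:
   de-duplicated, self-interactions and isolated nodes removed) is
   filtered per patient: an interaction survives iff both endpoint genes
   are expressed in at least one of the two tissues (tumor, adjacent).
2. **Mutation-effect propagation.** Each mutated gene present in the
   patient network seeds a random walk with restart (RWR),

   P<sub>t+1</sub> = (1 − r) M P<sub>t</sub> + r P<sub>0</sub>,

   with M the column-normalized adjacency, restart probability r = 0.7,
   and max-norm convergence tolerance 10⁻¹⁰. Genes with stationary score
   \> 0.001 form the seed's *propagation module*; the largest connected
   component of the union of a patient's modules is the mutant **giant
   cluster (GC)**, which typically covers nearly all seeds.
3. **Mutation ordering.** A greedy selection rule generates one mutation
   sequence per non-driver initial seed: at each step, among unmutated
   seeds whose module overlaps the current module union, pick the one
   minimizing the size of the merged connected cluster. Counting pairwise
   precedences across sequences gives a precedence matrix
   C\[i]\[j]; Copeland scoring turns it into a per-patient driver order,
   and summing matrices over patients of one consensus molecular subtype
   (CMS) gives the subtype consensus order.
4. **Criticality index and transition point.** For each driver step k,
   candidate genes (union of the first k drivers' modules, inside the
   GC) are filtered for differential expression, clustered by k-medoids
   on 1 − |Pearson r|, and the cluster maximizing the **criticality
   index**

   CI = size × SD<sub>i</sub> × PCC<sub>i</sub> / PCC<sub>o</sub>

   (mean member SD × mean within-group |r| / mean group-to-background
   |r|, computed across patients on log2 tumor/adjacent ratios) is the
   step's dominant group, trimmed to its coherent core. The CI peak over
   steps is the patient's **transition point**; its dominant group is the
   patient's DNB. Transition order is validated against clinical stage
   within each subtype.
5. **Enrichment and target mining.** GCs are tested against gene-set
   collections (upper-tail hypergeometric, Benjamini–Hochberg), profiles
   compared between subtypes (exact rank-sum), and candidate drug
   targets nominated: DNB genes lying on a directed pathway path between
   two drivers whose pathway orientation matches the consensus mutation
   order.

A synthetic-cohort generator plants a known driver order, DNB group and
transition step, so every stage is tested against ground truth without
any external downloads.

## Worked example

Generate a 300-gene, 24-patient synthetic cohort and run the full
pipeline:

```bash
tippingnet simulate --seed 11 --out cohort
# wrote cohort: 300 genes, 597 interactions, 24 patients -> cohort

cat > run.yaml <<'YAML'
inputs:
  ppi: cohort/ppi.tsv
  expression: cohort/expression.tsv
  manifest: cohort/manifest.tsv
  mutations: cohort/mutations.tsv
  clinical: cohort/clinical.tsv
  drivers: cohort/drivers.txt
  gene_sets: cohort/sets.gmt
  pathways: cohort/pathways
output: results
YAML

tippingnet run --config run.yaml
# build-networks: 24 records
# propagate: 348 records
# gc: 24 records
# order: 240 records
# consensus: 4 records
# dnb: 24 records
# validate: 36 records
# enrich: 480 records
# targets: 6 records
# parameter hash: 03361cf7f182b7a8
```

`results/dnb.json` holds each patient's CI series and transition point.
For patient P005 the CI rises along the driver sequence and peaks
sharply at step 5:

```json
"ci": [3.87, 4.99, 6.13, 6.67, 31.93],
"transition_step": 5,
"dnb_genes": ["G0017", "G0058", "G0088", "G0153", "G0252", "G0279"]
```

The cohort's `truth.json` confirms the planted transition step was 5 and
the planted DNB group is exactly the six genes detected — the ~5× CI jump
at the transition step is the early-warning signal the method looks for.
`results/targets.tsv` nominates DNB genes (e.g. G0017) sitting between
two drivers on a pathway whose direction matches the mutation order, and
`results/validation.json` reports the fraction of within-subtype patient
pairs whose transition order is consistent with clinical stage.

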