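# ragprint

DNA footprints of off-target V(D)J recombination at structural-variant
breakpoints, for genomics of *BCR-ABL1* B-lymphoblastic leukemia — plus the
companion single-cell cell-cycle/diversity metrics and residual-disease
log-reduction calls used alongside them.

## The problem

Secondary deletions that cooperate with *BCR-ABL1* (in *IKZF1*, *PAX5*,
*CDKN2A/B*, ...) are frequently created by the lymphoid recombination
machinery acting off-target.  Two enzymes leave diagnostic footprints at an
SV junction:

* **RAG1/2** cleaves at cryptic recombination signal sequences — the
  heptamer `CACAGTG` (reverse complement `CACTGTG`) or close variants —
  sitting immediately *inside* each breakpoint.  An SV is called **RSS+**
  when qualifying motifs flank both breakpoints within 30 bp, with four
  exception rules for less-conserved or more-distant motifs near recurrent
  breakpoint clusters.
* **TdT** adds non-template (N) nucleotides, biased toward G:C, during
  repair.  Each junction is decomposed into **NTS insertion**,
  **microhomology**, or **clean** by maximizing attribution of the junction
  contig to the two reference flanks.

Cohort-level, the package computes RSS+ fractions by SV category with an
exact test of association, fits the breakpoint-to-motif distances with a
maximum-likelihood negative binomial `NB(r, p)`, counts RAG-mediated SVs
(cooperating ∧ RSS+) per sample with a rank-sum group comparison, and
annotates breakpoints against BED interval tracks.  The single-cell module
implements QC and leukemic-marker filtering, gene-set scoring (mean log2
normalized expression), G0/G1S/G2M phase assignment at pooled mean+1SD
cutoffs, cycling fractions, and the Shannon index `H = −Σ pᵢ ln pᵢ` of
lineage annotations.  The response module computes base-10 log reductions
of *BCR-ABL1* transcript relative to the diagnostic baseline and classifies
major (≥3) and deep (≥4) molecular responses.

A seeded synthetic-data module generates full cohorts with planted truth —
reference, SVs with assembled junctions, breakpoint clusters (including
allowlist-motif and motif-less rescue cases), UMI matrices with planted
phases/lineages/QC failures, and response trajectories — so every stage is
testable without controlled-access data.  See `docs/methods.md` for the
model and all conventions.

## Worked example

Run the analysis chain on a simulated cohort (each script reads the previous
one's outputs under `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_rss_classification.py
python analysis/03_junction_calls.py
```

which prints:

```
SV cohort: 650 SVs (390 planted RAG-mediated, 110 non-RAG cooperating, 150 translocation-like) -> results/cohort
...
405/650 SVs RSS+; 3 breakpoint clusters
sensitivity on planted RAG SVs:      0.982
specificity on motif-free SVs:       0.975
rules among RSS+ calls: {'cluster_rescue': 2, 'base': 315, 'exception4': 4, 'exception1': 39, 'exception2': 45}
motif accounting: 808 motifs = 2*405 - 2 rescued breakpoints
stratum            n    %NTS   mean_len   %GC
cooperating RSS+   386   93.8      5.56    65.8
cooperating RSS-   114   64.0      6.12    67.6
translocation      150    8.0      2.58    74.2
```

Reading: 98.2% of planted RAG-mediated SVs are recovered as RSS+ and 97.5%
of motif-free SVs as RSS−; every RSS+ SV contributes one best motif per
breakpoint except the two cluster-rescued breakpoints (hence
808 = 2×405 − 2).  Junction decomposition recovers the TdT footprint: ~94%
of RSS+ cooperating SVs carry an NTS insertion of mean ~5.6 nt, about
two-thirds G:C, while translocation-like junctions are ~92% clean.
`04_cohort_statistics.py`, `05_cell_cycle_diversity.py` and
`06_molecular_response.py` continue with the NB distance fit (r ≈ 1.1,
mean ≈ 8.5 bp), per-sample RAG-SV burden by group, per-sample cycling
fractions and Shannon indices, and MMR/DMR calls.

The same steps are available as a CLI (`ragprint simulate / rss classify /
junctions call / stats / sc / response / run`) and as library functions
(`ragprint.classify_cohort`, `ragprint.call_junction`, ...).

## Layout

```
src/ragprint/      library: sv_catalog, rss, junctions, cohort_stats,
                   sc_metrics, response, simulate, pipeline, cli
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    model, conventions, generator design, limitations
```
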