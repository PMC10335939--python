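#!/usr/bin/env python
"""Generate the synthetic study cohort with planted truth.

Writes, under --outdir/cohort: the reference FASTA, the SV table, the truth
registry, the cluster-motif allowlist and sample groups; under
--outdir/cohort/sc the single-cell bundle (MTX triplet, gene sets, cluster
labels, per-cell truth); and the residual-disease series.  Downstream
analysis scripts read these files, so the whole analysis runs off disk the
same way it would on real inputs.
"""

import argparse
from pathlib import Path

import pandas as pd

from ragprint.simulate import (
    GeneratorConfig,
    gen_response_series,
    gen_sc_matrix,
    simulate_sv_cohort,
    write_response_table,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = GeneratorConfig(seed=args.seed)
    outdir = args.outdir / "cohort"

    cohort = simulate_sv_cohort(cfg)
    cohort.write(outdir)
    n_rag = sum(t.is_rag for t in cohort.truth.values())
    print(f"SV cohort: {len(cohort.svs)} SVs "
          f"({n_rag} planted RAG-mediated, "
          f"{cfg.n_nonrag_svs} non-RAG cooperating, "
          f"{cfg.n_translocation_svs} translocation-like) -> {outdir}")

    matrix, sc_truth, gene_sets, cluster_labels = gen_sc_matrix(cfg)
    sc_dir = outdir / "sc"
    matrix.to_mtx_dir(sc_dir)
    sc_truth.to_csv(sc_dir / "truth.tsv", sep="\t")
    with open(sc_dir / "gene_sets.gmt", "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + genes) + "\n")
    pd.Series(cluster_labels).rename("cluster").rename_axis("cell").to_csv(
        sc_dir / "clusters.tsv", sep="\t"
    )
    print(f"single-cell bundle: {len(matrix.cells)} cells x "
          f"{len(matrix.genes)} genes -> {sc_dir}")

    series, resp_truth = gen_response_series(cfg)
    write_response_table(series, outdir / "response.tsv")
    resp_truth.to_csv(outdir / "response_truth.tsv", sep="\t")
    print(f"residual-disease series: {len(series)} patients -> "
          f"{outdir / 'response.tsv'}")


if __name__ == "__main__":
    main()
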