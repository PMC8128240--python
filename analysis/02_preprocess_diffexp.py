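"""Merge the per-study sets, adjust batch effects, and run differential
expression with hierarchical clustering on the DE genes.

Reads the per-study TSVs written by 01_simulate_meta.py (regenerating them
if absent), merges on the common gene core, applies empirical-Bayes batch
adjustment protecting the sepsis/non-sepsis contrast, flags differential
genes at |logFC| >= 1 and BH-adjusted p < 0.05, and cuts the Ward
dendrogram of samples at three clusters.
"""

from pathlib import Path

import pandas as pd

import sepsismeta as sm

SCRATCH = Path("scratch/data")
RESULTS = Path("results")
FIXTURE_SEED = 7


def load_or_generate():
    tsvs = sorted(SCRATCH.glob("study*_expression.tsv"))
    if tsvs:
        sets = [
            sm.ExpressionSet.from_tsv(p, p.with_name(p.name.replace("expression", "metadata")))
            for p in tsvs
        ]
        return sets
    sets, _ = sm.generate_meta_expression(sm.default_fixture_config(seed=FIXTURE_SEED))
    return sets


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    Path("scratch").mkdir(exist_ok=True)
    merged = sm.merge_series(load_or_generate())
    labels = sm.consolidate_labels(merged.metadata)
    print(f"Merged set: {merged.n_genes} genes x {merged.n_samples} samples "
          f"({(labels == 'sepsis').mean():.1%} sepsis).")

    adjusted, model = sm.combat_adjust(
        merged, covariate=labels, return_model=True
    )
    model.to_json("scratch/batch_model.json")  # bulky audit record

    de = sm.differential_expression(adjusted, labels)
    de.to_csv("scratch/de_results.csv")
    n_de = int(de["is_de"].sum())
    print(f"Differential expression: {n_de} of {len(de)} genes flagged "
          f"(|logFC| >= 1, BH-adjusted p < 0.05).")

    top = de[de["is_de"]].reindex(
        de[de["is_de"]]["p_adj"].sort_values().index
    ).head(20)
    top.to_csv(RESULTS / "top_de_genes.csv")

    clustering = sm.hierarchical_cluster(adjusted, de.index[de["is_de"]], k=3)
    clustering.composition.to_csv(RESULTS / "cluster_composition.csv")
    print("Sample clustering on DE genes (3 clusters):")
    print(clustering.composition.to_string())


if __name__ == "__main__":
    main()
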