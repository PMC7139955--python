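"""Normalize a count cohort and recover its gene modules by clustering.

Upper-quartile normalizes the simulated counts over generally detected
genes, log2-transforms, centers each gene, and agglomerates genes with
centroid linkage under correlation distance.  Cutting the dendrogram at
height 0.5 (correlation ~0.5) separates tight co-expression modules
from the uncorrelated background; each module is annotated with its
dominant immunome classes.
"""

from immunosig import (
    ImmunomeModel,
    SimulationConfig,
    center_genes,
    extract_modules,
    hierarchical_cluster,
    log2_transform,
    simulate_expression,
    upper_quartile_normalize,
)

cohort = simulate_expression(SimulationConfig(seed=1))
normalized, log = upper_quartile_normalize(cohort.expression)
print(f"detected genes: {len(log.detected_genes)} / {cohort.expression.n_genes}")

centered = center_genes(log2_transform(normalized))
dendrogram = hierarchical_cluster(centered, axis="genes", linkage="centroid")
modules, unassigned = extract_modules(
    dendrogram, height=0.5, min_size=3, matrix=centered,
    immunome=ImmunomeModel.default(),
)

truth = cohort.truth["membership"]
for mod in modules:
    classes = ", ".join(mod.dominant_classes[:2]) or "unannotated"
    true_labels = {truth.get(g, "background") for g in mod.genes}
    print(
        f"{mod.name}: {len(mod.genes)} genes, mean within-module r = "
        f"{mod.mean_within_correlation:.2f}, dominant classes: {classes}, "
        f"true membership: {sorted(true_labels)}"
    )
print(f"unassigned (below min size): {len(unassigned)} genes")
# Every recovered module is pure with respect to the generating
# membership.  The large cytotoxic-lymphocyte module may split into
# submodules, and background genes that share cancer-type baseline
# structure can form a loose (low within-r) cluster of their own —
# both behaviors mirror what pan-cancer matrices actually do.
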