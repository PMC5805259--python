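"""Independent oracles and random-structure generators used by the tests."""

import numpy as np

from oralvirome.taxonomy import TaxonNode, TaxonomyTree


def brute_force_filter(hits, thresholds):
    """Row-by-row threshold scan, written independently of filter_hits."""
    kept = []
    for h in hits:
        ok = True
        if not (h.e_value < thresholds.max_evalue):
            ok = False
        if not (h.percent_identity >= thresholds.min_identity):
            ok = False
        if not (h.alignment_length / h.query_length >= thresholds.min_coverage):
            ok = False
        if ok:
            kept.append(h)
    return kept


def random_taxonomy(rng: np.random.Generator, max_nodes: int = 50) -> TaxonomyTree:
    """A random rank-complete forest with ≤ max_nodes nodes and one subject
    per species."""
    nodes = []
    subjects = {}
    n_orders = int(rng.integers(1, 4))
    counter = 0
    for o in range(n_orders):
        order_id = f"O{o}"
        nodes.append(TaxonNode(order_id, f"order{o}", "order", None))
        counter += 1
        for f in range(int(rng.integers(1, 4))):
            family_id = f"{order_id}F{f}"
            if counter >= max_nodes:
                break
            nodes.append(TaxonNode(family_id, f"fam{f}", "family", order_id))
            counter += 1
            for g in range(int(rng.integers(1, 4))):
                genus_id = f"{family_id}G{g}"
                if counter >= max_nodes:
                    break
                nodes.append(TaxonNode(genus_id, f"gen{g}", "genus", family_id))
                counter += 1
                for s in range(int(rng.integers(1, 4))):
                    species_id = f"{genus_id}S{s}"
                    if counter >= max_nodes:
                        break
                    nodes.append(
                        TaxonNode(species_id, f"sp{s}", "species", genus_id)
                    )
                    counter += 1
                    subjects[f"ref|{species_id}"] = (species_id, "bacteriophage")
    return TaxonomyTree(nodes, subjects)


def lca_oracle(tree: TaxonomyTree, taxon_ids):
    """Deepest common node by walking root-to-tip paths in parallel, an
    implementation route distinct from set intersection over ancestor sets.

    Returns None when the paths share no node at all.
    """
    paths = []
    for taxon_id in taxon_ids:
        path = []
        current = taxon_id
        while current is not None:
            path.append(current)
            current = tree.nodes[current].parent_id
        paths.append(list(reversed(path)))  # root → tip
    deepest = None
    for level in range(min(len(p) for p in paths)):
        first = paths[0][level]
        if all(p[level] == first for p in paths):
            deepest = first
        else:
            break
    return deepest
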