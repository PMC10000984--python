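"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the library's algorithms: the LCA oracle
intersects lineage sets, the consensus oracle enumerates every node and
counts covering lineages, and the filter oracle evaluates each predicate
explicitly.  They are only practical at fixture scale.
"""

from __future__ import annotations

import random

from consenstax.taxonomy import TaxNode, Taxonomy


def brute_lca(tax: Taxonomy, taxids) -> int:
    """Deepest node present in every lineage (set intersection)."""
    common = None
    for t in taxids:
        ids = {n.taxid for n in tax.lineage(t)}
        common = ids if common is None else common & ids
    return max(common, key=lambda t: (tax.depth(t), t))


def brute_consensus(tax: Taxonomy, taxids, level: float) -> int:
    """Enumerate all nodes, count covering lineages, pick the deepest
    qualifying one (votes count with multiplicity)."""
    n = len(taxids)
    lineages = [{nd.taxid for nd in tax.lineage(t)} for t in taxids]
    qualifying = [
        node
        for node in tax.nodes
        if sum(node in l for l in lineages) / n >= level
    ]
    return max(qualifying, key=lambda t: (tax.depth(t), t))


def brute_hard_filter(hits, max_evalue, min_pident, min_qcov):
    """Explicit predicate evaluation, one hit at a time."""
    kept = []
    for h in hits:
        ok_e = h.evalue <= max_evalue
        ok_p = h.pident >= min_pident
        cov = 100.0 * (h.qend - h.qstart + 1) / h.qlen
        ok_c = cov >= min_qcov - 1e-9
        if ok_e and ok_p and ok_c:
            kept.append(h)
    return kept


def random_taxonomy(rng: random.Random, n_nodes: int) -> Taxonomy:
    """Random rooted tree: node i attaches to a uniformly chosen earlier node."""
    nodes = {1: TaxNode(1, 1, "no rank", "root")}
    ids = [1]
    ranks = ["no rank", "family", "genus", "species"]
    for i in range(2, n_nodes + 1):
        parent = rng.choice(ids)
        nodes[i] = TaxNode(i, parent, rng.choice(ranks), f"node_{i}")
        ids.append(i)
    return Taxonomy(nodes)


def random_votes(rng: random.Random, tax: Taxonomy, max_len: int = 8) -> list[int]:
    ids = list(tax.nodes)
    return [rng.choice(ids) for _ in range(rng.randint(1, max_len))]
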