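"""Seeded generator of small heterogeneous module networks with planted
structure.

The generator emulates the statistical features the prioritization method
exploits in real data: cohesive protein complexes (planted dense modules on
a heavy-tailed background interactome), disease genes concentrated in one
"causal" module per disease, and an incomplete observed interaction network
(a fraction of true edges hidden uniformly at random — exactly the edges
length-3-path augmentation has a chance to recover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import AssociationSet, GeneGraph, ModuleSet


@dataclass
class SynthConfig:
    """Study conditions for one synthetic instance.

    Defaults give a 200-gene, 20-disease network with 10 planted modules,
    20% of true interactions hidden (edge_dropout) and 80% of each disease's
    genes drawn from its causal module (module_bias).
    """

    n_genes: int = 200
    n_diseases: int = 20
    n_modules: int = 10
    module_size_min: int = 8
    module_size_max: int = 15
    intra_module_p: float = 0.6
    background_attach: int = 2
    assoc_per_disease: int = 8
    module_bias: float = 0.8
    edge_dropout: float = 0.2
    heldout_fraction: float = 0.4
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.intra_module_p, self.module_bias, self.edge_dropout,
                  self.heldout_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_genes, self.n_diseases, self.n_modules,
               self.module_size_min, self.assoc_per_disease) < 1:
            raise ValueError("sizes must be positive")
        if self.module_size_max < self.module_size_min:
            raise ValueError("module_size_max < module_size_min")


def generate(
    config: SynthConfig,
) -> tuple[GeneGraph, GeneGraph, ModuleSet, AssociationSet, AssociationSet]:
    """Generate (full graph, observed graph, modules, train, heldout).

    The observed graph is the full graph minus an `edge_dropout` fraction of
    edges chosen uniformly; the removed edges are the augmentation-
    recoverable ground truth (full.edges - observed.edges). Associations are
    split per disease into train and heldout, disjoint by construction.
    Everything is reproducible from `config.seed`.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    genes = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    diseases = [f"d{i:03d}" for i in range(config.n_diseases)]

    # planted disjoint modules of random sizes
    sizes = rng.integers(
        config.module_size_min, config.module_size_max + 1, size=config.n_modules
    )
    if sizes.sum() > config.n_genes:
        raise ValueError(
            f"module sizes sum to {sizes.sum()} but only {config.n_genes} genes exist"
        )
    perm = rng.permutation(config.n_genes)
    modules: dict[str, set[str]] = {}
    pos = 0
    for m, size in enumerate(sizes):
        members = {genes[i] for i in perm[pos:pos + size]}
        modules[f"M{m:02d}"] = members
        pos += size
    module_set = ModuleSet(modules)

    full = GeneGraph(nodes=set(genes))
    # dense intra-module structure
    for members in modules.values():
        mem = sorted(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                if rng.random() < config.intra_module_p:
                    full.add_edge(mem[i], mem[j])
    # heavy-tailed background: each gene attaches to partners with
    # probability proportional to (degree + 1), preferential-attachment style
    deg = {g: 0 for g in genes}
    for a, b in full.edges:
        deg[a] += 1
        deg[b] += 1
    order = list(rng.permutation(config.n_genes))
    for gi in order:
        g = genes[gi]
        weights = np.asarray([deg[h] + 1 for h in genes], dtype=np.float64)
        weights[gi] = 0.0
        weights /= weights.sum()
        partners = rng.choice(
            config.n_genes, size=config.background_attach, replace=False, p=weights
        )
        for pj in partners:
            h = genes[pj]
            if not full.has_edge(g, h):
                full.add_edge(g, h)
                deg[g] += 1
                deg[h] += 1

    # observed graph: hide a uniform fraction of true edges
    edges = sorted(full.edges)
    n_drop = int(round(config.edge_dropout * len(edges)))
    drop_idx = set(rng.choice(len(edges), size=n_drop, replace=False)) if n_drop else set()
    observed = GeneGraph(nodes=set(genes))
    for i, (a, b) in enumerate(edges):
        if i not in drop_idx:
            observed.add_edge(a, b)

    # module-correlated disease associations, split train/heldout per disease
    module_ids = sorted(modules)
    train_pairs: set[tuple[str, str]] = set()
    heldout_pairs: set[tuple[str, str]] = set()
    for d in diseases:
        causal = modules[module_ids[rng.integers(len(module_ids))]]
        causal_sorted = sorted(causal)
        n_causal = min(int(round(config.module_bias * config.assoc_per_disease)),
                       len(causal_sorted))
        picked = {causal_sorted[i] for i in
                  rng.choice(len(causal_sorted), size=n_causal, replace=False)}
        others = sorted(set(genes) - picked)
        n_rest = config.assoc_per_disease - len(picked)
        if n_rest > 0:
            picked |= {others[i] for i in
                       rng.choice(len(others), size=n_rest, replace=False)}
        picked_sorted = sorted(picked)
        rng.shuffle(picked_sorted)
        n_held = min(len(picked_sorted) - 1,
                     max(1, int(round(config.heldout_fraction * len(picked_sorted)))))
        for g in picked_sorted[:n_held]:
            heldout_pairs.add((d, g))
        for g in picked_sorted[n_held:]:
            train_pairs.add((d, g))

    return (full, observed, module_set,
            AssociationSet(train_pairs), AssociationSet(heldout_pairs))
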