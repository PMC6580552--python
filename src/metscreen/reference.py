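"""Reference evaluator: recursive substitution on acyclic networks.

Independent of the iterative engine in :mod:`metscreen.simulate`; used as a
cross-check.  Builds the component dependency graph with networkx, requires it
to be acyclic, and evaluates every non-gene component once in topological
order using plain Python arithmetic.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx

from .network import MetabolicModel


def dataflow_reference(model: MetabolicModel, initial: Mapping[str, float]) -> dict[str, float]:
    """Topological-order substitution; raises on cyclic networks."""
    gene_ids = {c.id for c in model.genes()}
    producers: dict[str, list] = {c.id: [] for c in model.components}
    g = nx.DiGraph()
    g.add_nodes_from(producers)
    for r in model.reactions:
        for prod in r.products:
            if prod.component_id in gene_ids:
                continue  # genes are clamped sources
            producers[prod.component_id].append(r)
            for reac in r.reactants:
                g.add_edge(reac.component_id, prod.component_id)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("reference evaluator requires an acyclic network") from exc

    values = {c.id: 0.0 for c in model.components}
    for cid in gene_ids:
        values[cid] = float(initial.get(cid, 0.0))
    for cid in order:
        if cid in gene_ids:
            continue
        total = 0.0
        for r in producers[cid]:
            flux = r.law.effective_rate()
            for reac in r.reactants:
                flux *= values[reac.component_id] ** reac.role
            for prod in r.products:
                if prod.component_id == cid:
                    total += flux * prod.role
        values[cid] = total
    return values
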