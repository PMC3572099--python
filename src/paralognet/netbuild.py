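"""Assemble the full hub + kinase + substrate network and compare the seven
paralog subnetworks by Jaccard similarity of their partner sets.

A *partner* of a paralog is a direct neighbour of its hub node.  The optional
kinase layer adds, per subnetwork, any kinase or kinase substrate adjacent to
a partner (one extra hop, restricted to kinase-tagged nodes and their
substrate neighbours), mirroring how the kinase/substrate layer was grafted
onto the client network at full-network level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationBundle, LoadResult
from .model import AnnotatedNetwork, Interaction

logger = logging.getLogger(__name__)

__all__ = [
    "ISOFORM_LABELS",
    "ParalogNetwork",
    "assemble_full_network",
    "extract_paralog_subnetwork",
    "jaccard_matrix",
]

#: canonical ordering of the seven paralog labels
ISOFORM_LABELS = ("beta", "gamma", "epsilon", "eta", "sigma", "theta", "zeta")


@dataclass
class ParalogNetwork:
    """One paralog's subnetwork view over the full network."""

    isoform: str
    hub_id: str
    partner_ids: set[str]
    node_ids: set[str]
    edges: list[Interaction]
    parent: AnnotatedNetwork = field(repr=False, default=None)

    @property
    def partners(self) -> list:
        return [self.parent.proteins[p] for p in sorted(self.partner_ids)]

    def protein(self, pid: str):
        return self.parent.proteins[pid]


def assemble_full_network(
    interactions: LoadResult | list[Interaction],
    annotations: AnnotationBundle | None,
    isoform_id_map: dict[str, str],
) -> AnnotatedNetwork:
    """Build the annotated full network.

    ``isoform_id_map`` maps paralog label -> hub accession.  Every protein
    referenced by at least one retained edge becomes a node; annotations from
    the bundle are merged in deterministically.
    """
    edges = list(interactions)
    iso_ids = [isoform_id_map[lab] for lab in sorted(isoform_id_map, key=_label_order)]
    net = AnnotatedNetwork(isoform_ids=iso_ids)
    for e in edges:
        net.add_edge(e)
    present = set(net.proteins)
    for lab, acc in isoform_id_map.items():
        if acc not in present:
            logger.warning("isoform %s (%s) absent from interaction table", lab, acc)
    if annotations is not None:
        for rec in net.proteins.values():
            annotations.apply(rec)
    return net


def _label_order(label: str) -> int:
    return ISOFORM_LABELS.index(label) if label in ISOFORM_LABELS else len(ISOFORM_LABELS)


def extract_paralog_subnetwork(
    net: AnnotatedNetwork,
    isoform: str,
    isoform_id_map: dict[str, str],
    include_kinase_layer: bool = False,
) -> ParalogNetwork:
    """Partner set = direct neighbours of the hub node (other hubs excluded).

    With ``include_kinase_layer``, nodes adjacent to a partner that are
    kinases, or substrates of a kinase partner, join ``node_ids`` together
    with the connecting edges.
    """
    if isoform not in isoform_id_map:
        raise KeyError(
            f"unknown isoform {isoform!r}; valid labels: {sorted(isoform_id_map)}"
        )
    hub = isoform_id_map[isoform]
    if hub not in net.proteins:
        raise KeyError(f"isoform node {hub!r} not present in network")
    hubs = set(isoform_id_map.values())
    partner_ids = net.neighbors(hub) - hubs
    node_ids = set(partner_ids)
    if include_kinase_layer:
        for p in partner_ids:
            p_is_kinase = net.proteins[p].is_kinase
            for nb in net.neighbors(p):
                if nb in hubs or nb in partner_ids:
                    continue
                if net.proteins[nb].is_kinase or p_is_kinase:
                    node_ids.add(nb)
    keep = node_ids | {hub}
    edges = [e for e in net.edges if e.a in keep and e.b in keep]
    return ParalogNetwork(
        isoform=isoform,
        hub_id=hub,
        partner_ids=partner_ids,
        node_ids=node_ids,
        edges=edges,
        parent=net,
    )


def jaccard_matrix(paralog_networks: list[ParalogNetwork], on: str = "partners") -> pd.DataFrame:
    """Symmetric matrix of Jaccard coefficients between subnetwork node sets.

    ``on`` selects the compared sets: ``partners`` (direct neighbours of the
    hub, the default) or ``nodes`` (partners plus the kinase layer).
    An empty-vs-empty pair is defined as 0 and logged.
    """
    if len(paralog_networks) < 2:
        raise ValueError("need at least two paralog networks to compare")
    labels = [p.isoform for p in paralog_networks]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate isoform labels: {labels}")
    sets = {
        p.isoform: (p.partner_ids if on == "partners" else p.node_ids)
        for p in paralog_networks
    }
    m = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        union = sets[a] | sets[b]
        if not union:
            logger.warning("both %s and %s have empty sets; Jaccard defined as 0", a, b)
            j = 0.0
        else:
            j = len(sets[a] & sets[b]) / len(union)
        m.loc[a, b] = m.loc[b, a] = j
    return m
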