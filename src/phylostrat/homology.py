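"""Collapsing pfam instances into independent homology datapoints.

Homologous sequences share an origin, so treating each instance as a
datapoint is pseudoreplication.  Every retained pfam therefore contributes
a single datapoint: the unweighted mean of each property across all of its
instances (optionally restricted to one kingdom's instances).  Full genes
are grouped by their oldest pfam; when several pfams tie for oldest, genes
are grouped by a co-occurrence cluster id instead — two pfams are linked
when P(both | either) >= 50% over all genes, and links are closed under
single-link clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_pfam",
    "aggregate_datapoints",
    "cooccurrence_link",
    "single_link_groups",
    "gene_homology_key",
]


def aggregate_pfam(
    instances: pd.DataFrame,
    metric_cols: Sequence[str],
    scope: str = "all",
    clade_col: str = "clade",
) -> pd.Series:
    """Average one pfam's instances into a single datapoint.

    ``scope`` is ``"all"`` or a clade label; missing metric values (e.g. an
    undefined clustering index) are excluded from that metric's mean, with
    the number of contributing instances recorded per metric.
    """
    if scope != "all":
        instances = instances[instances[clade_col] == scope]
    if instances.empty:
        raise ValueError(f"no instances in scope {scope!r}")
    out = {}
    for col in metric_cols:
        vals = instances[col].dropna()
        out[col] = vals.mean() if len(vals) else np.nan
        out[f"n_{col}"] = len(vals)
    out["n_instances"] = len(instances)
    out["n_species"] = instances["species_id"].nunique()
    return pd.Series(out)


def aggregate_datapoints(
    instances: pd.DataFrame,
    metric_cols: Sequence[str],
    key_col: str = "pfam_id",
    scope: str = "all",
    clade_col: str = "clade",
) -> pd.DataFrame:
    """One datapoint per key (pfam or gene homology group)."""
    if scope != "all":
        instances = instances[instances[clade_col] == scope]
    grouped = instances.groupby(key_col, sort=True)
    rows = {
        key: aggregate_pfam(grp, metric_cols, scope="all", clade_col=clade_col)
        for key, grp in grouped
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = key_col
    return df


def cooccurrence_link(
    gene_pfams: Mapping[str, set[str]], pfam_a: str, pfam_b: str
) -> bool:
    """Link two pfams when P(AB | A or B) >= 50% over all genes."""
    with_a = {g for g, ps in gene_pfams.items() if pfam_a in ps}
    with_b = {g for g, ps in gene_pfams.items() if pfam_b in ps}
    union = with_a | with_b
    if not union:
        raise ValueError(f"neither {pfam_a} nor {pfam_b} occurs in any gene")
    both = with_a & with_b
    return 2 * len(both) >= len(union)


def single_link_groups(
    links: Iterable[tuple[str, str]], pfams: Iterable[str] = ()
) -> dict[str, str]:
    """Single-link clustering of the pfam link graph.

    Returns a mapping pfam -> group id, where the group id is the
    lexicographically smallest member, making ids deterministic and
    independent of link-list order.  ``pfams`` may list additional
    singletons with no links.
    """
    graph = nx.Graph()
    graph.add_nodes_from(pfams)
    graph.add_edges_from(links)
    mapping: dict[str, str] = {}
    for component in nx.connected_components(graph):
        gid = min(component)
        for member in component:
            mapping[member] = gid
    return mapping


def gene_homology_key(
    gene_pfams: Sequence[str],
    pfam_ages: Mapping[str, float],
    groups: Mapping[str, str],
) -> str:
    """Homology key for one gene: its oldest pfam, or that pfam's group on ties.

    When equally-oldest pfams fall in different (unlinked) groups the
    smallest group id wins, with a warning — ties across groups have no
    principled owner.
    """
    if not gene_pfams:
        raise ValueError("gene has no pfams")
    ages = {p: pfam_ages[p] for p in gene_pfams}
    oldest = max(ages.values())
    tied = sorted(p for p, a in ages.items() if a == oldest)
    if len(tied) == 1:
        return tied[0]
    gids = sorted({groups.get(p, p) for p in tied})
    if len(gids) > 1:
        logger.warning(
            "equally-oldest pfams %s span groups %s; assigning smallest", tied, gids
        )
    return gids[0]
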