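"""Topological role classification: Direct Parent vs Upstream Hub markers.

Direct Parent SNPs (DPSs) are the trait's parents in the final ancestral
graph; since the trait is constrained to have no children, they are exactly
its Markov blanket.  Upstream Hub SNPs (UHSs) are non-parent nodes with
high directed out-degree — pleiotropic upstream regulators whose influence
reaches the trait only through mediating markers.  Edge weights quantify
direct effects: each child is regressed on its parents in a deterministic
DAG extension of the CPDAG, all variables standardised, and the absolute
standardised coefficient is attached to the edge.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pc_graph import CPDAG

logger = logging.getLogger(__name__)

__all__ = ["classify_roles", "edge_weights", "out_degree_ranking"]

_TIE_COLS = ["out_degree", "total_degree", "marker_id"]


def _degree_table(g: CPDAG, trait: str) -> pd.DataFrame:
    rows = []
    for v in g.nodes:
        if v == trait:
            continue
        out_deg = sum(1 for u, w in g.directed_edges if u == v and w != trait)
        rows.append({
            "marker_id": v,
            "out_degree": out_deg,
            "total_degree": len(g.neighbors(v)),
        })
    df = pd.DataFrame(rows, columns=["marker_id", "out_degree", "total_degree"])
    return df.sort_values(_TIE_COLS, ascending=[False, False, True],
                          kind="stable").reset_index(drop=True)


def out_degree_ranking(g: CPDAG, trait: str | None = None) -> pd.DataFrame:
    """Nodes ordered by directed out-degree (edges into the trait excluded
    when a trait node is given), tie-broken by total degree then marker ID."""
    if not g.nodes:
        return pd.DataFrame(columns=["marker_id", "out_degree", "total_degree"])
    return _degree_table(g, trait if trait is not None else "\x00")


def classify_roles(g: CPDAG, trait: str, uhs_min_out_degree: int = 2,
                   uhs_top_k: int | None = None) -> pd.DataFrame:
    """Role table over the final ancestral graph.

    DPS: direct parents of the trait.  UHS: non-parents ranked by directed
    out-degree (edges into the trait excluded), retained when the out-degree
    reaches ``uhs_min_out_degree`` (or the top ``uhs_top_k`` by ranking).
    Everything else is labelled "other".  Ranks are unique within a role.
    """
    if trait not in set(g.nodes):
        raise KeyError(f"trait node {trait!r} not in graph")
    dps = set(g.parents(trait))
    table = _degree_table(g, trait)
    table["role"] = "other"
    table.loc[table["marker_id"].isin(dps), "role"] = "DPS"

    nonparent = table[table["role"] != "DPS"]
    if uhs_top_k is not None:
        uhs_ids = nonparent["marker_id"].head(uhs_top_k)
    else:
        uhs_ids = nonparent.loc[nonparent["out_degree"] >= uhs_min_out_degree,
                                "marker_id"]
    table.loc[table["marker_id"].isin(set(uhs_ids)), "role"] = "UHS"

    table["edge_weight_to_child"] = [
        g.edge_weights.get((mid, trait), np.nan) for mid in table["marker_id"]
    ]
    table["rank"] = table.groupby("role").cumcount() + 1
    order = pd.Categorical(table["role"], categories=["DPS", "UHS", "other"],
                           ordered=True)
    table = table.assign(_o=order).sort_values(["_o", "rank"], kind="stable")
    return table.drop(columns="_o").reset_index(drop=True)


def edge_weights(g: CPDAG, data: pd.DataFrame, ridge: float = 1e-6) -> CPDAG:
    """Annotate a CPDAG with direct-effect magnitudes.

    The CPDAG is first extended to one DAG of its equivalence class
    (deterministic Dor-Tarsi extension, logged when the fallback fires);
    each child is then regressed on its DAG parents with all variables
    standardised, and the edge weight is the absolute standardised
    coefficient.  Multicollinear parent sets fall back to a small ridge
    penalty.  Weights are attached to the returned copy of the graph
    (undirected edges keep their orientation only for weighting purposes).
    """
    dag = g.consistent_extension()
    vals = data.copy()
    for col in vals.columns:
        v = vals[col].to_numpy(dtype=float)
        sd = v.std()
        vals[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)

    out = g.copy()
    out.edge_weights = {}
    for child in dag.nodes:
        parents = dag.parents(child)
        parents = [p for p in parents if p in vals.columns]
        if not parents or child not in vals.columns:
            continue
        Xp = vals[parents].to_numpy()
        yv = vals[child].to_numpy()
        gram = Xp.T @ Xp
        try:
            coef = np.linalg.solve(gram, Xp.T @ yv)
        except np.linalg.LinAlgError:
            logger.warning("collinear parents of %s; ridge fallback", child)
            coef = np.linalg.solve(gram + ridge * len(yv) * np.eye(len(parents)),
                                   Xp.T @ yv)
        for parent, c in zip(parents, coef):
            out.edge_weights[(parent, child)] = float(abs(c))
    return out


def concentric_layout(roles: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Coordinates for the concentric "sunflower" rendering: trait at the
    origin, DPS ring at radius 1, UHS ring at radius 2, others at 3."""
    radius = {"DPS": 1.0, "UHS": 2.0, "other": 3.0}
    rows = [{"node": trait, "x": 0.0, "y": 0.0, "ring": "trait"}]
    for role, grp in roles.groupby("role", sort=False):
        ids = list(grp["marker_id"])
        r = radius[str(role)]
        for k, mid in enumerate(ids):
            angle = 2 * np.pi * k / max(len(ids), 1)
            rows.append({"node": mid, "x": r * np.cos(angle),
                         "y": r * np.sin(angle), "ring": str(role)})
    return pd.DataFrame(rows)
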