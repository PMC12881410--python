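"""Readers and writers for the pipeline's tabular and graph formats.

Dosage matrices travel as TSV/CSV with individuals in rows and marker IDs in
columns ("chr{C}.{H}_{POS}" convention); phenotypes as TSV keyed by genotype
ID.  An optional VCF reader (cyvcf2) accepts a dosage FORMAT field (DS) or
sums GT alleles for tetraploid calls.  Graphs are written as GraphML,
edge-list TSV and DOT.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

_MARKER_RE = re.compile(r"^chr([0-9A-Za-z]+)\.(\d+)[._](\d+)$")


def parse_marker_id(marker_id: str) -> tuple[str | None, int | None, int | None]:
    """Parse "chr{C}.{H}_{POS}" (or the dot-separated variant) into
    (chromosome, homolog-set tag, position); ``(None, None, None)`` if the ID
    does not follow the convention."""
    m = _MARKER_RE.match(marker_id)
    if m is None:
        return None, None, None
    return m.group(1), int(m.group(2)), int(m.group(3))


def marker_positions(marker_ids: Iterable[str]) -> pd.DataFrame:
    """Chromosome/position table for Manhattan ordering.

    Unparseable IDs keep their input order on a pseudo-chromosome sorted last.
    """
    rows = []
    for idx, mid in enumerate(marker_ids):
        chrom, _hom, pos = parse_marker_id(mid)
        if chrom is None:
            rows.append((mid, "zz_unplaced", idx))
        else:
            rows.append((mid, chrom, pos))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"]).set_index("marker_id")


# ---------------------------------------------------------------------------
# tabular I/O


def read_dosage(path: str | Path) -> pd.DataFrame:
    """Read a dosage matrix (TSV or CSV by extension); first column is the
    individual ID, header row holds marker IDs.  Missing calls may be empty
    or NA."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_dosage(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index_label="individual_id")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: first column genotype ID, remaining columns traits."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_phenotype(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="genotype_id")


def read_plot_table(path: str | Path) -> pd.DataFrame:
    """Plot-level trait table with columns genotype_id, replicate, row,
    column, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype_id", "row", "column", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    return df


def read_vcf_dosage(path: str | Path) -> pd.DataFrame:
    """Read tetraploid dosages from a VCF.

    Uses the DS FORMAT field when present, otherwise sums alternative alleles
    in GT (expected ploidy 4).  Marker IDs come from the ID column, falling
    back to "chr{CHROM}.1_{POS}".
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, columns = [], []
    for variant in vcf:
        if variant.ID and variant.ID != ".":
            mid = variant.ID
        else:
            chrom = variant.CHROM[3:] if variant.CHROM.startswith("chr") else variant.CHROM
            mid = f"chr{chrom}.1_{variant.POS}"
        fmts = variant.FORMAT
        if "DS" in fmts:
            ds = np.asarray(variant.format("DS"), dtype=float).reshape(len(samples))
        else:
            gt = np.asarray(variant.genotype.array(), dtype=float)
            alleles = gt[:, :-1]  # last column is phasing
            alleles[alleles < 0] = np.nan
            ds = np.nansum(alleles, axis=1)
            ds[np.all(np.isnan(alleles), axis=1)] = np.nan
        ids.append(mid)
        columns.append(ds)
    return pd.DataFrame(np.column_stack(columns) if columns else np.empty((len(samples), 0)),
                        index=pd.Index(samples, name="individual_id"), columns=ids)


# ---------------------------------------------------------------------------
# graph I/O


def graph_to_edgelist(g) -> pd.DataFrame:
    """Edge-list table (source, target, directed, weight) for a CPDAG."""
    rows = []
    for u, v in sorted(g.directed_edges):
        rows.append((u, v, True, g.edge_weights.get((u, v), np.nan)))
    for e in sorted(tuple(sorted(e)) for e in g.undirected_edges):
        rows.append((e[0], e[1], False, np.nan))
    return pd.DataFrame(rows, columns=["source", "target", "directed", "weight"])


def write_graph(g, prefix: str | Path, roles: pd.DataFrame | None = None) -> None:
    """Write a CPDAG as GraphML, edge-list TSV and DOT under ``prefix``."""
    import networkx as nx

    prefix = Path(prefix)
    nxg = g.to_networkx()
    if roles is not None:
        role_map = roles.set_index("marker_id")["role"].to_dict()
        outdeg = roles.set_index("marker_id")["out_degree"].to_dict()
        for node in nxg.nodes:
            nxg.nodes[node]["role"] = str(role_map.get(node, "trait"))
            nxg.nodes[node]["out_degree"] = int(outdeg.get(node, 0))
    nx.write_graphml(nxg, str(prefix) + ".graphml")
    graph_to_edgelist(g).to_csv(str(prefix) + ".edges.tsv", sep="\t", index=False)
    _write_dot(g, str(prefix) + ".dot")


def _write_dot(g, path: str | Path) -> None:
    lines = ["digraph cpdag {"]
    for node in g.nodes:
        lines.append(f'  "{node}";')
    for u, v in sorted(g.directed_edges):
        w = g.edge_weights.get((u, v))
        attr = f' [label="{w:.3f}"]' if w is not None else ""
        lines.append(f'  "{u}" -> "{v}"{attr};')
    for e in sorted(tuple(sorted(e)) for e in g.undirected_edges):
        lines.append(f'  "{e[0]}" -> "{e[1]}" [dir=none];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
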