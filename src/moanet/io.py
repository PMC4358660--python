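"""Readers and writers for the plain-text formats the pipeline consumes.

Edge lists (2-column TSV or 3-column SIF), expression tables, spectral-count
tables, GMT gene-set collections, dose–response matrix CSVs, screen plate
CSVs, fingerprint TSVs of 0/1 strings, and the JSON truth manifest emitted
next to simulated fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .assay import DoseResponseMatrix
from .network import clean_network
from .synthetic import SyntheticTruth


# -- interaction networks ---------------------------------------------------

def read_edge_list(path: str | Path) -> nx.Graph:
    """Undirected network from a 2-column TSV (header optional) or SIF file.

    SIF rows carry an interaction type in the middle column, which is
    ignored.  Self-loops are dropped and duplicate edges collapsed.
    """
    graph = nx.Graph()
    with open(path) as handle:
        for line_no, line in enumerate(handle):
            fields = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:
                a, _, b = fields
            else:
                raise ValueError(f"{path}:{line_no + 1}: expected 2 or 3 columns")
            if line_no == 0 and {a.lower(), b.lower()} & {"gene_a", "gene_b", "source", "target"}:
                continue  # header
            graph.add_edge(a, b)
    return clean_network(graph)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            handle.write(f"{a}\t{b}\n")


def write_weighted_edge_list(wnet: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_a\tgene_b\tweight\n")
        for (a, b), data in sorted(
            ((tuple(sorted((u, v))), d) for u, v, d in wnet.edges(data=True))
        ):
            handle.write(f"{a}\t{b}\t{data.get('weight', 1.0):.10g}\n")


# -- expression & spectral counts ------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV with gene_id, fpkm_control, fpkm_treated and/or fold_change."""
    table = pd.read_csv(path, sep="\t").set_index("gene_id")
    known = {"fpkm_control", "fpkm_treated", "fold_change"}
    if not known & set(table.columns):
        raise ValueError(f"{path}: no expression columns found")
    return table


def write_expression(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index_label="gene_id")


def read_spectral_counts(path: str | Path) -> pd.DataFrame:
    """Seed TSV: (gene_id, sc_immobilized, sc_competition) or (gene_id, strength)."""
    table = pd.read_csv(path, sep="\t").set_index("gene_id")
    if "strength" in table.columns:
        return table
    if {"sc_immobilized", "sc_competition"} <= set(table.columns):
        return table
    raise ValueError(f"{path}: expected spectral-count or strength columns")


def write_spectral_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


# -- gene sets --------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set]:
    """GMT: term_id <tab> description <tab> member genes...  Flat sets only."""
    collection: dict[str, set] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no + 1}: GMT rows need >= 3 columns")
            term_id, _description, *members = fields
            if term_id in collection:
                raise ValueError(f"{path}: duplicate term {term_id!r}")
            members = {m for m in members if m}
            if not members:
                raise ValueError(f"{path}: term {term_id!r} has no members")
            collection[term_id] = members
    return collection


def write_gmt(collection: dict[str, set], path: str | Path) -> None:
    with open(path, "w") as handle:
        for term_id in sorted(collection):
            members = "\t".join(sorted(collection[term_id]))
            handle.write(f"{term_id}\t{term_id}\t{members}\n")


# -- dose-response matrices -------------------------------------------------

def read_dose_response(path: str | Path) -> DoseResponseMatrix:
    """Matrix CSV: first row/column are dose labels, cell (0,0) untreated."""
    table = pd.read_csv(path, index_col=0)
    table.index = table.index.astype(float)
    table.columns = table.columns.astype(float)
    return DoseResponseMatrix(table)


def write_dose_response(drm: DoseResponseMatrix, path: str | Path) -> None:
    drm.viability.to_csv(path)


# -- screen plates & fingerprints ------------------------------------------

def read_plates(path: str | Path) -> pd.DataFrame:
    plates = pd.read_csv(path)
    expected = {"plate_id", "well_id", "compound_id", "replicate", "signal"}
    missing = expected - set(plates.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return plates


def write_plates(plates: pd.DataFrame, path: str | Path) -> None:
    plates.to_csv(path, index=False)


def read_fingerprints(path: str | Path) -> pd.DataFrame:
    """Fingerprint TSV: compound_id <tab> bitstring of 0/1."""
    rows = []
    ids = []
    length = None
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("compound_id"):
            handle.seek(0)
        for line_no, line in enumerate(handle):
            if not line.strip():
                continue
            compound_id, bits = line.rstrip("\n").split("\t")
            if set(bits) - {"0", "1"}:
                raise ValueError(f"{path}:{line_no + 1}: bitstring must be 0/1")
            if length is None:
                length = len(bits)
            elif len(bits) != length:
                raise ValueError(f"{path}: unequal fingerprint lengths")
            ids.append(compound_id)
            rows.append([int(c) for c in bits])
    return pd.DataFrame(
        rows,
        index=pd.Index(ids, name="compound_id"),
        columns=[f"bit{j}" for j in range(length or 0)],
    )


def write_fingerprints(fps: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("compound_id\tbits\n")
        for compound_id, row in fps.iterrows():
            handle.write(f"{compound_id}\t{''.join(str(int(b)) for b in row)}\n")


# -- truth manifest ---------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_module": sorted(truth.planted_module),
        "planted_term_id": truth.planted_term_id,
        "module_anchors": list(truth.module_anchors),
        "true_hits": sorted(truth.true_hits),
        "true_clusters": truth.true_clusters,
        "synergy_flag": truth.synergy_flag,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_module=set(payload.get("planted_module", [])),
        planted_term_id=payload.get("planted_term_id"),
        module_anchors=list(payload.get("module_anchors", [])),
        true_hits=set(payload.get("true_hits", [])),
        true_clusters=dict(payload.get("true_clusters", {})),
        synergy_flag=payload.get("synergy_flag"),
    )


def write_fixture(fixture: dict, outdir: str | Path) -> dict[str, Path]:
    """Write a complete simulated input directory plus the truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "targets": outdir / "targets.tsv",
        "genesets": outdir / "genesets.gmt",
        "truth": outdir / "truth.json",
    }
    write_edge_list(fixture["network"], paths["network"])
    write_expression(fixture["expression"], paths["expression"])
    write_spectral_counts(fixture["targets"], paths["targets"])
    write_gmt(fixture["genesets"], paths["genesets"])
    write_truth(fixture["truth"], paths["truth"])
    return paths
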