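"""Plain-text serialization: expression/class TSVs, pathway-set JSON, results.

All formats are diff-able text.  Expression TSV: first column gene id,
header row of sample ids, tab-separated floats.  Class TSV: one
``sample<TAB>class`` line per sample (optional third column: pairing key
for matched designs), exactly two distinct classes.  Pathway sets are a
JSON document holding, per pathway, the node list, edge list, gene
annotations and the grid arrangement.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import GridEmbedding, LatticeGrid
from .expression import ExpressionMatrix
from .network import PathwayNetwork
from .preprocess import PreprocessedPathway
from .stats import PathwayResult

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_classes_tsv",
    "write_classes_tsv",
    "read_expression",
    "pathway_set_to_json",
    "pathway_set_from_json",
    "save_pathway_set",
    "load_pathway_set",
    "results_to_frame",
    "write_results_tsv",
    "read_results_tsv",
]

PATHWAY_SET_SCHEMA_VERSION = 1


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None  # writer labels the column "gene"; keep round trips exact
    df.columns = df.columns.astype(str)
    return df


def write_expression_tsv(values: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees binary64 round trips through the text file
    values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_classes_tsv(path: str | Path) -> tuple[dict[str, str], dict[str, str] | None]:
    """Sample-to-class map plus the optional pairing column."""
    labels: dict[str, str] = {}
    pairs: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected sample<TAB>class")
        labels[parts[0]] = parts[1]
        if len(parts) > 2 and parts[2]:
            pairs[parts[0]] = parts[2]
    if len(set(labels.values())) != 2:
        raise ValueError(
            f"{path}: expected exactly two classes, found {sorted(set(labels.values()))}"
        )
    return labels, (pairs if pairs else None)


def write_classes_tsv(labels: dict[str, str], path: str | Path,
                      pairs: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for sample, cls in labels.items():
            if pairs and sample in pairs:
                fh.write(f"{sample}\t{cls}\t{pairs[sample]}\n")
            else:
                fh.write(f"{sample}\t{cls}\n")


def read_expression(expr_path: str | Path, classes_path: str | Path) -> ExpressionMatrix:
    """Load expression and class files into an ExpressionMatrix."""
    values = read_expression_tsv(expr_path)
    labels, pairs = read_classes_tsv(classes_path)
    missing = [s for s in labels if s not in values.columns]
    if missing:
        raise ValueError(f"samples in class file missing from expression: {missing}")
    values = values[[s for s in values.columns if s in labels]]
    return ExpressionMatrix(values=values, class_labels=labels, pairs=pairs)


def _pathway_to_dict(pw: PreprocessedPathway) -> dict:
    net, emb = pw.network, pw.embedding
    return {
        "pathway_id": net.pathway_id,
        "title": net.title,
        "kind": net.kind,
        "nodes": list(net.nodes),
        "edges": [list(e) for e in net.edges],
        "node_genes": {v: sorted(g) for v, g in net.node_genes.items()},
        "grid": {
            "rows": emb.grid.rows,
            "cols": emb.grid.cols,
            "placement": {v: list(rc) for v, rc in emb.placement.items()},
            "total_length": emb.total_length,
            "optimal": emb.optimal,
        },
    }


def _pathway_from_dict(d: dict) -> PreprocessedPathway:
    nodes = list(d["nodes"])
    pos = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    for u, v in d["edges"]:
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = 1
    net = PathwayNetwork(
        pathway_id=d["pathway_id"],
        nodes=nodes,
        node_genes={v: frozenset(g) for v, g in d["node_genes"].items()},
        adjacency=a,
        title=d.get("title", ""),
        kind=d.get("kind", "metabolic"),
    )
    g = d["grid"]
    emb = GridEmbedding(
        grid=LatticeGrid(rows=g["rows"], cols=g["cols"]),
        placement={v: (int(r), int(c)) for v, (r, c) in g["placement"].items()},
        total_length=int(g["total_length"]),
        optimal=bool(g["optimal"]),
    )
    return PreprocessedPathway(network=net, embedding=emb)


def pathway_set_to_json(pathways: list[PreprocessedPathway]) -> str:
    doc = {
        "schema_version": PATHWAY_SET_SCHEMA_VERSION,
        "pathways": [_pathway_to_dict(p) for p in pathways],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def pathway_set_from_json(text: str) -> list[PreprocessedPathway]:
    doc = json.loads(text)
    return [_pathway_from_dict(d) for d in doc["pathways"]]


def save_pathway_set(pathways: list[PreprocessedPathway], path: str | Path) -> None:
    Path(path).write_text(pathway_set_to_json(pathways))


def load_pathway_set(path: str | Path) -> list[PreprocessedPathway]:
    return pathway_set_from_json(Path(path).read_text())


_RESULT_COLUMNS = [
    "pathway_id", "title", "score", "p_value", "p_adjusted",
    "n_up", "n_nochange", "n_down", "best_shift", "best_level",
    "best_section_row", "best_section_col", "best_kind",
]


def results_to_frame(results: list[PathwayResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        shift, level, sr, sc, kind = r.best_key
        rows.append([
            r.pathway_id, r.title, r.score, r.p_value, r.p_adjusted,
            r.n_up, r.n_nochange, r.n_down, shift, level, sr, sc, kind,
        ])
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results_tsv(results: list[PathwayResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
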