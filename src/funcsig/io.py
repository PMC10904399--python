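"""Readers and writers for the tab-delimited formats the package consumes.

GMT gene-set collections, two-column ontology hierarchies, GCT-like
expression matrices, long-format signature tables, embedding tables and
prediction/benchmark exports.  All formats are plain text and round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .graph import Hyperedge
from .signature import GeneSignature, SignatureVector

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_hierarchy",
    "write_hierarchy",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_signature_table",
    "write_signature_table",
    "write_stationary_profiles",
    "write_signature_vector",
    "write_predictions",
]


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """GMT: one set per line — id, free-text description, then members.
    Gene ids are case-sensitive; duplicates within a line are preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    out: dict[str, tuple[str, list[str]]] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 columns): {line!r}")
        out[parts[0]] = (parts[1], parts[2:])
    return out


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, genes) in sets.items():
            fh.write("\t".join([sid, desc, *genes]) + "\n")


def gmt_to_hyperedges(sets: Mapping[str, tuple[str, Iterable[str]]],
                      hierarchy: Mapping[str, Iterable[str]] | None = None
                      ) -> list[Hyperedge]:
    """Hyperedges from a GMT collection; ``hierarchy`` maps child id ->
    parent ids and is inverted into per-edge children sets."""
    children: dict[str, set[str]] = {sid: set() for sid in sets}
    if hierarchy:
        for child, parents in hierarchy.items():
            for p in parents:
                if p in children and child in sets:
                    children[p].add(child)
    return [Hyperedge(sid, frozenset(genes), frozenset(children[sid]))
            for sid, (_, genes) in sets.items()]


def read_hierarchy(path: str | Path) -> dict[str, list[str]]:
    """Two-column tab-delimited child_id -> parent_id table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hierarchy file not found: {path}")
    out: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        child, parent = line.split("\t")[:2]
        out.setdefault(child, []).append(parent)
    return out


def write_hierarchy(hierarchy: Mapping[str, Iterable[str]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for child, parents in hierarchy.items():
            for p in parents:
                fh.write(f"{child}\t{p}\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Tab-delimited genes x samples matrix; also accepts the GCT dialect
    (two header lines starting '#1.2' and dimensions, description column)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    first = path.read_text().splitlines()[0]
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        df = df.drop(columns=[c for c in ("Description", "description")
                              if c in df.columns])
        return df
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(df: pd.DataFrame, path: str | Path,
                            gct: bool = False) -> None:
    if gct:
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", df.index)
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        df.to_csv(path, sep="\t")


_SIG_COLUMNS = ["perturbagen_id", "perturbagen_type", "cell_line", "tas",
                "signature_id", "gene"]


def read_signature_table(path: str | Path) -> list[GeneSignature]:
    """Long-format signature table: one row per (signature, gene)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = set(_SIG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"signature table missing columns: {sorted(missing)}")
    sigs = []
    for (pid, ptype, cell, tas, sid), grp in df.groupby(
            ["perturbagen_id", "perturbagen_type", "cell_line", "tas",
             "signature_id"], sort=True):
        sigs.append(GeneSignature(frozenset(grp.gene), pid, ptype, cell,
                                  float(tas), sid))
    return sigs


def write_signature_table(signatures: Iterable[GeneSignature],
                          path: str | Path) -> None:
    rows = [{"perturbagen_id": s.perturbagen_id,
             "perturbagen_type": s.perturbagen_type,
             "cell_line": s.cell_line, "tas": s.tas,
             "signature_id": s.signature_id, "gene": g}
            for s in signatures for g in sorted(s.genes)]
    pd.DataFrame(rows, columns=_SIG_COLUMNS).to_csv(path, sep="\t", index=False)


def write_stationary_profiles(profiles, universe, path: str | Path) -> None:
    """Tab-delimited (source, gene, probability) rows."""
    with open(path, "w") as fh:
        fh.write("source\tgene\tprobability\n")
        for prof in profiles:
            for g, p in zip(universe.genes, prof.distribution):
                fh.write(f"{prof.source}\t{g}\t{p!r}\n")


def write_signature_vector(sv: SignatureVector, path: str | Path) -> None:
    """Vector as one tab-delimited row; per-gene weight ledger in a
    .weights.tsv sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(repr(float(x)) for x in sv.vector) + "\n")
    side = path.with_suffix(path.suffix + ".weights.tsv")
    rows = [{"gene": r.gene, "r_ontology": r.r_ontology,
             "r_expression": r.r_expression, "z_ontology": r.z_ontology,
             "z_expression": r.z_expression, "weight": r.weight}
            for r in sv.per_gene]
    pd.DataFrame(rows).to_csv(side, sep="\t", index=False)


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    """Prediction table: compound_id, target_gene, cell_line,
    perturbagen_type, probability."""
    cols = ["compound_id", "target_gene", "cell_line", "perturbagen_type",
            "probability"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    df[cols].to_csv(path, sep="\t", index=False)
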