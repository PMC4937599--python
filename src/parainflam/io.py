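"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices are TSV (genes as rows, header = sample ids) with an
optional GCT 1.2 flavor; gene lists are one symbol per line with ``#``
comments; models and signatures serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .datatypes import (
    CountMatrix,
    ExpressionMatrix,
    GeneList,
    ParainflamError,
    PISignature,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------- expression

def read_expression_tsv(
    path: PathLike, annotations: Optional[PathLike] = None
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = None
    ann = read_annotations_tsv(annotations) if annotations else None
    return ExpressionMatrix(values, ann)


def write_expression_tsv(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_gct(path: PathLike) -> ExpressionMatrix:
    """Read a GCT 1.2 file (two header lines, then NAME/Description/samples)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "1.2"):
            raise ParainflamError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        table = pd.read_csv(fh, sep="\t", index_col=0)
    table = table.drop(columns=[table.columns[0]])  # Description column
    table.index.name = None
    if table.shape != (n_genes, n_samples):
        raise ParainflamError(
            f"GCT dimensions {table.shape} disagree with header {(n_genes, n_samples)}"
        )
    return ExpressionMatrix(table)


def write_gct(expr: ExpressionMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.values.shape[0]}\t{expr.values.shape[1]}\n")
        out = expr.values.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="NAME")


def read_annotations_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_annotations_tsv(ann: pd.DataFrame, path: PathLike) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id")


# -------------------------------------------------------------------- counts

def read_counts(counts_path: PathLike, conditions_path: PathLike) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    cond = pd.read_csv(conditions_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts, cond)


def write_counts(cm: CountMatrix, counts_path: PathLike, conditions_path: PathLike) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.conditions.rename("condition").to_csv(
        conditions_path, sep="\t", index_label="sample_id"
    )


# ---------------------------------------------------------------- gene lists

def read_gene_list(path: PathLike, name: Optional[str] = None) -> GeneList:
    """One symbol per line; ``#`` starts a comment; blank lines ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return GeneList(name or Path(path).stem, genes, source=str(path))


def write_gene_list(gl: GeneList, path: PathLike) -> None:
    Path(path).write_text("\n".join(gl.genes) + "\n")


# ----------------------------------------------------------------- signature

def signature_to_dict(sig: PISignature) -> dict:
    def _gl(gl: Optional[GeneList]):
        if gl is None:
            return None
        d = {"name": gl.name, "genes": gl.genes, "source": gl.source}
        if gl.annotations is not None:
            d["annotations"] = gl.annotations.to_dict()
        return d

    return {
        "species": sig.species,
        "up": _gl(sig.up),
        "down": _gl(sig.down),
        "expanded": _gl(sig.expanded),
    }


def signature_from_dict(d: dict) -> PISignature:
    def _gl(sub):
        if sub is None:
            return None
        ann = sub.get("annotations")
        return GeneList(
            sub["name"],
            sub["genes"],
            sub.get("source", ""),
            pd.Series(ann) if ann else None,
        )

    return PISignature(
        up=_gl(d["up"]),
        down=_gl(d.get("down")),
        expanded=_gl(d.get("expanded")),
        species=d.get("species", "mouse"),
    )


def write_signature(sig: PISignature, path: PathLike) -> None:
    Path(path).write_text(json.dumps(signature_to_dict(sig), indent=1))


def read_signature(path: PathLike) -> PISignature:
    return signature_from_dict(json.loads(Path(path).read_text()))


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=float))


__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gct",
    "write_gct",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_counts",
    "write_counts",
    "read_gene_list",
    "write_gene_list",
    "write_signature",
    "read_signature",
    "signature_to_dict",
    "signature_from_dict",
    "write_json",
]
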