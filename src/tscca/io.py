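"""Readers and writers for every external representation the pipeline touches.

All tabular formats are TSV (UTF-8); gene sets may also come as GMT
lines; tensors persist in HDF5 with labelled axes.  Readers are strict:
nothing is silently coerced, and every rejection names the offending
row/column.  Every reader/writer pair is a lossless round trip at 1e-12
for numeric payloads and exact for labels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Module, ModuleSet, SparsityParams
from .errors import FormatError, ParameterError, ParseError, ValidationError
from .tensor import CorrelationTensor, ExpressionMatrix

__all__ = [
    "AnnotationBundle",
    "SurvivalTable",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_edge_list",
    "write_edge_list",
    "read_gene_set",
    "read_family_table",
    "read_survival_tsv",
    "write_survival_tsv",
    "read_tensor_hdf5",
    "write_tensor_hdf5",
    "write_module_tables",
    "read_module_tables",
]


@dataclass
class AnnotationBundle:
    """Optional annotation inputs: cancer sets, families, interaction edges."""

    cancer_genes: set[str] = field(default_factory=set)
    cancer_mirnas: set[str] = field(default_factory=set)
    families: dict[str, set[str]] = field(default_factory=dict)
    mirna_gene_edges: set[tuple[str, str]] = field(default_factory=set)
    gene_gene_edges: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        for e in self.gene_gene_edges:
            if len(e) != 2:
                raise ValidationError(f"self-loop or malformed gene-gene edge: {set(e)}")
        for a, b in self.mirna_gene_edges:
            if not a or not b:
                raise ValidationError("edge endpoints must be nonempty strings")


@dataclass
class SurvivalTable:
    """Per-sample follow-up: (sample_id, time >= 0, event in {0, 1})."""

    records: list[tuple[str, float, int]]

    def __post_init__(self) -> None:
        seen = set()
        for sid, t, e in self.records:
            if sid in seen:
                raise ValidationError(f"duplicate sample id in survival table: {sid!r}")
            seen.add(sid)
            if t < 0:
                raise ValidationError(f"negative survival time for sample {sid!r}: {t}")
            if e not in (0, 1):
                raise ValidationError(f"event for sample {sid!r} must be 0 or 1, got {e}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["sample", "time", "event"])


def _read_lines(source) -> list[str]:
    return Path(source).read_text(encoding="utf-8").splitlines()


def read_expression_tsv(source, orientation: str = "features_as_rows",
                        ) -> ExpressionMatrix:
    """Read a TSV expression table into samples × features orientation.

    The default genomics convention is features as rows: first column
    holds feature ids, header holds sample ids; ``samples_as_rows``
    flips the interpretation.  Parsing is strict — any non-numeric cell
    is an error naming its row and column (1-based, data cells).
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    lines = [ln for ln in _read_lines(source) if ln != ""]
    if len(lines) < 2:
        raise FormatError(f"{source}: need a header and at least one data row")
    header = lines[0].split("\t")
    col_ids = [c.strip() for c in header[1:]]
    ncol = len(header)
    row_ids: list[str] = []
    data: list[list[float]] = []
    for r, ln in enumerate(lines[1:], start=1):
        parts = ln.split("\t")
        if len(parts) != ncol:
            raise FormatError(
                f"{source}: row {r} has {len(parts)} fields, expected {ncol}"
            )
        row_ids.append(parts[0].strip())
        row = []
        for c, cell in enumerate(parts[1:], start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{source}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
        data.append(row)
    values = np.array(data, dtype=float)
    if orientation == "features_as_rows":
        return ExpressionMatrix(values.T, sample_ids=col_ids, feature_ids=row_ids)
    return ExpressionMatrix(values, sample_ids=row_ids, feature_ids=col_ids)


def write_expression_tsv(E: ExpressionMatrix, destination,
                         orientation: str = "features_as_rows") -> None:
    """Inverse of :func:`read_expression_tsv` (full float precision)."""
    if orientation == "features_as_rows":
        df = pd.DataFrame(E.values.T, index=E.feature_ids, columns=E.sample_ids)
        df.index.name = "feature"
    elif orientation == "samples_as_rows":
        df = pd.DataFrame(E.values, index=E.sample_ids, columns=E.feature_ids)
        df.index.name = "sample"
    else:
        raise ParameterError(f"unknown orientation {orientation!r}")
    df.to_csv(destination, sep="\t", float_format="%.17g")


def read_edge_list(source, directed: bool):
    """Read a 2-column TSV edge list ('#' lines are comments).

    Duplicate edges collapse; for undirected lists (a, b) and (b, a)
    collapse to one unordered pair (self-loops are rejected there).
    Returns ``(edges, nodes)``: a set of 2-tuples (directed) or
    frozensets (undirected), and the node set.
    """
    edges: set = set()
    nodes: set[str] = set()
    for r, ln in enumerate(_read_lines(source), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) != 2:
            raise FormatError(
                f"{source}: line {r} has {len(parts)} fields, expected 2"
            )
        a, b = parts
        if not a or not b:
            raise FormatError(f"{source}: empty endpoint at line {r}")
        nodes.update((a, b))
        if directed:
            edges.add((a, b))
        else:
            if a == b:
                raise FormatError(f"{source}: self-loop {a!r} at line {r}")
            edges.add(frozenset((a, b)))
    return edges, nodes


def write_edge_list(edges, destination) -> None:
    rows = sorted(tuple(sorted(e)) if isinstance(e, frozenset) else e
                  for e in edges)
    with open(destination, "w", encoding="utf-8") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_gene_set(source) -> set[str]:
    """Read ids from a one-per-line file or GMT lines (name, desc, members)."""
    out: set[str] = set()
    for ln in _read_lines(source):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) >= 3:  # GMT: set name, description, members...
            out.update(p.strip() for p in parts[2:] if p.strip())
        else:
            out.add(parts[0])
    return out


def read_family_table(source) -> dict[str, set[str]]:
    """Read (family_id, member) TSV into a family -> member-set mapping."""
    fams: dict[str, set[str]] = {}
    for r, ln in enumerate(_read_lines(source), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) != 2:
            raise FormatError(
                f"{source}: line {r} has {len(parts)} fields, expected 2"
            )
        fam, member = parts
        fams.setdefault(fam, set()).add(member)
    return fams


def read_survival_tsv(source) -> SurvivalTable:
    """Read (sample, time, event) TSV; a header line is auto-detected."""
    records = []
    lines = [ln for ln in _read_lines(source) if ln.strip()
             and not ln.lstrip().startswith("#")]
    for r, ln in enumerate(lines, start=1):
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) != 3:
            raise FormatError(
                f"{source}: line {r} has {len(parts)} fields, expected 3"
            )
        if r == 1:
            try:
                float(parts[1])
            except ValueError:
                continue  # header
        try:
            t = float(parts[1])
            e = int(parts[2])
        except ValueError:
            raise ParseError(
                f"{source}: unparseable time/event at line {r}: {parts[1:]!r}"
            ) from None
        records.append((parts[0], t, e))
    return SurvivalTable(records)


def write_survival_tsv(table: SurvivalTable, destination) -> None:
    with open(destination, "w", encoding="utf-8") as fh:
        fh.write("sample\ttime\tevent\n")
        for sid, t, e in table.records:
            fh.write(f"{sid}\t{t:.17g}\t{e}\n")


def write_tensor_hdf5(tensor: CorrelationTensor, destination) -> None:
    """Persist a labelled tensor: /tensor (p×q×M), /genes, /mirnas, /cancers."""
    with h5py.File(destination, "w") as f:
        f.create_dataset("tensor", data=tensor.values)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("genes", data=tensor.gene_ids, dtype=str_dt)
        f.create_dataset("mirnas", data=tensor.mirna_ids, dtype=str_dt)
        f.create_dataset("cancers", data=tensor.cancer_ids, dtype=str_dt)
        if tensor.sample_counts is not None:
            f.create_dataset("sample_counts", data=np.asarray(tensor.sample_counts))
        f.attrs["built_from_data"] = bool(tensor.built_from_data)


def read_tensor_hdf5(source) -> CorrelationTensor:
    with h5py.File(source, "r") as f:
        values = f["tensor"][()]
        genes = [x.decode() if isinstance(x, bytes) else str(x) for x in f["genes"][()]]
        mirnas = [x.decode() if isinstance(x, bytes) else str(x) for x in f["mirnas"][()]]
        cancers = [x.decode() if isinstance(x, bytes) else str(x) for x in f["cancers"][()]]
        counts = (list(map(int, f["sample_counts"][()]))
                  if "sample_counts" in f else None)
        built = bool(f.attrs.get("built_from_data", True))
    return CorrelationTensor(values, genes, mirnas, cancers,
                             sample_counts=counts, built_from_data=built)


_SUMMARY = "modules_summary.tsv"
_LONG = "modules_long.tsv"


def write_module_tables(modules: ModuleSet, tensor_labels, destination) -> None:
    """Write a fitted ModuleSet as two TSVs under ``destination``.

    ``modules_summary.tsv`` has one row per module (id, singular value,
    support sizes, iterations, converged); ``modules_long.tsv`` holds
    every nonzero weight as (module_id, axis, element_id, weight).
    ``tensor_labels`` supplies the axis ids, e.g. the CorrelationTensor
    the modules were fitted to.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    genes = tensor_labels.gene_ids
    mirnas = tensor_labels.mirna_ids
    cancers = tensor_labels.cancer_ids
    srows = []
    lrows = []
    for mid, m in enumerate(modules.modules, start=1):
        I, J, K = m.supports()
        srows.append((mid, m.d, len(I), len(J), len(K), m.iterations,
                      int(m.converged)))
        for i in I:
            lrows.append((mid, "gene", genes[i], m.u[i]))
        for j in J:
            lrows.append((mid, "miRNA", mirnas[j], m.v[j]))
        for k in K:
            lrows.append((mid, "cancer", cancers[k], m.w[k]))
    pd.DataFrame(
        srows, columns=["module_id", "singular_value", "n_genes", "n_mirnas",
                        "n_cancers", "iterations", "converged"],
    ).to_csv(dest / _SUMMARY, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        lrows, columns=["module_id", "axis", "element_id", "weight"],
    ).to_csv(dest / _LONG, sep="\t", index=False, float_format="%.17g")


def read_module_tables(source, tensor_labels) -> ModuleSet:
    """Rebuild factors and supports from :func:`write_module_tables` output.

    Only what the tables carry is reconstructed: u, v, w, d and the
    supports.  The residual tensor is not persisted, so the returned
    set carries a zero residual; sparsity params are inferred as the
    maximum support sizes.
    """
    src = Path(source)
    summary = pd.read_csv(src / _SUMMARY, sep="\t")
    long = pd.read_csv(src / _LONG, sep="\t")
    gidx = {g: i for i, g in enumerate(tensor_labels.gene_ids)}
    midx = {m: j for j, m in enumerate(tensor_labels.mirna_ids)}
    cidx = {c: k for k, c in enumerate(tensor_labels.cancer_ids)}
    p, q, M = len(gidx), len(midx), len(cidx)
    modules = []
    for _, row in summary.iterrows():
        mid = row["module_id"]
        u = np.zeros(p)
        v = np.zeros(q)
        w = np.zeros(M)
        sub = long[long["module_id"] == mid]
        for _, e in sub.iterrows():
            eid = str(e["element_id"])
            if e["axis"] == "gene":
                u[gidx[eid]] = e["weight"]
            elif e["axis"] == "miRNA":
                v[midx[eid]] = e["weight"]
            elif e["axis"] == "cancer":
                w[cidx[eid]] = e["weight"]
            else:
                raise FormatError(f"unknown axis {e['axis']!r} in module table")
        modules.append(Module(u=u, v=v, w=w, d=float(row["singular_value"]),
                              iterations=int(row["iterations"]),
                              converged=bool(row["converged"])))
    W = (np.stack([m.w for m in modules], axis=1) if modules
         else np.zeros((M, 0)))
    params = SparsityParams(
        max((len(m.I) for m in modules), default=1),
        max((len(m.J) for m in modules), default=1),
        max((len(m.K) for m in modules), default=1),
    )
    residual = CorrelationTensor(
        np.zeros((p, q, M)), list(tensor_labels.gene_ids),
        list(tensor_labels.mirna_ids), list(tensor_labels.cancer_ids),
        built_from_data=False,
    )
    return ModuleSet(modules=modules, W=W, residual=residual, params=params)
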