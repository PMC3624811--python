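"""In-memory data model and TSV I/O for expression compendia and edge matrices.

An expression compendium is a genes x conditions matrix where each condition is
either a steady-state measurement or one time point of a time series.  Condition
metadata links every non-initial time point to its predecessor, which is all the
structure the time-lagged design/response transform needs.  Edge matrices
(structure priors and gold standards) live on TF x gene axes aligned to the
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConditionMeta",
    "ExpressionDataset",
    "EdgeMatrix",
    "PriorMatrix",
    "GoldStandard",
    "FormatError",
    "load_dataset",
    "load_edge_matrix",
    "write_dataset",
    "write_edge_matrix",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected dialect or invariants."""


@dataclass(frozen=True)
class ConditionMeta:
    """Time-course annotation of a single condition (one expression column)."""

    condition: str
    is_time_series: bool = False
    is_first_in_series: bool = False
    prev_condition: str | None = None
    delta_t: float | None = None

    def __post_init__(self) -> None:
        if self.is_time_series and not self.is_first_in_series:
            if self.prev_condition is None:
                raise FormatError(
                    f"condition {self.condition!r}: non-initial time point needs prev_condition"
                )
            if self.delta_t is None or not self.delta_t > 0:
                raise FormatError(
                    f"condition {self.condition!r}: non-initial time point needs delta_t > 0"
                )
        if not self.is_time_series and self.prev_condition is not None:
            raise FormatError(
                f"condition {self.condition!r}: steady state must not have prev_condition"
            )


@dataclass
class ExpressionDataset:
    """Validated genes x conditions expression matrix with time-course metadata.

    Attributes
    ----------
    values : (n_genes, n_conditions) float array
        Expression levels; units are taken as-is (typically log scale).
    gene_ids, condition_ids : list of str
        Ordered axis labels.
    meta : list of ConditionMeta
        One entry per condition, same order as ``condition_ids``.
    tf_ids : list of str
        Subset of ``gene_ids`` designated as candidate regulators.
    """

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]
    meta: list[ConditionMeta]
    tf_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise FormatError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains missing or non-finite values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise FormatError("duplicate condition ids")
        if len(self.meta) != len(self.condition_ids):
            raise FormatError("metadata does not cover every condition")
        known = set(self.condition_ids)
        for m, cid in zip(self.meta, self.condition_ids):
            if m.condition != cid:
                raise FormatError(f"metadata order mismatch at condition {cid!r}")
            if m.prev_condition is not None and m.prev_condition not in known:
                raise FormatError(
                    f"condition {cid!r}: unknown prev_condition {m.prev_condition!r}"
                )
        gene_set = set(self.gene_ids)
        unknown_tfs = [t for t in self.tf_ids if t not in gene_set]
        if unknown_tfs:
            raise FormatError(f"tf ids not present in gene ids: {unknown_tfs[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    def meta_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": m.condition,
                "is_time_series": int(m.is_time_series),
                "is_first": int(m.is_first_in_series),
                "prev_condition": m.prev_condition if m.prev_condition is not None else "",
                "delta_t": m.delta_t if m.delta_t is not None else "",
            }
            for m in self.meta
        ]
        return pd.DataFrame(rows)


@dataclass
class EdgeMatrix:
    """TF x gene 0/1 edge indicator aligned to a dataset's axes.

    ``signs`` optionally annotates each edge with -1/+1; only presence/absence is
    used by the inference machinery (structure priors carry connectivity only).
    """

    entries: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]
    signs: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise FormatError("edge matrix shape does not match axis labels")
        if not np.isin(self.entries, (0, 1)).all():
            raise FormatError("edge matrix entries must be 0/1 after loading")
        self.entries = self.entries.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.entries.sum())

    def edge_list(self) -> list[tuple[str, str]]:
        tfs, genes = np.nonzero(self.entries)
        return [(self.tf_ids[j], self.gene_ids[i]) for j, i in zip(tfs, genes)]

    def has_edge(self, tf: str, gene: str) -> bool:
        return bool(self.entries[self.tf_ids.index(tf), self.gene_ids.index(gene)])

    def copy(self) -> "EdgeMatrix":
        return replace(
            self,
            entries=self.entries.copy(),
            signs=None if self.signs is None else self.signs.copy(),
        )


class PriorMatrix(EdgeMatrix):
    """Prior-known interactions (PKIs) supplied to the inference as structure prior."""


class GoldStandard(EdgeMatrix):
    """Gold-standard interactions (GSIs) used only for evaluation."""


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "t"}
_FALSY = {"0", "false", "no", "f", ""}


def _parse_flag(value, context: str) -> bool:
    s = str(value).strip().lower()
    if s in ("nan",):
        s = ""
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise FormatError(f"{context}: cannot parse flag value {value!r}")


def load_dataset(expression_path, meta_path, tf_path) -> ExpressionDataset:
    """Load an expression TSV, its condition metadata TSV, and a TF list.

    The expression file has a header row of condition ids and a first column of
    gene ids; the metadata file has columns
    ``condition, is_time_series, is_first, prev_condition, delta_t``.
    """
    try:
        expr = pd.read_csv(expression_path, sep="\t", index_col=0,
                           float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"cannot parse expression file: {exc}") from exc
    values = expr.to_numpy()
    if values.dtype.kind not in "fiu":
        raise FormatError("expression matrix contains non-numeric cells")

    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    required = {"condition", "is_time_series", "is_first", "prev_condition", "delta_t"}
    missing = required - set(meta_df.columns)
    if missing:
        raise FormatError(f"metadata file missing columns: {sorted(missing)}")
    meta_by_cond: dict[str, ConditionMeta] = {}
    for _, row in meta_df.iterrows():
        cond = str(row["condition"])
        prev = str(row["prev_condition"]).strip()
        dt = str(row["delta_t"]).strip()
        meta_by_cond[cond] = ConditionMeta(
            condition=cond,
            is_time_series=_parse_flag(row["is_time_series"], cond),
            is_first_in_series=_parse_flag(row["is_first"], cond),
            prev_condition=prev or None,
            delta_t=float(dt) if dt else None,
        )
    cond_ids = [str(c) for c in expr.columns]
    if set(cond_ids) != set(meta_by_cond):
        raise FormatError("condition sets of expression and metadata files differ")

    with open(tf_path) as fh:
        tf_ids = [line.strip() for line in fh if line.strip()]

    return ExpressionDataset(
        values=values,
        gene_ids=[str(g) for g in expr.index],
        condition_ids=cond_ids,
        meta=[meta_by_cond[c] for c in cond_ids],
        tf_ids=tf_ids,
    )


def write_dataset(dataset: ExpressionDataset, expression_path, meta_path, tf_path) -> None:
    dataset.to_frame().to_csv(expression_path, sep="\t")
    dataset.meta_frame().to_csv(meta_path, sep="\t", index=False)
    with open(tf_path, "w") as fh:
        for t in dataset.tf_ids:
            fh.write(t + "\n")


def _edges_to_matrix(edges, dataset: ExpressionDataset, strict: bool, kind):
    tf_index = {t: j for j, t in enumerate(dataset.tf_ids)}
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    entries = np.zeros((dataset.n_tfs, dataset.n_genes), dtype=np.int8)
    signs = np.zeros_like(entries)
    for tf, gene, value in edges:
        if tf not in tf_index or gene not in gene_index:
            if strict:
                raise FormatError(f"edge ({tf}, {gene}) references unknown identifiers")
            continue
        if value == 0:
            continue
        entries[tf_index[tf], gene_index[gene]] = 1
        signs[tf_index[tf], gene_index[gene]] = 1 if value > 0 else -1
    return kind(entries=entries, tf_ids=list(dataset.tf_ids),
                gene_ids=list(dataset.gene_ids), signs=signs)


def load_edge_matrix(path, dataset: ExpressionDataset, *, kind=PriorMatrix,
                     strict: bool = True) -> EdgeMatrix:
    """Load a prior or gold-standard file aligned to ``dataset``'s axes.

    Two dialects are accepted: a TF x gene matrix (header of gene ids, first
    column of TF ids, values in {-1, 0, 1}) or a headerless three-column edge
    list ``tf <TAB> gene <TAB> value``.  Signs are retained as annotation only;
    presence/absence is what downstream code consumes.  An empty file denotes
    "no priors".
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return kind(
            entries=np.zeros((dataset.n_tfs, dataset.n_genes), dtype=np.int8),
            tf_ids=list(dataset.tf_ids), gene_ids=list(dataset.gene_ids),
        )

    gene_set = set(dataset.gene_ids)
    header = lines[0].split("\t")
    looks_like_matrix = len(header) > 1 and all(h in gene_set for h in header[1:])
    rows = [ln.split("\t") for ln in lines]

    if looks_like_matrix:
        df = pd.read_csv(path, sep="\t", index_col=0)
        edges = []
        for tf in df.index:
            for gene in df.columns:
                v = float(df.loc[tf, gene])
                if v not in (-1.0, 0.0, 1.0):
                    raise FormatError(f"edge value {v} at ({tf}, {gene}) not in {{-1,0,1}}")
                if v != 0:
                    edges.append((str(tf), str(gene), v))
        return _edges_to_matrix(edges, dataset, strict, kind)

    if all(len(r) == 3 for r in rows):
        edges = []
        for tf, gene, raw in rows:
            try:
                v = float(raw)
            except ValueError as exc:
                raise FormatError(f"non-numeric edge value {raw!r}") from exc
            if v not in (-1.0, 0.0, 1.0):
                raise FormatError(f"edge value {v} not in {{-1,0,1}}")
            edges.append((tf, gene, v))
        return _edges_to_matrix(edges, dataset, strict, kind)

    raise FormatError(f"{path}: neither a TF x gene matrix nor a 3-column edge list")


def write_edge_matrix(matrix: EdgeMatrix, path) -> None:
    values = matrix.entries.astype(int)
    if matrix.signs is not None:
        values = values * np.where(matrix.signs < 0, -1, 1)
    pd.DataFrame(values, index=matrix.tf_ids, columns=matrix.gene_ids).to_csv(path, sep="\t")
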