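"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are UTF-8, tab-separated files with a header row and
"." as the decimal mark: expression matrices (features x samples), sample
tables, feature annotations, differential-expression tables and bipartite
edge lists.  Networks can additionally be exported as GraphML for
visualization, and run summaries as JSON.

Domain containers defined here (:class:`ExpressionMatrix`,
:class:`SampleTable`, :class:`FeatureAnnotation`, :class:`BipartiteNetwork`)
validate their invariants on construction, so any object obtained through a
reader is guaranteed well formed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered phenotype labels: tumor-adjacent normal tissue then stages I-IV.
STAGE_ORDER: tuple[str, ...] = ("NT", "I", "II", "III", "IV")

#: Accepted spellings of each phenotype label (lower-cased, stripped).
_STAGE_ALIASES: dict[str, str] = {}
for _alias in ("nt", "normal", "control", "solid tissue normal"):
    _STAGE_ALIASES[_alias] = "NT"
for _i, _roman in enumerate(("i", "ii", "iii", "iv"), start=1):
    _canon = _roman.upper()
    for _alias in (_roman, f"stage {_roman}", f"st_{_roman}", str(_i), f"stage{_roman}"):
        _STAGE_ALIASES[_alias] = _canon

#: Labels meaning "no stage recorded"; such rows are dropped at read time.
_MISSING_STAGE = {"", "not reported", "not_reported", "na", "nan", "none"}

EDGE_COLUMNS = ("mir_id", "gene_id", "mi")
DE_COLUMNS = ("base_mean_ref", "base_mean_test", "log2fc", "p_raw", "p_adj", "status")


class FormatError(ValueError):
    """A file violated the on-disk contract of one of the pipeline formats."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A features x samples abundance matrix with a feature-kind tag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns.  Values
        must be finite and non-negative (integers when the units are raw
        counts, but the container does not enforce integrality).
    feature_kind
        ``"gene"`` or ``"miR"``.
    units
        Free-text provenance tag, e.g. ``"raw counts"`` or ``"normalized"``.
    """

    data: pd.DataFrame
    feature_kind: str
    units: str = "raw counts"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "miR"):
            raise ValueError(f"feature_kind must be 'gene' or 'miR', got {self.feature_kind!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if values.size:
            if not np.all(np.isfinite(values)):
                i, j = np.argwhere(~np.isfinite(values))[0]
                raise FormatError(
                    f"non-finite value at feature {idx[i]!r}, sample {cols[j]!r}"
                )
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise FormatError(
                    f"negative value at feature {idx[i]!r}, sample {cols[j]!r}"
                )

    # -- convenience accessors ------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        """Column subset (preserving the given order)."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[ids].copy(), self.feature_kind, self.units)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        return ExpressionMatrix(self.data.loc[ids].copy(), self.feature_kind, self.units)


def read_expression(path: str | Path, feature_kind: str) -> ExpressionMatrix:
    """Read a tab-separated features x samples matrix.

    First column holds feature ids, the header row holds sample ids, all
    remaining cells must be non-negative numbers.  Duplicate ids, negative
    or non-numeric cells and ragged rows are hard errors.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = {c for c in header if header.count(c) > 1}
    if dup_cols:
        raise FormatError(f"{path}: duplicate sample id {sorted(dup_cols)[0]!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if df.isna().any().any():
        feat = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row {feat!r} (ragged row?)")
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    try:
        return ExpressionMatrix(numeric, feature_kind=feature_kind)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (inverse of :func:`read_expression`)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mat.data.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Mapping from sample id to one of the five ordered phenotypes."""

    stages: dict[str, str] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for sid, stage in self.stages.items():
            if stage not in STAGE_ORDER:
                raise ValueError(f"sample {sid!r} has invalid phenotype {stage!r}")

    def samples_for(self, phenotype: str) -> list[str]:
        return [s for s, st in self.stages.items() if st == phenotype]

    def counts(self) -> dict[str, int]:
        return {st: len(self.samples_for(st)) for st in STAGE_ORDER}

    def __len__(self) -> int:
        return len(self.stages)


def normalize_stage_label(label: str) -> str | None:
    """Map a free-text stage label to NT/I/II/III/IV, or None if missing.

    Raises :class:`FormatError` for a non-empty label outside the accepted
    vocabulary.
    """
    key = label.strip().lower()
    if key in _MISSING_STAGE:
        return None
    if key in _STAGE_ALIASES:
        return _STAGE_ALIASES[key]
    raise FormatError(f"unmappable stage label {label!r}")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a two-column (sample id, stage label) TSV.

    Rows with an empty or "not reported" stage are silently dropped (the
    count is logged and stored on the returned table); any other unmappable
    label is a hard error.
    """
    path = Path(path)
    stages: dict[str, str] = {}
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("%s: empty sample table", path)
        return SampleTable({}, 0)
    start = 0
    first = lines[0].split("\t")
    # tolerate a header row
    if first and first[0].strip().lower() in ("sample_id", "sample", "id"):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
        sid = parts[0].strip()
        stage = normalize_stage_label(parts[1])
        if stage is None:
            dropped += 1
            continue
        if sid in stages:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        stages[sid] = stage
    if dropped:
        logger.info("%s: dropped %d samples with unreported stage", path, dropped)
    return SampleTable(stages, dropped)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tstage\n")
        for sid, stage in table.stages.items():
            fh.write(f"{sid}\t{stage}\n")


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------

ANNOT_COLUMNS = ("chromosome", "cytoband", "start", "end", "strand", "biotype")


@dataclass
class FeatureAnnotation:
    """feature id -> (chromosome, cytoband, start, end, strand, biotype).

    Coordinates are 1-based fully closed intervals; ``cytoband`` is the full
    "chromosome + band" string (e.g. ``"12q13.13"``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOT_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing columns {missing}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r} in annotation")
        t = self.table
        if (t["start"] > t["end"]).any():
            fid = t.index[t["start"] > t["end"]][0]
            raise FormatError(f"feature {fid!r}: start > end")
        if (t["start"] < 1).any():
            fid = t.index[t["start"] < 1][0]
            raise FormatError(f"feature {fid!r}: start must be >= 1 (1-based)")
        if (t["chromosome"].astype(str).str.len() == 0).any():
            raise FormatError("empty chromosome name in annotation")
        bad = ~t["strand"].isin(["+", "-", "."])
        if bad.any():
            fid = t.index[bad][0]
            raise FormatError(f"feature {fid!r}: invalid strand {t.loc[fid, 'strand']!r}")

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def locus(self, feature_id: str) -> pd.Series | None:
        if feature_id not in self.table.index:
            return None
        return self.table.loc[feature_id]


def read_annotation(path: str | Path) -> FeatureAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype={"chromosome": str, "cytoband": str, "strand": str, "biotype": str},
    )
    df.index = df.index.astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return FeatureAnnotation(df)


def write_annotation(annot: FeatureAnnotation, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annot.table.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Bipartite networks (edge lists)
# ---------------------------------------------------------------------------

@dataclass
class BipartiteNetwork:
    """A set of (miR, gene, MI) edges for one phenotype.

    ``filtered`` records provenance: ``raw`` (all candidate pairs), ``topk``
    (K highest-MI edges) or ``canonical`` (opposite-sign filtered).  Edge
    identity is the (mir_id, gene_id) pair; the MI score is metadata.
    """

    phenotype: str
    edges: pd.DataFrame
    k: int | None = None
    filtered: str = "raw"

    def __post_init__(self) -> None:
        if self.filtered not in ("raw", "topk", "canonical"):
            raise ValueError(f"invalid filter state {self.filtered!r}")
        if list(self.edges.columns) != list(EDGE_COLUMNS):
            self.edges = self.edges.reindex(columns=list(EDGE_COLUMNS))
        if self.edges.duplicated(subset=["mir_id", "gene_id"]).any():
            row = self.edges[self.edges.duplicated(subset=["mir_id", "gene_id"])].iloc[0]
            raise FormatError(f"duplicate edge ({row.mir_id!r}, {row.gene_id!r})")
        mi = self.edges["mi"].to_numpy()
        if mi.size and (not np.all(np.isfinite(mi)) or (mi < 0).any()):
            raise FormatError("MI scores must be finite and >= 0")
        self.edges = self.edges.reset_index(drop=True)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(zip(self.edges["mir_id"], self.edges["gene_id"]))

    def __len__(self) -> int:
        return len(self.edges)


def write_edges(net: BipartiteNetwork, path: str | Path) -> None:
    """Write an edge list as TSV with full floating-point precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for mir, gene, mi in net.edges.itertuples(index=False):
            fh.write(f"{mir}\t{gene}\t{float(mi):.17g}\n")


def read_edges(path: str | Path, phenotype: str = "", k: int | None = None,
               filtered: str = "raw") -> BipartiteNetwork:
    """Read an edge-list TSV written by :func:`write_edges`."""
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(EDGE_COLUMNS):
            raise FormatError(f"{path}:1: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                mi = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad MI value {parts[2]!r}") from exc
            rows.append((parts[0], parts[1], mi))
    df = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    return BipartiteNetwork(phenotype=phenotype, edges=df, k=k, filtered=filtered)


def write_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    """Export a network as GraphML (node attribute `kind`, edge attr `mi`)."""
    g = nx.Graph()
    for mir, gene, mi in net.edges.itertuples(index=False):
        g.add_node(mir, kind="miR")
        g.add_node(gene, kind="gene")
        g.add_edge(mir, gene, mi=float(mi))
    g.graph["phenotype"] = net.phenotype
    g.graph["filtered"] = net.filtered
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Differential-expression tables and JSON summaries
# ---------------------------------------------------------------------------

def write_de_table(table: pd.DataFrame, path: str | Path, contrast_label: str = "") -> None:
    """Write a DE table (index: feature id) with the standard column set."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in DE_COLUMNS if c in table.columns]
    with open(path, "w", encoding="utf-8") as fh:
        if contrast_label:
            fh.write(f"# contrast: {contrast_label}\n")
        table[cols].to_csv(fh, sep="\t", index_label="feature_id")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
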