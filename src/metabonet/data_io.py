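"""Readers and writers for abundance tables, networks and result tables.

The canonical on-disk format for abundance data is a *wide CSV*: first
column ``sample_id``, second column ``group``, optional third column
``subgroup``, and one column per metabolite holding non-negative MS
intensities (counts per second).  A best-effort reader for the flat
``MS_METABOLITE_DATA`` block of Metabolomics Workbench mwTab exports is
also provided; it is deliberately not a general mwTab parser.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "GroupPair",
    "DEFAULT_GROUP_ALIASES",
    "read_abundance_table",
    "write_abundance_table",
    "write_network",
    "read_network",
    "write_results_table",
]

#: Case-insensitive aliases used when ingesting public exports, whose group
#: spellings vary.  Users may extend or replace this mapping via config.
DEFAULT_GROUP_ALIASES: dict[str, str] = {
    "ctr": "CTR",
    "ctrl": "CTR",
    "control": "CTR",
    "healthy": "CTR",
    "crc": "CRC",
    "cancer": "CRC",
    "colorectal cancer": "CRC",
    "pp": "PP",
    "polyp": "PP",
    "polyposis": "PP",
}


def canonical_name(name: str) -> str:
    """Whitespace/case canonical form used for uniqueness checks."""
    return re.sub(r"\s+", " ", str(name).strip()).lower()


@dataclass
class AbundanceMatrix:
    """Samples x metabolites intensity matrix with per-sample group labels.

    ``values`` is a float DataFrame indexed by sample id with metabolite
    columns.  Missing measurements are represented as NaN (never silently
    zero); all observed entries of raw data must be non-negative.
    ``scale`` records the measurement scale: ``"raw"`` intensities are
    non-negative, derived scales (``"sqrt"``, ``"int"`` for the rank-based
    inverse normal transform) may carry signed values.
    """

    values: pd.DataFrame
    groups: pd.Series
    subgroups: pd.Series | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups, index=self.values.index).astype(str)
        if self.subgroups is not None:
            self.subgroups = pd.Series(self.subgroups, index=self.values.index)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        canon = [canonical_name(c) for c in self.values.columns]
        if len(set(canon)) != len(canon):
            seen: set[str] = set()
            dup = sorted({c for c in canon if c in seen or seen.add(c)})  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate metabolite names (after canonicalization): {dup}")
        if self.scale == "raw":
            arr = self.values.to_numpy()
            if np.nanmin(arr, initial=np.inf) < 0:
                raise ValueError("raw abundance values must be non-negative")
        if not self.groups.index.equals(idx):
            raise ValueError("group labels must cover every sample")
        if self.groups.isna().any() or (self.groups == "").any():
            raise ValueError("every sample needs a group label")

    # -- basic accessors ----------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns.astype(str))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.groups.unique().tolist())

    @property
    def has_missing(self) -> bool:
        return bool(self.values.isna().to_numpy().any())

    def group_values(self, group: str) -> np.ndarray:
        """Dense value matrix for one group (samples x metabolites)."""
        if group not in set(self.groups):
            raise KeyError(f"unknown group {group!r}; available: {self.group_labels}")
        return self.values.loc[self.groups == group].to_numpy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(sample_ids)
        return AbundanceMatrix(
            values=self.values.loc[ids].copy(),
            groups=self.groups.loc[ids].copy(),
            subgroups=None if self.subgroups is None else self.subgroups.loc[ids].copy(),
            scale=self.scale,
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        drop = set(sample_ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.subset_samples(keep)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=values,
            groups=self.groups.copy(),
            subgroups=None if self.subgroups is None else self.subgroups.copy(),
            scale=self.scale if scale is None else scale,
        )

    # -- missing data -------------------------------------------------
    def impute_missing(self, max_missing_frac: float = 0.2) -> "AbundanceMatrix":
        """Impute missing entries as half the minimum positive value per metabolite.

        A metabolite with more than ``max_missing_frac`` missing within any
        group is rejected with an error (common MS practice; the imputation
        default is documented, not a claim about any specific study).
        """
        if not self.has_missing:
            return self
        vals = self.values.copy()
        for g in self.group_labels:
            sub = vals.loc[self.groups == g]
            frac = sub.isna().mean(axis=0)
            bad = frac[frac > max_missing_frac]
            if len(bad):
                raise ValueError(
                    f"metabolites with >{max_missing_frac:.0%} missing in group {g}: "
                    f"{sorted(bad.index.tolist())}"
                )
        for col in vals.columns:
            v = vals[col]
            if v.isna().any():
                pos = v[v > 0]
                fill = 0.5 * pos.min() if len(pos) else 0.0
                vals[col] = v.fillna(fill)
        return self.with_values(vals)


@dataclass(frozen=True)
class GroupPair:
    """An ordered pair of group labels; the first group is the 'case'."""

    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")

    def validate_in(self, data: AbundanceMatrix) -> None:
        present = set(data.groups)
        for g in (self.group_a, self.group_b):
            if g not in present:
                raise KeyError(f"group {g!r} not present; available: {sorted(present)}")

    def swapped(self) -> "GroupPair":
        return GroupPair(self.group_b, self.group_a)

    def __str__(self) -> str:  # used in result tables
        return f"{self.group_a}_vs_{self.group_b}"


# ---------------------------------------------------------------------------
# abundance table I/O
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


def _map_group(label: str, aliases: Mapping[str, str] | None,
               allowed_groups: Sequence[str] | None) -> str:
    lab = str(label).strip()
    if aliases:
        lab = aliases.get(lab.lower(), lab)
    if allowed_groups is not None and lab not in set(allowed_groups):
        raise ValueError(
            f"unknown group label {label!r}; allowed labels: {sorted(set(allowed_groups))}"
        )
    return lab


def read_abundance_table(
    path: str | Path,
    format: str = "wide_csv",
    *,
    group_aliases: Mapping[str, str] | None = None,
    allowed_groups: Sequence[str] | None = None,
) -> AbundanceMatrix:
    """Read an abundance table from disk.

    ``format="wide_csv"`` expects sample_id, group, [subgroup], metabolites.
    ``format="mwtab_flat"`` reads the MS_METABOLITE_DATA tabular block of a
    Metabolomics Workbench flat export (metabolites in rows, samples in
    columns, a ``Factors`` line carrying the group labels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wide_csv":
        return _read_wide_csv(path, group_aliases, allowed_groups)
    if format == "mwtab_flat":
        return _read_mwtab_flat(path, group_aliases, allowed_groups)
    raise ValueError(f"unknown format {format!r}; expected 'wide_csv' or 'mwtab_flat'")


def _parse_cell(raw: str, sample: str, column: str) -> float:
    s = raw.strip()
    if s.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise ValueError(
            f"non-numeric value {raw!r} at sample {sample!r}, metabolite {column!r}"
        ) from None


def _read_wide_csv(path: Path, aliases, allowed) -> AbundanceMatrix:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    canon = [canonical_name(c) for c in header[2:]]
    if len(set(canon)) != len(canon):
        seen: set[str] = set()
        dup = sorted({c for c in canon if c in seen or seen.add(c)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate metabolite names: {dup}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValueError("wide_csv needs sample_id, group and >=1 metabolite column")
    cols = list(raw.columns)
    sample_col, group_col = cols[0], cols[1]
    has_sub = len(cols) > 2 and cols[2].strip().lower() == "subgroup"
    met_cols = cols[3:] if has_sub else cols[2:]
    if not met_cols:
        raise ValueError("no metabolite columns found")
    samples = raw[sample_col].astype(str).tolist()
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dup}")
    groups = [_map_group(g, aliases, allowed) for g in raw[group_col]]
    data = np.empty((len(samples), len(met_cols)))
    for j, col in enumerate(met_cols):
        data[:, j] = [_parse_cell(v, samples[i], col) for i, v in enumerate(raw[col])]
    if np.nanmin(data, initial=np.inf) < 0:
        raise ValueError("negative intensity encountered in raw abundance table")
    values = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"), columns=met_cols)
    sub = raw[cols[2]].astype(str).set_axis(values.index) if has_sub else None
    if sub is not None:
        sub = sub.replace({t: None for t in ("", "NA", "nan")})
    return AbundanceMatrix(values=values, groups=pd.Series(groups, index=values.index),
                           subgroups=sub)


def _read_mwtab_flat(path: Path, aliases, allowed) -> AbundanceMatrix:
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if "MS_METABOLITE_DATA_START" in l)
        end = next(i for i, l in enumerate(lines) if "MS_METABOLITE_DATA_END" in l)
    except StopIteration:
        raise ValueError("no MS_METABOLITE_DATA block found") from None
    block = [l for l in lines[start + 1 : end] if l.strip()]
    if len(block) < 3:
        raise ValueError("MS_METABOLITE_DATA block too short")
    header = block[0].split("\t")
    factors = block[1].split("\t")
    if not header[0].strip().lower().startswith("sample"):
        raise ValueError("first block line must be the Samples line")
    samples = [s.strip() for s in header[1:]]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in mwTab block")
    # Factors cells typically look like 'Diagnosis:CRC'; take text after last ':'
    groups = [_map_group(f.rsplit(":", 1)[-1], aliases, allowed) for f in factors[1:]]
    if len(groups) != len(samples):
        raise ValueError("Factors line does not match Samples line")
    met_names: list[str] = []
    rows: list[list[float]] = []
    for line in block[2:]:
        parts = line.split("\t")
        name = parts[0].strip()
        met_names.append(name)
        rows.append([_parse_cell(v, samples[i], name) for i, v in enumerate(parts[1:])])
    values = pd.DataFrame(
        np.asarray(rows, dtype=float).T,
        index=pd.Index(samples, name="sample_id"),
        columns=met_names,
    )
    return AbundanceMatrix(values=values, groups=pd.Series(groups, index=values.index))


def write_abundance_table(data: AbundanceMatrix, path: str | Path) -> None:
    """Write an abundance matrix as wide CSV (the canonical format)."""
    out = data.values.copy()
    out.insert(0, "group", data.groups)
    if data.subgroups is not None:
        out.insert(1, "subgroup", data.subgroups)
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path, format: str = "graphml") -> None:
    """Write an association network to GraphML or an edge TSV.

    Every node is written with a ``connectivity`` attribute (sum of
    probability-weighted absolute edge weights over its incident edges);
    every edge carries ``weight`` (signed Spearman r) and ``probability``.
    In the TSV format isolated nodes appear as rows with an empty target.
    """
    import networkx as nx

    g = net if isinstance(net, nx.Graph) else net.graph
    g = g.copy()
    for node in g.nodes:
        conn = sum(
            d.get("probability", 1.0) * abs(d.get("weight", 1.0))
            for _, _, d in g.edges(node, data=True)
        )
        g.nodes[node]["connectivity"] = float(conn)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "target", "weight", "probability"])
            isolated = set(g.nodes)
            for u, v, d in sorted(g.edges(data=True)):
                isolated.discard(u)
                isolated.discard(v)
                w.writerow([u, v, repr(float(d.get("weight", 1.0))),
                            repr(float(d.get("probability", 1.0)))])
            for node in sorted(isolated):
                w.writerow([node, "", "", ""])
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml"):
    """Read a network written by :func:`write_network`.

    Returns an :class:`~metabonet.pclrc.AssociationNetwork` with unknown
    thresholds (set to 0).
    """
    import networkx as nx

    from .pclrc import AssociationNetwork

    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        h = nx.Graph()
        h.add_nodes_from(g.nodes())
        for u, v, d in g.edges(data=True):
            h.add_edge(u, v, weight=float(d.get("weight", 1.0)),
                       probability=float(d.get("probability", 1.0)))
        return AssociationNetwork(graph=h, p_min=0.0, r_min=0.0)
    if format == "edge_tsv":
        g = nx.Graph()
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:2] != ["source", "target"]:
                raise ValueError("not an edge TSV written by write_network")
            for row in reader:
                if len(row) < 2 or row[1] == "":
                    g.add_node(row[0])
                else:
                    g.add_edge(row[0], row[1], weight=float(row[2]),
                               probability=float(row[3]))
        return AssociationNetwork(graph=g, p_min=0.0, r_min=0.0)
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results_table(rows, path: str | Path) -> None:
    """Write result records as a TSV with deterministic row order.

    ``rows`` may be a DataFrame, a list of dataclasses or a list of dicts.
    Rows are sorted by metabolite name then comparison (when those columns
    exist); floats are rendered with 8 significant digits.
    """
    import dataclasses

    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        recs = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in rows
        ]
        df = pd.DataFrame(recs)
    sort_cols = [c for c in ("metabolite", "pathway_id", "pair", "comparison") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort")
    for col in df.columns:
        if df[col].map(lambda x: isinstance(x, GroupPair)).any():
            df[col] = df[col].map(str)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
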