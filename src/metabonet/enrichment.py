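"""Hypergeometric pathway over-representation with an impact-score filter.

The query set (e.g. significantly differentially connected metabolites)
is matched by canonicalized name against a pathway library; for each
pathway the upper-tail hypergeometric p-value of the overlap is
computed, BH-adjusted across pathways, and pathways are filtered to
impact score > 0.01.  The impact score of a pathway is the sum of the
importance measures of its matched compounds divided by the sum over
all its compounds (with importance defaulting to 1, this is k/K).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import benjamini_hochberg

__all__ = [
    "Pathway",
    "PathwayLibrary",
    "EnrichmentResult",
    "load_pathway_library",
    "toy_pathway_library",
    "hypergeometric_enrich",
    "hypergeom_pvalue",
    "impact_score",
]

IMPACT_MIN = 0.01


def hypergeom_pvalue(k: int, n_universe: int, pathway_size: int, query_size: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(pathway_size, query_size)):
        raise ValueError("impossible overlap count")
    return float(stats.hypergeom.sf(k - 1, n_universe, pathway_size, query_size))


def canonical_compound(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    s = re.sub(r"[^\w\s]", " ", str(name).lower())
    return re.sub(r"\s+", " ", s).strip()


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    pathway_name: str
    member_compounds: frozenset[str]
    importance: dict[str, float] = field(hash=False, default_factory=dict)

    def __post_init__(self) -> None:
        imp = self.importance or {c: 1.0 for c in self.member_compounds}
        object.__setattr__(self, "importance", imp)
        if set(self.importance) != set(self.member_compounds):
            raise ValueError(f"importance keys must equal members in {self.pathway_id}")
        if any(v < 0 for v in self.importance.values()):
            raise ValueError("importance measures must be non-negative")
        if sum(self.importance.values()) <= 0:
            raise ValueError(f"pathway {self.pathway_id} has zero total importance")


@dataclass
class PathwayLibrary:
    pathways: list[Pathway]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.member_compounds
        return frozenset(out)


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k_matched: int
    pathway_size: int
    p_value: float
    q_value: float
    impact: float
    matched: tuple[str, ...]


def load_pathway_library(path: str | Path) -> PathwayLibrary:
    """Read a TSV library: pathway_id, pathway_name, compound[, importance]."""
    df = pd.read_csv(path, sep="\t")
    required = {"pathway_id", "compound"}
    if not required <= set(df.columns):
        raise ValueError(f"library TSV needs columns {sorted(required)}")
    pathways = []
    for pid, sub in df.groupby("pathway_id", sort=True):
        name = str(sub["pathway_name"].iloc[0]) if "pathway_name" in sub else str(pid)
        members = [canonical_compound(c) for c in sub["compound"]]
        if "importance" in sub.columns:
            imp = dict(zip(members, sub["importance"].astype(float)))
        else:
            imp = {m: 1.0 for m in members}
        pathways.append(
            Pathway(
                pathway_id=str(pid),
                pathway_name=name,
                member_compounds=frozenset(members),
                importance=imp,
            )
        )
    return PathwayLibrary(pathways=pathways)


def toy_pathway_library() -> PathwayLibrary:
    """The small synthetic pathway library shipped for tests and demos."""
    ref = resources.files("metabonet").joinpath("data/toy_pathways.tsv")
    with resources.as_file(ref) as path:
        return load_pathway_library(path)


def impact_score(matched: set[str], pathway: Pathway) -> float:
    """Importance mass of the matched compounds relative to the whole pathway."""
    matched = set(matched)
    if not matched <= pathway.member_compounds:
        raise ValueError("matched compounds must be pathway members")
    total = sum(pathway.importance.values())
    return sum(pathway.importance[c] for c in matched) / total


def hypergeometric_enrich(
    query: set[str],
    lib: PathwayLibrary,
    *,
    synonyms: dict[str, str] | None = None,
    impact_min: float = IMPACT_MIN,
) -> list[EnrichmentResult]:
    """Over-representation of a metabolite set in each library pathway.

    Query names are canonicalized (and optionally mapped through a
    synonyms table) before matching; the universe is all compounds of the
    library.  p = P(X >= k) with X ~ Hypergeometric(N, K, n); BH across
    all pathways, then filtering to impact > ``impact_min``.
    """
    syn = {canonical_compound(k): canonical_compound(v) for k, v in (synonyms or {}).items()}
    mapped = {syn.get(canonical_compound(q), canonical_compound(q)) for q in query}
    universe = lib.universe
    in_universe = mapped & universe
    if query and not in_universe:
        warnings.warn("no query metabolite matched the library universe")
        return []
    n_universe = len(universe)
    n_query = len(in_universe)
    rows = []
    for pw in lib.pathways:
        matched = in_universe & pw.member_compounds
        k = len(matched)
        big_k = len(pw.member_compounds)
        p = hypergeom_pvalue(k, n_universe, big_k, n_query)
        rows.append((pw, matched, k, big_k, p))
    q_values = benjamini_hochberg([r[4] for r in rows]) if rows else []
    results = []
    for (pw, matched, k, big_k, p), q in zip(rows, q_values):
        imp = impact_score(matched, pw)
        if imp > impact_min:
            results.append(
                EnrichmentResult(
                    pathway_id=pw.pathway_id,
                    pathway_name=pw.pathway_name,
                    k_matched=k,
                    pathway_size=big_k,
                    p_value=p,
                    q_value=float(q),
                    impact=imp,
                    matched=tuple(sorted(matched)),
                )
            )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results
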