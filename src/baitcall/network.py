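"""Condition-resolved interaction networks and screen summary statistics.

Hit lists become bait-prey edge lists annotated with the growth
condition, the kind of evidence (absent from both controls vs
significantly enriched over them) and, for enriched preys, the log2
fold enrichment against the tagged control — the quantity conventionally
mapped to edge width in Cytoscape. Prey nodes carry a functional
category drawn from a 10-label controlled vocabulary; assignment is
user-supplied input (curation), not computed.

Also here: the screen-level summaries — replicate/condition Venn
overlaps, pairwise bait-similarity matrices and volcano tables.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .qualitative import QualitativeHitList
from .quantitative import VERDICT_ABSENT, VERDICT_ENRICHED

EVIDENCE_ABSENT = "absent_in_controls"
EVIDENCE_ENRICHED = "enriched"

UNASSIGNED = "unassigned"


def default_category_vocabulary() -> tuple[str, ...]:
    """The packaged 10-label functional vocabulary for prey proteins."""
    text = resources.files("baitcall").joinpath("data/prey_categories.txt").read_text(
        encoding="utf-8"
    )
    return tuple(line.strip() for line in text.splitlines() if line.strip())


@dataclass
class CategoryMap:
    """accession -> functional category, restricted to a vocabulary."""

    mapping: dict
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.vocabulary:
            self.vocabulary = default_category_vocabulary()
        bad = {v for v in self.mapping.values() if v not in self.vocabulary}
        if bad:
            raise DataError(f"categories outside vocabulary: {sorted(bad)[:5]}")

    def category(self, accession: str) -> str:
        return self.mapping.get(accession, UNASSIGNED)

    @classmethod
    def from_tsv(cls, path: str | Path, vocabulary: Sequence[str] = ()) -> "CategoryMap":
        mapping = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) >= 2 and row[0].strip():
                    mapping[row[0].strip()] = row[1].strip()
        return cls(mapping, tuple(vocabulary))


@dataclass(frozen=True)
class InteractionEdge:
    """One bait-prey interaction under one growth condition."""

    bait: str
    prey: str
    condition: str
    evidence: str  # EVIDENCE_ABSENT or EVIDENCE_ENRICHED
    weight: Optional[float]  # log2fc vs control2; None iff evidence is absence
    prey_category: str = UNASSIGNED


Records = Union[pd.DataFrame, QualitativeHitList]


def build_network(
    records: Iterable[Records] | Records,
    categories: CategoryMap | None = None,
) -> list[InteractionEdge]:
    """One edge per final hit.

    Accepts quantitative record tables (rows with ``final_hit`` True
    become edges; the evidence and weight come from the control2 verdict)
    and/or qualitative hit lists (always absence evidence, no weight).
    """
    if isinstance(records, (pd.DataFrame, QualitativeHitList)):
        records = [records]
    categories = categories or CategoryMap({})
    edges: list[InteractionEdge] = []
    for rec in records:
        if isinstance(rec, QualitativeHitList):
            for prey in sorted(rec.hits):
                edges.append(
                    InteractionEdge(
                        rec.bait, prey, rec.condition, EVIDENCE_ABSENT, None,
                        categories.category(prey),
                    )
                )
            continue
        hits = rec[rec["final_hit"]]
        for _, row in hits.iterrows():
            if row["verdict_c2"] == VERDICT_ABSENT:
                evidence, weight = EVIDENCE_ABSENT, None
            else:
                assert row["verdict_c2"] == VERDICT_ENRICHED
                evidence, weight = EVIDENCE_ENRICHED, float(row["log2fc_c2"])
            edges.append(
                InteractionEdge(
                    row["bait"], row["accession"], row["condition"],
                    evidence, weight, categories.category(row["accession"]),
                )
            )
    return edges


def condition_overlap(hits_by_condition: Mapping[str, Iterable]) -> dict[tuple, int]:
    """Venn region counts of one bait's hit sets across three conditions.

    Returns a dict keyed by the tuple of conditions a region belongs to
    (all 7 nonempty combinations); region counts sum to the union size.
    """
    items = [(c, frozenset(s)) for c, s in hits_by_condition.items()]
    if len(items) != 3:
        raise DataError(f"expected hit sets for 3 conditions, got {len(items)}")
    names = [c for c, _ in items]
    sets = dict(items)
    out: dict[tuple, int] = {}
    for k in (1, 2, 3):
        for combo in combinations(names, k):
            inside = frozenset.intersection(*(sets[c] for c in combo))
            outside = frozenset.union(
                frozenset(), *(sets[c] for c in names if c not in combo)
            )
            out[tuple(combo)] = len(inside - outside)
    return out


def bait_similarity(
    hit_sets: Mapping[str, Iterable], mode: str = "weighted"
) -> pd.DataFrame:
    """Pairwise percent similarity of per-bait interactant sets.

    ``mode="weighted"`` (default): 100 * |Si n Sj| / |Si u Sj| scaled by
    |Si u Sj| / |union over all baits| — percent shared interactants
    weighted by how much of the whole screen the pair covers.
    ``mode="jaccard"``: plain 100 * Jaccard. The diagonal is 100 by
    definition in both modes; the matrix is symmetric. If no bait has
    any interactant the similarity is undefined and the matrix is NaN.
    """
    if mode not in ("weighted", "jaccard"):
        raise DataError(f"unknown similarity mode {mode!r}")
    baits = list(hit_sets)
    if len(baits) < 2:
        raise DataError("need at least 2 baits for a similarity matrix")
    sets = {b: frozenset(hit_sets[b]) for b in baits}
    universe = frozenset().union(*sets.values())
    mat = pd.DataFrame(
        np.full((len(baits), len(baits)), math.nan), index=baits, columns=baits
    )
    if not universe:
        return mat
    for i, bi in enumerate(baits):
        mat.loc[bi, bi] = 100.0
        for bj in baits[i + 1:]:
            union = sets[bi] | sets[bj]
            if not union:
                value = 0.0
            else:
                jaccard = len(sets[bi] & sets[bj]) / len(union)
                if mode == "weighted":
                    value = 100.0 * jaccard * (len(union) / len(universe))
                else:
                    value = 100.0 * jaccard
            mat.loc[bi, bj] = value
            mat.loc[bj, bi] = value
    return mat


def volcano_table(records: pd.DataFrame, control: str = "c2") -> pd.DataFrame:
    """Enrichment vs significance table for plotting, one row per record.

    Proteins absent from the chosen control were never tested: they are
    flagged (``absent_in_control`` True) and keep NaN in the fold and
    p-value columns rather than being given fabricated coordinates.
    """
    if control not in ("c1", "c2"):
        raise DataError(f"control must be 'c1' or 'c2', got {control!r}")
    padj = records[f"padj_{control}"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neg_log10 = np.where(np.isnan(padj), np.nan, -np.log10(padj))
    return pd.DataFrame(
        {
            "accession": records["accession"].to_numpy(),
            "log2fc": records[f"log2fc_{control}"].to_numpy(dtype=float),
            "neg_log10_padj": neg_log10,
            "absent_in_control": (
                records[f"verdict_{control}"] == VERDICT_ABSENT
            ).to_numpy(),
            "final_hit": records["final_hit"].to_numpy(),
        }
    )


def to_networkx(edges: Sequence[InteractionEdge]) -> nx.MultiDiGraph:
    """Directed multigraph bait -> prey, one edge per (condition, pair)."""
    g = nx.MultiDiGraph()
    for e in edges:
        if e.bait not in g:
            g.add_node(e.bait)
        g.nodes[e.bait]["kind"] = "bait"  # bait status wins if a node is both
        if e.prey not in g:
            g.add_node(e.prey, kind="prey")
        g.nodes[e.prey].setdefault("category", e.prey_category)
        attrs = {"condition": e.condition, "evidence": e.evidence}
        if e.weight is not None:
            attrs["weight"] = e.weight
        g.add_edge(e.bait, e.prey, **attrs)
    return g


def export_network(
    edges: Sequence[InteractionEdge], fmt: str, path: str | Path
) -> Path:
    """Write the edge list for graph tooling.

    ``fmt``: ``"SIF"`` (Cytoscape simple interaction format, interaction
    type ``bait-prey``), ``"GraphML"`` (all attributes carried) or
    ``"TSV"`` (flat edge table).
    """
    path = Path(path)
    key = fmt.strip().lower()
    if key == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for e in edges:
                fh.write(f"{e.bait}\tbait-prey\t{e.prey}\n")
    elif key == "graphml":
        nx.write_graphml(to_networkx(edges), path)
    elif key == "tsv":
        pd.DataFrame(
            {
                "bait": [e.bait for e in edges],
                "prey": [e.prey for e in edges],
                "condition": [e.condition for e in edges],
                "evidence": [e.evidence for e in edges],
                "log2fc_c2": [
                    e.weight if e.weight is not None else math.nan for e in edges
                ],
                "prey_category": [e.prey_category for e in edges],
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        raise DataError(f"unknown network format {fmt!r} (SIF, GraphML or TSV)")
    return path


def write_node_table(edges: Sequence[InteractionEdge], path: str | Path) -> Path:
    """Cytoscape-style node attribute table (kind, category)."""
    g = to_networkx(edges)
    pd.DataFrame(
        {
            "node": list(g.nodes),
            "kind": [g.nodes[n].get("kind", "prey") for n in g.nodes],
            "category": [g.nodes[n].get("category", "") for n in g.nodes],
        }
    ).to_csv(path, sep="\t", index=False)
    return Path(path)
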