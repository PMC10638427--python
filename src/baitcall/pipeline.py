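"""End-to-end drivers: simulate a fixture bundle, process a screen,
report networks and summaries.

These functions are the programmatic entry points the example scripts
wrap. Every output is a plain text file (TSV/YAML/JSON/SIF/GraphML) and
every run writes a deterministic manifest (inputs, configuration hash,
package version) so results are traceable; given identical inputs and
configuration the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .design import SampleDesign, save_design
from .io import IntensityTable, write_maxquant_like
from .network import (
    CategoryMap,
    bait_similarity,
    build_network,
    condition_overlap,
    export_network,
    volcano_table,
    write_node_table,
)
from .qualitative import qualitative_screen_group, write_hit_list
from .quantitative import (
    QuantConfig,
    condition_global_stats,
    quantitative_screen,
    write_global_stats,
    write_records,
)
from .simulate import SimParams, generate_dataset, write_truth

logger = logging.getLogger(__name__)


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_manifest(outdir: Path, kind: str, config: dict, inputs: list[str]) -> None:
    manifest = {
        "tool": f"baitcall {__version__}",
        "step": kind,
        "inputs": sorted(inputs),
        "config": config,
        "config_hash": _config_hash(config),
    }
    (outdir / f"{kind}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def simulate_bundle(params: SimParams | None = None, outdir: str | Path = ".") -> dict:
    """Generate a synthetic screen and write it as a fixture bundle.

    Writes one intensity TSV per condition, the design YAML and the
    ground-truth TSV; returns the paths plus the in-memory objects.
    """
    params = params or SimParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, design, truth = generate_dataset(params)
    paths = {}
    for condition in design.conditions:
        sub = table.subset_runs(design.condition_runs(condition))
        p = outdir / f"intensities_{condition}.tsv"
        write_maxquant_like(sub, p)
        paths[f"intensities_{condition}"] = p
    save_design(design, outdir / "design.yaml")
    paths["design"] = outdir / "design.yaml"
    write_truth(truth, outdir / "truth.tsv")
    paths["truth"] = outdir / "truth.tsv"
    _write_manifest(outdir, "simulate", dataclasses.asdict(params), [])
    return {"paths": paths, "table": table, "design": design, "truth": truth}


def run_processing(
    table: IntensityTable,
    design: SampleDesign,
    strategy: str = "both",
    quant_cfg: QuantConfig | None = None,
    outdir: str | Path | None = None,
    input_names: list[str] | None = None,
) -> dict:
    """Run the selected strategy/strategies over every (bait, condition).

    Returns ``{"qualitative": {(bait, cond): QualitativeHitList},
    "quantitative": {(bait, cond): records DataFrame},
    "global_stats": [...]}`` (keys present per strategy); if ``outdir``
    is given, also writes one TSV per (bait, condition) and strategy,
    the condition-level global statistics and a manifest.
    """
    if strategy not in ("qualitative", "quantitative", "both"):
        raise ValueError(f"unknown strategy {strategy!r}")
    quant_cfg = quant_cfg or QuantConfig()
    results: dict = {}
    if strategy in ("qualitative", "both"):
        results["qualitative"] = {
            (bait, cond): qualitative_screen_group(table, design, bait, cond)
            for bait, cond in design.experiment_groups()
        }
    if strategy in ("quantitative", "both"):
        results["quantitative"] = quantitative_screen(table, design, quant_cfg)
        results["global_stats"] = condition_global_stats(table, design, quant_cfg)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (bait, cond), hit_list in results.get("qualitative", {}).items():
            write_hit_list(
                hit_list, table, design, outdir / f"qualitative_{bait}_{cond}.tsv"
            )
        for (bait, cond), records in results.get("quantitative", {}).items():
            write_records(records, outdir / f"quantitative_{bait}_{cond}.tsv")
        if "global_stats" in results:
            write_global_stats(results["global_stats"], outdir / "global_stats.tsv")
        _write_manifest(
            outdir,
            "process",
            {"strategy": strategy, "quant": dataclasses.asdict(quant_cfg)},
            input_names or [],
        )
    return results


def run_report(
    quant_results: dict,
    outdir: str | Path,
    categories: CategoryMap | None = None,
    similarity_mode: str = "weighted",
) -> dict:
    """Turn quantitative screen results into network and summary files.

    Writes SIF/GraphML/TSV network exports, a node table, per-bait
    condition-overlap (Venn) counts, the bait-similarity matrix and
    per-(bait, condition) volcano tables. ``quant_results`` is the
    ``"quantitative"`` mapping returned by :func:`run_processing`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = build_network(list(quant_results.values()), categories)
    export_network(edges, "SIF", outdir / "network.sif")
    export_network(edges, "GraphML", outdir / "network.graphml")
    export_network(edges, "TSV", outdir / "edges.tsv")
    write_node_table(edges, outdir / "nodes.tsv")

    hit_sets: dict[str, set] = {}
    by_bait_condition: dict[str, dict[str, set]] = {}
    for (bait, cond), records in quant_results.items():
        hits = set(records.loc[records["final_hit"], "accession"])
        hit_sets.setdefault(bait, set()).update(hits)
        by_bait_condition.setdefault(bait, {})[cond] = hits

    venn_rows = []
    for bait, per_cond in by_bait_condition.items():
        if len(per_cond) == 3:
            for region, count in condition_overlap(per_cond).items():
                venn_rows.append(
                    {"bait": bait, "region": "&".join(region), "count": count}
                )
    pd.DataFrame(venn_rows, columns=["bait", "region", "count"]).to_csv(
        outdir / "condition_overlap.tsv", sep="\t", index=False
    )

    similarity = None
    if len(hit_sets) >= 2:
        similarity = bait_similarity(hit_sets, mode=similarity_mode)
        similarity.to_csv(outdir / f"bait_similarity_{similarity_mode}.tsv", sep="\t")

    for (bait, cond), records in quant_results.items():
        for control in ("c1", "c2"):
            volcano_table(records, control).to_csv(
                outdir / f"volcano_{bait}_{cond}_{control}.tsv", sep="\t", index=False
            )

    _write_manifest(outdir, "report", {"similarity_mode": similarity_mode}, [])
    return {"edges": edges, "hit_sets": hit_sets, "similarity": similarity}
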