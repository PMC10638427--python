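"""Presence/absence (qualitative) hit calling.

The strictest reading of a double-control AP-MS screen: a prey is a hit
for a bait under a condition only if it was detected (raw intensity > 0)
in all three experimental replicates and never detected — in any
replicate — of either the untagged-strain control or the
heterologous-tag control. Intensities play no role beyond detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .design import SampleDesign
from .errors import DataError
from .io import IntensityTable

REPLICATES = 3


@dataclass(frozen=True)
class DetectionSet:
    """Accessions detected (raw intensity > 0) in one LC-MS/MS run."""

    run_code: str
    accessions: frozenset


@dataclass(frozen=True)
class QualitativeHitList:
    """Hits for one (bait, condition): the experimental triplicate core
    minus everything seen in any control replicate."""

    bait: str
    condition: str
    hits: frozenset


def detected_accessions(table: IntensityTable, run_code: str) -> DetectionSet:
    """Accessions with raw intensity strictly greater than 0 in a run."""
    col = table.column(run_code)
    return DetectionSet(run_code, frozenset(col.index[col.to_numpy() > 0]))


def _require_three(reps: Sequence[DetectionSet]) -> None:
    if len(reps) != REPLICATES:
        raise DataError(f"expected exactly {REPLICATES} replicates, got {len(reps)}")


def triplicate_core(reps: Sequence[DetectionSet]) -> frozenset:
    """Proteins detected in all three replicates (three-way intersection)."""
    _require_three(reps)
    a, b, c = (r.accessions for r in reps)
    return frozenset(a & b & c)


def qualitative_hits(
    core_exp: Iterable,
    control1_reps: Sequence[DetectionSet],
    control2_reps: Sequence[DetectionSet],
    bait: str = "",
    condition: str = "",
) -> QualitativeHitList:
    """Reject any core protein detected in even one control replicate.

    The rejection set is the union of all six control detection sets —
    absence must hold in every replicate of both controls, not merely in
    the controls' triplicate cores.
    """
    _require_three(control1_reps)
    _require_three(control2_reps)
    rejected: set = set()
    for r in (*control1_reps, *control2_reps):
        rejected |= r.accessions
    return QualitativeHitList(bait, condition, frozenset(core_exp) - rejected)


def qualitative_screen_group(
    table: IntensityTable, design: SampleDesign, bait: str, condition: str
) -> QualitativeHitList:
    """Run the full qualitative strategy for one (bait, condition)."""
    exp = [detected_accessions(table, r) for r in design.runs_for(bait, condition)]
    c1 = [detected_accessions(table, r) for r in design.control_runs(condition, "control1")]
    c2 = [detected_accessions(table, r) for r in design.control_runs(condition, "control2")]
    return qualitative_hits(triplicate_core(exp), c1, c2, bait=bait, condition=condition)


def replicate_overlap_fraction(reps: Sequence[DetectionSet]) -> float:
    """|three-way intersection| / |three-way union| of replicate detections.

    Measures replicate reproducibility; returns NaN when no protein was
    detected in any replicate (undefined).
    """
    _require_three(reps)
    union = reps[0].accessions | reps[1].accessions | reps[2].accessions
    if not union:
        return math.nan
    return len(triplicate_core(reps)) / len(union)


def write_hit_list(
    hit_list: QualitativeHitList,
    table: IntensityTable,
    design: SampleDesign,
    path: str | Path,
) -> Path:
    """Write one (bait, condition) hit list as TSV.

    Carries gene name, description and the per-replicate normalized
    log10 intensities of the experimental runs, so the user can sort and
    compare hits even though the qualitative call ignores intensity.
    """
    from .quantitative import normalize_and_log  # local import; no cycle at runtime

    runs = design.runs_for(hit_list.bait, hit_list.condition)
    norm = {r: normalize_and_log(table, r) for r in runs}
    accs = [a for a in table.accessions if a in hit_list.hits]
    out = pd.DataFrame(
        {
            "accession": accs,
            "gene": table.proteins.loc[accs, "gene"].to_numpy(),
            "description": table.proteins.loc[accs, "description"].to_numpy(),
        }
    )
    for i, r in enumerate(runs, start=1):
        out[f"norm_log10_rep{i}"] = norm[r].loc[accs].to_numpy()
    out.to_csv(path, sep="\t", index=False)
    return Path(path)
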