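"""Intensity-based (quantitative) hit calling.

A background binder is not necessarily a false positive: a prey may
stick weakly to the resin or the tag yet still be pulled down in
significantly higher amount by its true bait. This strategy therefore
compares intensities instead of mere presence:

1. within each run, divide every raw intensity by the run's median
   nonzero intensity (inter-run normalization); a raw 0 (not detected)
   maps to a normalized value of 1;
2. take log10, so "not detected" becomes exactly 0;
3. pool every transformed value of a growth condition (all baits and
   both controls, placeholder zeros included) into a single global
   variance / standard deviation for that condition;
4. average each protein's three replicate values per sample
   ("av_intensity");
5. against each control: if the control average is exactly 0 the
   protein is *absent in control* (no test needed); otherwise require a
   log2-scale enrichment >= 1.5 and assess it with a one-sided z-score
   using the condition's global SD, Benjamini-Hochberg-adjusted within
   the family of tested proteins;
6. a final hit must be detected in all three experimental replicates
   and be absent-or-significantly-enriched relative to *both* controls.

Reductions (means, pooled variance) are accumulated sequentially in a
fixed run-major, row-major order so results are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign
from .errors import DataError, StatsError
from .io import IntensityTable

logger = logging.getLogger(__name__)

LOG10_2 = math.log10(2.0)
_SQRT2 = math.sqrt(2.0)

VERDICT_ABSENT = "absent_in_control"
VERDICT_ENRICHED = "enriched"
VERDICT_REJECTED = "rejected"

RECORD_COLUMNS = [
    "accession", "gene", "description", "bait", "condition",
    "norm_rep1", "norm_rep2", "norm_rep3",
    "av_exp", "av_c1", "av_c2",
    "log2fc_c1", "log2fc_c2", "z_c1", "z_c2",
    "p_c1", "p_c2", "padj_c1", "padj_c2",
    "verdict_c1", "verdict_c2", "present_all_reps", "final_hit",
]


@dataclass(frozen=True)
class QuantConfig:
    """Tunable thresholds and modes of the quantitative strategy.

    fold_threshold_log2:
        Minimum enrichment of experiment over control, on the log2
        scale (default 1.5, boundary inclusive).
    alpha_adjusted:
        Maximum BH-adjusted one-sided p-value (default 0.01).
    sd_mode:
        ``"sample"`` (n-1 denominator, default) or ``"population"`` for
        the condition-wide global variance.
    zscore_scale:
        ``"raw"`` (default): z = (av_exp - av_ctrl)/global_sd.
        ``"mean_of_three"``: divide additionally by sqrt(2/3), the SD of
        a difference of two means of three values.
    fold_scale:
        ``"log2"`` (default): apply the threshold to
        (av_exp - av_ctrl)/log10(2). ``"log10"``: apply it directly to
        the log10 difference.
    bh_family:
        ``"per_control"`` (default): adjust p-values separately per
        control within one (bait, condition). ``"per_sample"``: pool
        both controls' tested p-values into one family.
    """

    fold_threshold_log2: float = 1.5
    alpha_adjusted: float = 0.01
    sd_mode: str = "sample"
    zscore_scale: str = "raw"
    fold_scale: str = "log2"
    bh_family: str = "per_control"

    def __post_init__(self) -> None:
        if not self.fold_threshold_log2 > 0:
            raise DataError("fold_threshold_log2 must be > 0")
        if not 0 < self.alpha_adjusted < 1:
            raise DataError("alpha_adjusted must be in (0, 1)")
        if self.sd_mode not in ("sample", "population"):
            raise DataError(f"unknown sd_mode {self.sd_mode!r}")
        if self.zscore_scale not in ("raw", "mean_of_three"):
            raise DataError(f"unknown zscore_scale {self.zscore_scale!r}")
        if self.fold_scale not in ("log2", "log10"):
            raise DataError(f"unknown fold_scale {self.fold_scale!r}")
        if self.bh_family not in ("per_control", "per_sample"):
            raise DataError(f"unknown bh_family {self.bh_family!r}")


@dataclass(frozen=True)
class GlobalStats:
    """Pooled dispersion of all transformed intensities of one condition."""

    condition: str
    global_variance: float
    global_sd: float
    n_values: int


class VerdictResult(NamedTuple):
    verdict: str
    log2fc: float  # NaN when the control average is 0
    z: float  # NaN unless tested
    p: float  # NaN unless tested


def normalize_and_log(table: IntensityTable, run_code: str) -> pd.Series:
    """Median-normalize one run and take log10.

    value = log10(raw / median_of_nonzero_raws) for detected proteins,
    0 for raw = 0 (the "replace with 1 before log" rule). A run with no
    detections yields an all-zero column (logged as a warning).
    """
    raw = table.column(run_code).to_numpy(dtype=float)
    out = np.zeros(raw.shape[0], dtype=float)
    mask = raw > 0
    if not mask.any():
        logger.warning("run %s has no nonzero intensities; column is all zero", run_code)
    else:
        median = float(np.median(raw[mask]))
        # scalar log10: bit-reproducible across platforms/SIMD paths
        out[mask] = [math.log10(v / median) for v in raw[mask]]
    return pd.Series(out, index=table.accessions, name=run_code)


def global_stats(
    columns: Iterable, mode: str = "sample", condition: str = ""
) -> GlobalStats:
    """Variance/SD over the pooled multiset of transformed values.

    ``columns`` are the normalized log10 columns of *all* samples of one
    growth condition (experiments and controls, zero placeholders
    included). Pooling is a multiset operation: how values are grouped
    into columns does not matter.
    """
    if mode not in ("sample", "population"):
        raise DataError(f"unknown sd_mode {mode!r}")
    values: list[float] = []
    for col in columns:
        values.extend(float(v) for v in np.asarray(col, dtype=float))
    n = len(values)
    if n < 2:
        raise StatsError(f"need at least 2 values for global stats, got {n}")
    total = 0.0
    for v in values:
        total += v
    mean = total / n
    ss = 0.0
    for v in values:
        ss += (v - mean) ** 2
    var = ss / (n - 1) if mode == "sample" else ss / n
    return GlobalStats(condition, var, math.sqrt(var), n)


def average_triplicate(values: Sequence[float]) -> float:
    """Arithmetic mean of the three replicate values ("av_intensity")."""
    if len(values) != 3:
        raise DataError(f"expected exactly 3 replicate values, got {len(values)}")
    return (values[0] + values[1] + values[2]) / 3


def upper_tail_p(z: float) -> float:
    """One-sided upper-tail standard-normal probability."""
    return math.erfc(z / _SQRT2) / 2


def control_verdict(
    av_exp: float, av_ctrl: float, stats: GlobalStats, cfg: QuantConfig
) -> VerdictResult:
    """Judge one protein against one control (before BH adjustment).

    A control average of exactly 0 means the protein was never scored in
    that control: verdict ``absent_in_control``, no test performed.
    Otherwise the enrichment must reach the fold threshold
    (``rejected`` if not) and is then assigned a one-sided z and p
    (verdict ``enriched``; significance is settled later by the adjusted
    p-value).
    """
    if av_ctrl == 0:
        return VerdictResult(VERDICT_ABSENT, math.nan, math.nan, math.nan)
    diff = av_exp - av_ctrl
    log2fc = diff / LOG10_2
    effect = log2fc if cfg.fold_scale == "log2" else diff
    if not effect >= cfg.fold_threshold_log2:
        return VerdictResult(VERDICT_REJECTED, log2fc, math.nan, math.nan)
    scale = 1.0 if cfg.zscore_scale == "raw" else math.sqrt(2.0 / 3.0)
    denom = stats.global_sd * scale
    if denom == 0:
        logger.warning(
            "global SD is 0 with enrichment %.3g; p set to 0 by convention", diff
        )
        return VerdictResult(VERDICT_ENRICHED, log2fc, math.inf, 0.0)
    z = diff / denom
    return VerdictResult(VERDICT_ENRICHED, log2fc, z, upper_tail_p(z))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    adjusted[i] = min(1, min_{j: rank >= rank_i} p_j * m / rank_j), the
    standard step-up; ties are handled by stable sorting.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = (p[order] * m) / np.arange(1, m + 1, dtype=float)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def quantitative_hits(
    table: IntensityTable,
    design: SampleDesign,
    bait: str,
    condition: str,
    cfg: QuantConfig | None = None,
) -> pd.DataFrame:
    """Run the full quantitative strategy for one (bait, condition).

    Returns one row (see :data:`RECORD_COLUMNS`) per protein detected in
    at least one experimental replicate — not only the hits — flagged by
    ``final_hit``, so every intermediate quantity can be inspected or
    deposited. BH adjustment is applied within the family of proteins
    that actually required a test for a given control (control average
    > 0 and fold threshold met) in this (bait, condition).
    """
    cfg = cfg or QuantConfig()
    exp_runs = design.runs_for(bait, condition)
    c1_runs = design.control_runs(condition, "control1")
    c2_runs = design.control_runs(condition, "control2")
    cond_runs = design.condition_runs(condition)
    for r in cond_runs:
        if r not in table.intensities.columns:
            raise DataError(f"design run {r!r} missing from intensity table")

    norm = {r: normalize_and_log(table, r) for r in cond_runs}
    stats = global_stats(
        [norm[r] for r in cond_runs], mode=cfg.sd_mode, condition=condition
    )

    raw = table.intensities
    detected = raw[list(exp_runs)].to_numpy() > 0
    keep = detected.any(axis=1)
    accs = [a for a, k in zip(table.accessions, keep) if k]

    rows: list[dict] = []
    for acc in accs:
        reps = [float(norm[r].loc[acc]) for r in exp_runs]
        av_exp = average_triplicate(reps)
        av_c1 = average_triplicate([float(norm[r].loc[acc]) for r in c1_runs])
        av_c2 = average_triplicate([float(norm[r].loc[acc]) for r in c2_runs])
        v1 = control_verdict(av_exp, av_c1, stats, cfg)
        v2 = control_verdict(av_exp, av_c2, stats, cfg)
        present_all = bool(all(raw.loc[acc, r] > 0 for r in exp_runs))
        rows.append(
            {
                "accession": acc,
                "gene": table.proteins.loc[acc, "gene"],
                "description": table.proteins.loc[acc, "description"],
                "bait": bait,
                "condition": condition,
                "norm_rep1": reps[0],
                "norm_rep2": reps[1],
                "norm_rep3": reps[2],
                "av_exp": av_exp,
                "av_c1": av_c1,
                "av_c2": av_c2,
                "log2fc_c1": v1.log2fc,
                "log2fc_c2": v2.log2fc,
                "z_c1": v1.z,
                "z_c2": v2.z,
                "p_c1": v1.p,
                "p_c2": v2.p,
                "padj_c1": math.nan,
                "padj_c2": math.nan,
                "verdict_c1": v1.verdict,
                "verdict_c2": v2.verdict,
                "present_all_reps": present_all,
                "final_hit": False,
            }
        )

    tested1 = [i for i, r in enumerate(rows) if r["verdict_c1"] == VERDICT_ENRICHED]
    tested2 = [i for i, r in enumerate(rows) if r["verdict_c2"] == VERDICT_ENRICHED]
    if cfg.bh_family == "per_control":
        for tested, key in ((tested1, "c1"), (tested2, "c2")):
            if tested:
                adj = bh_adjust([rows[i][f"p_{key}"] for i in tested])
                for i, a in zip(tested, adj):
                    rows[i][f"padj_{key}"] = float(a)
    else:  # per_sample: one family pooling both controls
        family = [(i, "c1") for i in tested1] + [(i, "c2") for i in tested2]
        if family:
            adj = bh_adjust([rows[i][f"p_{key}"] for i, key in family])
            for (i, key), a in zip(family, adj):
                rows[i][f"padj_{key}"] = float(a)

    for r in rows:
        ok1 = r["verdict_c1"] == VERDICT_ABSENT or (
            r["verdict_c1"] == VERDICT_ENRICHED
            and r["padj_c1"] <= cfg.alpha_adjusted
        )
        ok2 = r["verdict_c2"] == VERDICT_ABSENT or (
            r["verdict_c2"] == VERDICT_ENRICHED
            and r["padj_c2"] <= cfg.alpha_adjusted
        )
        r["final_hit"] = bool(r["present_all_reps"] and ok1 and ok2)

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def quantitative_screen(
    table: IntensityTable, design: SampleDesign, cfg: QuantConfig | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    """Quantitative records for every (bait, condition) in the design."""
    cfg = cfg or QuantConfig()
    return {
        (bait, condition): quantitative_hits(table, design, bait, condition, cfg)
        for bait, condition in design.experiment_groups()
    }


def condition_global_stats(
    table: IntensityTable, design: SampleDesign, cfg: QuantConfig | None = None
) -> list[GlobalStats]:
    """GlobalStats of every condition in the design (for reporting)."""
    cfg = cfg or QuantConfig()
    out = []
    for condition in design.conditions:
        cols = [normalize_and_log(table, r) for r in design.condition_runs(condition)]
        out.append(global_stats(cols, mode=cfg.sd_mode, condition=condition))
    return out


def write_records(records: pd.DataFrame, path: str | Path) -> Path:
    """Write one (bait, condition) record table as TSV."""
    records.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_global_stats(stats: Sequence[GlobalStats], path: str | Path) -> Path:
    """Write condition-level global statistics as TSV."""
    pd.DataFrame(
        {
            "condition": [s.condition for s in stats],
            "n_values": [s.n_values for s in stats],
            "global_variance": [s.global_variance for s in stats],
            "global_sd": [s.global_sd for s in stats],
        }
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def with_alpha(cfg: QuantConfig, alpha: float) -> QuantConfig:
    """Convenience: same config with a different adjusted-p cutoff."""
    return replace(cfg, alpha_adjusted=alpha)
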