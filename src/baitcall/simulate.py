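"""Synthetic AP-MS datasets with known ground truth.

The generator emulates what the double-control design is built to
disentangle, one protein class per background mechanism:

* ``bait`` — the tagged protein itself: expressed everywhere (it is a
  native protein of the background strain) and strongly boosted in its
  own pull-down;
* ``specific_prey`` — a true interactant of one bait; either present
  *only* in that bait's pull-downs (``prey_mode="exclusive"``, the only
  kind a presence/absence strategy can see) or present everywhere but
  enriched by ``effect_log10`` in its bait's pull-downs
  (``prey_mode="enriched"``, detectable only by the quantitative
  strategy);
* ``resin_binder`` — sticks to the chromatography resins: present at an
  equal expected level in every sample, including the untagged control;
* ``tag_binder`` — binds the affinity tag: present in the tagged
  control and in all experimental pull-downs, absent from the untagged
  control;
* ``bystander`` — ordinary background, present everywhere at baseline.

Raw intensities are lognormal: 10**(protein baseline + class/role
offset + Normal(0, replicate_noise_sd)), then zeroed with probability
``dropout_prob`` (stochastic nondetection). Protein baselines are drawn
once from Normal(baseline_log10_mean, baseline_log10_sd).

Draw order (stable across versions): 1) all protein baselines; then per
condition, per sample group in design order (baits, control1,
control2), per replicate: one noise vector over all proteins followed
by one dropout-uniform vector over all proteins. Dropout uniforms are
drawn even when dropout_prob = 0 so intensities are comparable across
dropout settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import SampleDesign, SampleEntry
from .errors import ParameterError
from .io import IntensityTable, make_table

CLASS_BAIT = "bait"
CLASS_PREY = "specific_prey"
CLASS_RESIN = "resin_binder"
CLASS_TAG = "tag_binder"
CLASS_BYSTANDER = "bystander"

DEFAULT_CONDITIONS = ("LB_log", "LB_ON", "M9_ac_ON")


@dataclass(frozen=True)
class SimParams:
    """Stated world of the default benchmark.

    Defaults: 300 proteins, 3 baits with 10 exclusive-presence preys
    each, 30 resin binders, 20 tag binders, the rest bystanders;
    Orbitrap-scale baseline abundance 10**Normal(7, 0.5); prey effect
    2.0 log10 units; replicate noise 0.15 log10; no dropout; bait
    boosted 2.0 log10 in its own pull-down; seed 42.
    """

    n_proteins: int = 300
    n_baits: int = 3
    preys_per_bait: int = 10
    n_resin_binders: int = 30
    n_tag_binders: int = 20
    baseline_log10_mean: float = 7.0
    baseline_log10_sd: float = 0.5
    effect_log10: float = 2.0
    replicate_noise_sd: float = 0.15
    dropout_prob: float = 0.0
    bait_log10_boost: float = 2.0
    prey_mode: str = "exclusive"  # or "enriched"
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_baits", "preys_per_bait",
                     "n_resin_binders", "n_tag_binders"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_baits < 1:
            raise ParameterError("n_baits must be >= 1")
        planted = (self.n_baits + self.n_baits * self.preys_per_bait
                   + self.n_resin_binders + self.n_tag_binders)
        if planted > self.n_proteins:
            raise ParameterError(
                f"n_proteins={self.n_proteins} too small for "
                f"{planted} planted proteins (baits + preys + resin + tag binders)"
            )
        for name in ("baseline_log10_sd", "effect_log10",
                     "replicate_noise_sd", "bait_log10_boost"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ParameterError("dropout_prob must be in [0, 1)")
        if self.prey_mode not in ("exclusive", "enriched"):
            raise ParameterError(f"unknown prey_mode {self.prey_mode!r}")
        if not self.conditions:
            raise ParameterError("conditions must be nonempty")
        object.__setattr__(self, "conditions", tuple(self.conditions))


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``table`` is indexed by accession with columns ``protein_class``,
    ``owner_bait`` (the bait a specific prey belongs to; the bait's own
    name for bait rows; empty otherwise) and ``baseline_log10``.
    """

    table: pd.DataFrame
    params: SimParams = field(repr=False)

    def members(self, protein_class: str) -> frozenset:
        return frozenset(
            self.table.index[self.table["protein_class"] == protein_class]
        )

    def preys_of(self, bait: str) -> frozenset:
        sel = (self.table["protein_class"] == CLASS_PREY) & (
            self.table["owner_bait"] == bait
        )
        return frozenset(self.table.index[sel])

    def bait_accession(self, bait: str) -> str:
        sel = (self.table["protein_class"] == CLASS_BAIT) & (
            self.table["owner_bait"] == bait
        )
        (acc,) = self.table.index[sel]
        return acc

    def expected_mean_log10(self, accession: str, entry: SampleEntry) -> Optional[float]:
        """Expected log10 intensity of a protein in one run; None if the
        protein is planted absent from that sample."""
        row = self.table.loc[accession]
        present, offset = _presence_offset(
            row["protein_class"], row["owner_bait"], entry, self.params
        )
        return float(row["baseline_log10"] + offset) if present else None


def _presence_offset(
    protein_class: str, owner: str, entry: SampleEntry, params: SimParams
) -> tuple[bool, float]:
    """(present?, mean log10 offset) of one protein class in one sample."""
    own_pulldown = entry.role == "experiment" and entry.bait == owner
    if protein_class == CLASS_BAIT:
        return True, params.bait_log10_boost if own_pulldown else 0.0
    if protein_class == CLASS_PREY:
        if params.prey_mode == "exclusive":
            return own_pulldown, 0.0
        return True, params.effect_log10 if own_pulldown else 0.0
    if protein_class == CLASS_RESIN:
        return True, 0.0
    if protein_class == CLASS_TAG:
        return entry.role != "control1", 0.0
    return True, 0.0  # bystander


def _build_design(params: SimParams) -> SampleDesign:
    baits = [f"Bait{i + 1}" for i in range(params.n_baits)]
    entries: list[SampleEntry] = []
    for condition in params.conditions:
        for bait in baits:
            for rep in (1, 2, 3):
                entries.append(
                    SampleEntry(f"{bait}.{condition}.r{rep}", bait, condition,
                                rep, "experiment")
                )
        for rep in (1, 2, 3):
            entries.append(
                SampleEntry(f"untagged.{condition}.r{rep}", "untagged_wt",
                            condition, rep, "control1")
            )
        for rep in (1, 2, 3):
            entries.append(
                SampleEntry(f"tagctrl.{condition}.r{rep}", "tagged_decoy",
                            condition, rep, "control2")
            )
    return SampleDesign(entries)


def _assign_classes(params: SimParams) -> pd.DataFrame:
    classes: list[str] = []
    owners: list[str] = []
    genes: list[str] = []
    baits = [f"Bait{i + 1}" for i in range(params.n_baits)]
    for bait in baits:
        classes.append(CLASS_BAIT)
        owners.append(bait)
        genes.append(f"bait_{bait}")
    for bait in baits:
        for j in range(params.preys_per_bait):
            classes.append(CLASS_PREY)
            owners.append(bait)
            genes.append(f"prey_{bait}_{j + 1}")
    for j in range(params.n_resin_binders):
        classes.append(CLASS_RESIN)
        owners.append("")
        genes.append(f"resin_{j + 1}")
    for j in range(params.n_tag_binders):
        classes.append(CLASS_TAG)
        owners.append("")
        genes.append(f"tag_{j + 1}")
    while len(classes) < params.n_proteins:
        j = len(classes)
        classes.append(CLASS_BYSTANDER)
        owners.append("")
        genes.append(f"byst_{j + 1}")
    accessions = [f"P{i:05d}" for i in range(params.n_proteins)]
    return pd.DataFrame(
        {"protein_class": classes, "owner_bait": owners, "gene": genes},
        index=pd.Index(accessions, name="accession"),
    )


def generate_dataset(
    params: SimParams | None = None,
) -> tuple[IntensityTable, SampleDesign, SyntheticTruth]:
    """Draw one synthetic screen: intensity table, design, ground truth.

    Deterministic: the same params (including seed) always produce an
    identical dataset.
    """
    params = params or SimParams()
    design = _build_design(params)
    assignment = _assign_classes(params)
    rng = np.random.default_rng(params.seed)

    n = params.n_proteins
    baselines = rng.normal(params.baseline_log10_mean, params.baseline_log10_sd, n)

    cls_list = assignment["protein_class"].tolist()
    owner_list = assignment["owner_bait"].tolist()
    columns: dict[str, np.ndarray] = {}
    for entry in design.entries:
        noise = rng.normal(0.0, params.replicate_noise_sd, n)
        dropout_u = rng.uniform(size=n)
        col = np.zeros(n, dtype=float)
        for i in range(n):
            present, offset = _presence_offset(
                cls_list[i], owner_list[i], entry, params
            )
            if present and dropout_u[i] >= params.dropout_prob:
                col[i] = 10.0 ** (baselines[i] + offset + noise[i])
        columns[entry.run_code] = col

    table = make_table(
        assignment.index,
        [e.run_code for e in design.entries],
        np.column_stack([columns[e.run_code] for e in design.entries]),
        genes=assignment["gene"],
        descriptions=[
            f"synthetic {c}" for c in assignment["protein_class"]
        ],
    )
    truth_table = assignment[["protein_class", "owner_bait"]].copy()
    truth_table["baseline_log10"] = baselines
    return table, design, SyntheticTruth(truth_table, params)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground-truth table as TSV."""
    truth.table.to_csv(path, sep="\t")
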