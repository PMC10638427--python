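"""Experimental sample design for a double-control AP-MS screen.

A screen consists of bait pull-downs and two kinds of negative control,
each grown under one or more conditions and purified in biological
triplicate:

* ``experiment`` — a strain expressing one tagged bait protein;
* ``control1``  — the untagged background strain (captures proteins that
  stick to the chromatography resins);
* ``control2``  — the same strain expressing an unrelated tagged protein
  (captures proteins that bind the affinity tag itself).

Every LC-MS/MS run is identified by a short run code; the design maps
run codes to ``(bait-or-control, condition, replicate, role)``. The
packaged default design describes the E. coli replication-protein screen
this package was written around: 8 baits (DiaA, DnaA, DnaB, DnaG, Hda,
HolD, NrdB, SeqA) x 3 growth conditions (LB_log, LB_ON, M9_ac_ON) x 3
replicates, plus both control types in triplicate per condition — 90
runs in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import DesignError

ROLES = ("experiment", "control1", "control2")

REPLICATES_PER_GROUP = 3


@dataclass(frozen=True)
class SampleEntry:
    """One LC-MS/MS run: its code and its place in the design."""

    run_code: str
    bait: str  # bait protein name, or the control strain label
    condition: str
    replicate: int  # 1-based
    role: str  # one of ROLES


class SampleDesign:
    """Validated mapping of run codes to samples.

    Construct with :func:`load_design`, :meth:`SampleDesign.from_dict` or
    :func:`default_design`.
    """

    def __init__(self, entries: Iterable[SampleEntry]):
        self.entries: tuple[SampleEntry, ...] = tuple(entries)
        self._by_run: dict[str, SampleEntry] = {}
        for e in self.entries:
            if e.role not in ROLES:
                raise DesignError(f"unknown role {e.role!r} for run {e.run_code!r}")
            if e.run_code in self._by_run:
                raise DesignError(f"duplicate run code {e.run_code!r}")
            self._by_run[e.run_code] = e
        self._validate_groups()

    # -- validation ---------------------------------------------------------

    def _validate_groups(self) -> None:
        groups: dict[tuple[str, str, str], list[SampleEntry]] = {}
        for e in self.entries:
            groups.setdefault((e.bait, e.condition, e.role), []).append(e)
        for (bait, condition, role), members in groups.items():
            if len(members) != REPLICATES_PER_GROUP:
                raise DesignError(
                    f"group ({bait!r}, {condition!r}, {role!r}) has "
                    f"{len(members)} replicates; expected {REPLICATES_PER_GROUP}"
                )
            if sorted(m.replicate for m in members) != list(
                range(1, REPLICATES_PER_GROUP + 1)
            ):
                raise DesignError(
                    f"group ({bait!r}, {condition!r}, {role!r}) replicates must "
                    f"be numbered 1..{REPLICATES_PER_GROUP}"
                )
        for condition in self.conditions:
            for role in ("control1", "control2"):
                labels = {
                    e.bait for e in self.entries
                    if e.condition == condition and e.role == role
                }
                if len(labels) != 1:
                    raise DesignError(
                        f"condition {condition!r} must have exactly one {role} "
                        f"group, found {sorted(labels)}"
                    )

    # -- queries ------------------------------------------------------------

    @property
    def run_codes(self) -> tuple[str, ...]:
        return tuple(e.run_code for e in self.entries)

    @property
    def baits(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.role == "experiment":
                seen.setdefault(e.bait)
        return tuple(seen)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.condition)
        return tuple(seen)

    def lookup(self, run_code: str) -> SampleEntry:
        try:
            return self._by_run[run_code]
        except KeyError:
            raise DesignError(f"unknown run code {run_code!r}") from None

    def runs_for(self, bait: str, condition: str) -> tuple[str, ...]:
        """Run codes of one experimental triplicate, in replicate order."""
        members = sorted(
            (e for e in self.entries
             if e.bait == bait and e.condition == condition
             and e.role == "experiment"),
            key=lambda e: e.replicate,
        )
        if not members:
            raise DesignError(f"no experimental group ({bait!r}, {condition!r})")
        return tuple(e.run_code for e in members)

    def control_runs(self, condition: str, role: str) -> tuple[str, ...]:
        """Run codes of one control triplicate, in replicate order."""
        if role not in ("control1", "control2"):
            raise DesignError(f"{role!r} is not a control role")
        members = sorted(
            (e for e in self.entries
             if e.condition == condition and e.role == role),
            key=lambda e: e.replicate,
        )
        if not members:
            raise DesignError(f"no {role} group for condition {condition!r}")
        return tuple(e.run_code for e in members)

    def condition_runs(self, condition: str) -> tuple[str, ...]:
        """All run codes of one condition (experiments and both controls),
        in design order."""
        codes = tuple(e.run_code for e in self.entries if e.condition == condition)
        if not codes:
            raise DesignError(f"unknown condition {condition!r}")
        return codes

    def experiment_groups(self) -> tuple[tuple[str, str], ...]:
        """All (bait, condition) experimental groups, in design order."""
        seen: dict[tuple[str, str], None] = {}
        for e in self.entries:
            if e.role == "experiment":
                seen.setdefault((e.bait, e.condition))
        return tuple(seen)

    # -- construction / serialisation ---------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "SampleDesign":
        try:
            conditions = list(cfg["conditions"])
            baits = cfg["baits"]
            controls = cfg["controls"]
        except (KeyError, TypeError) as exc:
            raise DesignError(f"design config missing section: {exc}") from exc
        entries: list[SampleEntry] = []

        def add_group(label: str, role: str, per_condition: Mapping) -> None:
            for condition, codes in per_condition.items():
                if condition not in conditions:
                    raise DesignError(
                        f"unknown condition {condition!r} for {label!r} "
                        f"(declared: {conditions})"
                    )
                for i, code in enumerate(codes, start=1):
                    entries.append(SampleEntry(str(code), label, condition, i, role))

        for bait, per_condition in baits.items():
            add_group(str(bait), "experiment", per_condition)
        for role in ("control1", "control2"):
            if role not in controls:
                raise DesignError(f"controls section must define {role!r}")
        extra = set(controls) - {"control1", "control2"}
        if extra:
            raise DesignError(f"unknown control role(s): {sorted(extra)}")
        for role in ("control1", "control2"):
            block = dict(controls[role])
            label = str(block.pop("label", role))
            add_group(label, role, block)
        return cls(entries)

    def to_dict(self) -> dict:
        """Inverse of :meth:`from_dict` (suitable for YAML dumping)."""
        baits: dict[str, dict[str, list[str]]] = {}
        controls: dict[str, dict] = {}
        for e in self.entries:
            if e.role == "experiment":
                baits.setdefault(e.bait, {}).setdefault(e.condition, []).append(
                    e.run_code
                )
            else:
                block = controls.setdefault(e.role, {"label": e.bait})
                block.setdefault(e.condition, []).append(e.run_code)
        return {
            "conditions": list(self.conditions),
            "baits": baits,
            "controls": controls,
        }


def load_design(config_path: str | Path) -> SampleDesign:
    """Read and validate a YAML sample-design file.

    The file declares ``conditions`` (list of labels), ``baits`` (mapping
    bait -> condition -> list of 3 run codes) and ``controls`` (mapping
    ``control1``/``control2`` -> optional ``label`` plus condition -> run
    codes). Raises :class:`~baitcall.errors.DesignError` on duplicate run
    codes, groups without exactly three replicates, or unknown
    role/condition labels.
    """
    path = Path(config_path)
    with path.open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise DesignError(f"{path} does not contain a design mapping")
    return SampleDesign.from_dict(cfg)


def save_design(design: SampleDesign, path: str | Path) -> None:
    """Write a design back to YAML (round-trips through load_design)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


@lru_cache(maxsize=1)
def default_design() -> SampleDesign:
    """The packaged E. coli replication-protein screen design (90 runs)."""
    ref = resources.files("baitcall").joinpath("data/ecoli_replication_design.yaml")
    cfg = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return SampleDesign.from_dict(cfg)
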