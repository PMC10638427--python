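"""Shared fixtures: tiny hand-built screens and random-instance builders."""

import numpy as np
import pytest

from baitcall import SampleDesign, SampleEntry, make_table


def toy_design(n_baits=1, conditions=("LB_log",)):
    """Minimal valid design: run codes e{b}.{c}.{r}, c1.{c}.{r}, c2.{c}.{r}."""
    entries = []
    for c in conditions:
        for b in range(1, n_baits + 1):
            for r in (1, 2, 3):
                entries.append(SampleEntry(f"e{b}.{c}.{r}", f"BaitA{b}", c, r, "experiment"))
        for r in (1, 2, 3):
            entries.append(SampleEntry(f"c1.{c}.{r}", "wt", c, r, "control1"))
        for r in (1, 2, 3):
            entries.append(SampleEntry(f"c2.{c}.{r}", "decoy", c, r, "control2"))
    return SampleDesign(entries)


def random_instance(seed, max_proteins=50, zero_prob=0.35):
    """One random single-bait, single-condition screen for oracle tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_proteins + 1))
    design = toy_design()
    runs = [e.run_code for e in design.entries]
    values = 10 ** rng.uniform(4.0, 8.0, size=(n, len(runs)))
    values[rng.uniform(size=values.shape) < zero_prob] = 0.0
    accs = [f"Q{i:04d}" for i in range(n)]
    table = make_table(accs, runs, values)
    return table, design


@pytest.fixture
def small_screen():
    """3-protein, single-bait screen with easily traced values."""
    design = toy_design()
    runs = [e.run_code for e in design.entries]
    rows = {
        # two background binders present everywhere at different levels
        # (two, so that neither sits exactly at the control median)
        "ACC0": {r: 1e6 for r in runs},
        "ACC1": {r: 4e6 for r in runs},
        # present only in the experimental triplicate
        "ACC2": {r: (5e6 if r.startswith("e") else 0.0) for r in runs},
        # present in 2 of 3 experimental replicates only
        "ACC3": {r: (2e6 if r in ("e1.LB_log.1", "e1.LB_log.2") else 0.0) for r in runs},
    }
    values = [[rows[a][r] for r in runs] for a in rows]
    table = make_table(list(rows), runs, values, genes=["g0", "g1", "g2", "g3"])
    return table, design
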