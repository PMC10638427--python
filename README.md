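# baitcall

Double negative-control hit calling for AP-MS protein-interaction screens.

## The problem

In affinity purification coupled with mass spectrometry (AP-MS), a tagged
bait protein is pulled down together with its interaction partners, which
are then identified and quantified (MaxQuant-style protein lists, one raw
intensity column per LC-MS/MS run). The read-out is dominated by two
classes of false positives: proteins that stick to the chromatography
resins, and proteins that bind the affinity tag itself. A double
negative-control design separates the two: **control 1** is the untagged
background strain (resin binders), **control 2** expresses an unrelated
tagged protein (tag binders). Each bait and control sample is purified in
biological triplicate, optionally across several growth conditions.

`baitcall` implements two complementary hit-calling strategies over this
design, a ground-truth synthetic data generator to benchmark them, and
condition-resolved interaction-network reporting. It was written around
an *E. coli* DNA-replication interactome screen (8 SPA-tagged baits × 3
growth conditions; the packaged default design) but applies to any
MaxQuant-style screen with the same control structure.

## The two strategies

**Qualitative (presence/absence).** A protein is a hit for bait *b*
under condition *c* iff it is detected (raw intensity > 0) in **all
three** experimental replicates and in **no replicate** of either
control. Strict, simple, and blind to preys that weakly contact the
resin or tag.

**Quantitative (normalized intensity).** A background binder is not
automatically a false positive if the bait pulls it down in
significantly higher amount. Per run, intensities are divided by the
median nonzero intensity and log10-transformed (raw 0 → normalized 1 →
log 0). All transformed values of one condition are pooled into a global
SD σ. With av the mean of three replicate values, the protein passes
against a control when either

- av_ctrl = 0 (absent from that control), or
- Δ = av_exp − av_ctrl satisfies Δ/log₁₀2 ≥ 1.5 and the one-sided
  z = Δ/σ survives Benjamini–Hochberg adjustment at padj ≤ 0.01
  (family: the tested proteins of that bait, condition and control),

and a final hit must be present in all three experimental replicates and
pass against **both** controls. All thresholds and the ambiguous modes
(fold scale, z scaling, SD denominator, BH family) are configurable via
`QuantConfig`; defaults are the values above.

## Worked example

```python
from baitcall import SimParams, QuantConfig, generate_dataset, quantitative_hits

params = SimParams(seed=42, prey_mode="enriched", effect_log10=2.0)
table, design, truth = generate_dataset(params)
rec = quantitative_hits(table, design, "Bait1", "LB_log", QuantConfig())
print(rec[rec.final_hit][["accession", "gene", "log2fc_c2", "padj_c2"]])
```

prints (run `python examples/03_quantitative_screen.py` for the full
script):

```
accession          gene   log2fc_c2  padj_c2
   P00000    bait_Bait1    6.397428 0.000533
   P00003  prey_Bait1_1    6.257007 0.000563
   ...
   P00012 prey_Bait1_10    7.490387 0.000322
```

Eleven final hits: the bait itself (boosted 2 log10 units in its own
pull-down, and always the most enriched protein — a standard sanity
check) and all ten planted preys, each ~6–7 log2 units above the tagged
control with BH-adjusted p ≪ 0.01. Resin binders, tag binders and
bystanders, present at equal levels in the controls, are rejected. In
`prey_mode="enriched"` the preys appear in the controls too, so the
qualitative strategy cannot see them; with exclusive-presence preys
(`examples/02_qualitative_screen.py`) it recovers exactly the planted
set.

The other examples: `01_simulate_dataset.py` writes a fixture bundle
(per-condition intensity TSVs, design YAML, truth TSV);
`04_network_report.py` exports Cytoscape-ready SIF/GraphML networks plus
condition-overlap (Venn) counts, the weighted bait-similarity matrix and
volcano tables.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch: it simulates
the default double-control screen with the given seed, runs both
hit-calling strategies over every (bait, condition), builds the network
report, and writes the results JSON to `--out`.

## Layout

- `src/baitcall/design.py` — run-code ↔ sample mapping, packaged default design
- `src/baitcall/io.py` — MaxQuant-style protein-list reader/writer, flag filtering
- `src/baitcall/qualitative.py` / `quantitative.py` — the two strategies
- `src/baitcall/simulate.py` — ground-truth synthetic screens
- `src/baitcall/network.py` — edges, Venn overlaps, similarity, volcano, exports
- `src/baitcall/pipeline.py` — simulate/process/report drivers with manifests
- `docs/methods.md` — model, assumptions, numerical choices, limitations
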