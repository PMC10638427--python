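"""Generate a synthetic double-control AP-MS screen with known truth.

Builds the default world — 300 proteins, 3 baits with 10 exclusive
preys each, resin binders, tag binders and bystanders, in triplicate
across three growth conditions — and writes it as a fixture bundle.
"""

from pathlib import Path

from baitcall import SimParams, simulate_bundle

out = Path("scratch/example_bundle")
params = SimParams(seed=42)
result = simulate_bundle(params, out)

table, truth = result["table"], result["truth"]
print(f"proteins: {table.n_proteins}, runs: {len(table.run_codes)}")
print("class counts:")
print(truth.table["protein_class"].value_counts().to_string())
print(f"files written under {out}/ (one intensity TSV per condition,")
print("design.yaml, truth.tsv) — the inputs every other example loads.")
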