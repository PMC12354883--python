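"""Run the whole pipeline: simulate -> filter -> force -> mobility -> QC.

Everything is driven by a single RunConfig (serializable to YAML; see
`smforce init-config`).  The result bundle embeds the config, so any run
is reproducible from its results.json alone.
"""

import tempfile

from smforce import RunConfig, run_pipeline

cfg = RunConfig(seed=7)  # default: 10% of tracks at 5 pN, 30% immobilized

with tempfile.TemporaryDirectory() as outdir:
    results = run_pipeline(cfg, outdir, figures=False)

hf = results["force"]["high_force_fraction"]
print(f"high-force fraction: {hf['fraction_point']:.4f} "
      f"(bootstrap SE {hf['bootstrap']['se']:.4f})")
pdf = results["force"]["force_pdf"]
print(f"force PDF median: {pdf['median']:.2f} pN (injected 5 pN)")
mob = results["mobility"]
print(f"immobilized fraction, cell: {mob['cell']['fraction']:.3f}; "
      f"no cell: {mob['no_cell']['fraction']:.3f}")
ks = results["stats"]["cell_vs_no_cell"]
print(f"cell vs no-cell KS: D+ = {ks['statistic']:.4f}, p = {ks['p_value']:.4f}")
print("QC gates:")
for gate in results["qc"]["gates"]:
    print(f"  {gate['name']}: {gate['verdict']}")
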