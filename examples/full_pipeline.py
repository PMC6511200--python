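"""Run the whole strain-evaluation pipeline on a mixed dataset.

Builds a dataset from the packaged FAME composition table plus synthetic
culture time series, composition measurements and a rapid light curve,
runs every analysis stage, and writes a versioned report bundle.
"""

import tempfile
from pathlib import Path

import pandas as pd

from algafuel import (
    ChemostatConfig,
    Dataset,
    RLCConfig,
    run_pipeline,
    simulate_chemostat_sweep,
    simulate_rlc,
    write_report,
)
from algafuel.io import _data_path  # packaged reference table

workdir = Path(tempfile.mkdtemp(prefix="algafuel-"))

d_grid = [0.1, 0.2, 0.3, 0.4, 0.6]
frames = []
for strain, seed in (("StrainA", 1), ("StrainB", 2)):
    sweep = simulate_chemostat_sweep(ChemostatConfig(), d_grid, seed=seed,
                                     strain=strain)
    frames.append(sweep.timeseries_frame())
pd.concat(frames).to_csv(workdir / "timeseries.csv", index=False)

comp = pd.DataFrame([
    {"strain": strain, "dilution_rate": d, "lipid_pct": lip,
     "fame_pct": lip * 0.6, "protein_pct": 25.0}
    for strain, lipids in (("StrainA", [15, 17.9, 16, 14, 12]),
                           ("StrainB", [12, 13, 14, 12, 10]))
    for d, lip in zip(d_grid, lipids)
])
comp.to_csv(workdir / "composition.csv", index=False)

simulate_rlc(RLCConfig(), seed=5).frame("StrainA-rlc").to_csv(
    workdir / "rlc.csv", index=False)

dataset = Dataset.from_paths(
    fame_profiles=_data_path("reference_fame_profiles.csv"),
    timeseries=workdir / "timeseries.csv",
    composition=workdir / "composition.csv",
    rlc=workdir / "rlc.csv",
)
bundle = run_pipeline(dataset, criterion="lipid")

print("strain ranking by lipid productivity at each strain's optimum:")
print(bundle.tables["ranking"].to_string(index=False))
print("\nPlatt fits:")
print(bundle.tables["rlc_fits"].to_string(index=False))

files = write_report(bundle, workdir / "report")
print(f"\nwrote {len(files)} report files to {workdir / 'report'} "
      f"(config hash {bundle.metadata['config_hash']})")
print("\nThe ranking orders strains by the productivity criterion at their "
      "individually optimal dilution rate; the report CSVs are stamped "
      "with the package version and configuration hash for provenance.")
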