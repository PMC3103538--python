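"""Full multi-regime pipeline on a synthetic salt-bridge dimer.

Generates three conformer ensembles of a toy two-chain peptide whose Glu and
Lys form a 3 Å salt bridge.  In the glu0 ensemble (sampled as if the acid
were neutral) the bridge is broken.  The pipeline computes per-snapshot
titration curves, averages them within each regime, weights the regimes by
pH and extracts pK1/2 — then repeats using only the all-charged (allC)
ensemble.  The acid's multi-regime pK lands above the allC-only value: a
single all-charged regime overestimates the salt-bridge stabilisation of
the deprotonated acid.
"""
import tempfile
from pathlib import Path

import numpy as np

from multipk.cli import RunConfig, run_titration
from multipk.fixtures import FixtureSpec, make_regime_ensembles
from multipk.structure_io import write_ensemble

spec = FixtureSpec(chains=("AEA", "AKA"), bridge=((0, 2), (1, 2), 3.0),
                   n_snapshots=2, jitter_sigma=0.15, seed=11)

with tempfile.TemporaryDirectory() as tmp:
    paths = {}
    for regime, ens in make_regime_ensembles(spec).items():
        p = Path(tmp) / f"{regime}.pdb"
        p.write_text(write_ensemble(ens))
        paths[regime] = str(p)

    multi = run_titration(RunConfig(inputs=paths, mode="multi-regime",
                                    output_dir=f"{tmp}/multi", ph_step=0.25, seed=1))
    allc = run_titration(RunConfig(inputs={"allC": paths["allC"]}, mode="single-regime",
                                   regime="allC", output_dir=f"{tmp}/allc",
                                   ph_step=0.25, seed=1))

print("pK1/2 per site (multi-regime combination):")
print(multi["pk_table"][["pk_half"]].to_string())

w = multi["weights"].weights
ph = multi["curves"][0].ph
print("\nregime weights:  pH 0: glu0 =", round(float(w["glu0"][0]), 3),
      "| pH 7: allC =", round(float(w["allC"][np.argmin(np.abs(ph - 7))]), 3),
      "| pH 14: lys0 =", round(float(w["lys0"][-1]), 3))

glu_multi = next(r.pk_mean for r in multi["results"] if r.site_key == ("GLU", 2, ""))
glu_allc = next(r.pk_mean for r in allc["results"] if r.site_key == ("GLU", 2, ""))
print(f"\nGlu pK1/2: allC-only {glu_allc:.2f}  vs  multi-regime {glu_multi:.2f}")
print("The upward shift is the regime correction: around its own midpoint the")
print("acid is half-neutral, so conformers without the salt bridge (glu0 set)")
print("carry comparable weight to the bridged all-charged conformers.")
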