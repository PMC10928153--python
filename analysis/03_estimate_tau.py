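#!/usr/bin/env python
"""Estimate tau three ways per subject and check estimator agreement.

On the clean derivation cohort the decay-fit tau and the pulse-pressure-
method product R_est * C_ppm must both sit on the ground truth R*C; the
closed-form formula with the fixed coefficient k' = 0.7 is the estimator
under study.  Writes the per-subject tau table and prints worst-case
relative errors of the exact estimators.
"""

from pathlib import Path

import numpy as np

from wktau.io import write_table
from wktau.pipeline import cohort_with_features, tau_table
from wktau.population import PopulationConfig

OUT = Path(__file__).resolve().parent.parent / "results"

def main() -> None:
    cohort, subjects = cohort_with_features(PopulationConfig(n=3818, seed=1))
    taus = tau_table(cohort, subjects, kprime=0.7)
    write_table(taus, OUT / "tau_estimates.csv")

    err_exp = np.max(np.abs(taus["tau_exp"] / taus["tau_ref"] - 1))
    err_ppm = np.max(np.abs(taus["C_ppm"] * taus["R_est"] / taus["tau_ref"] - 1))
    ratio = taus["tau_formula"] / taus["tau_ref"]
    print(f"tau battery for n={len(taus)} subjects -> {OUT/'tau_estimates.csv'}")
    print(f"  decay-fit tau vs R*C   : max |rel err| = {err_exp:.2e}")
    print(f"  R_est*C_ppm vs R*C     : max |rel err| = {err_ppm:.2e}")
    print(f"  formula (k'=0.7) vs R*C: mean ratio {ratio.mean():.3f} "
          f"(sd {ratio.std():.3f}) - the coefficient carries all remaining error")

if __name__ == "__main__":
    main()
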