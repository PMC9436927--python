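#!/usr/bin/env python
"""Design-stage power analysis for the three-group behavioural comparison.

How many animals per group does a one-way ANOVA need to detect a medium
effect (eta^2 = 0.1) at alpha = 0.05 with 80% power? Computes the analytic
noncentral-F power over a range of group sizes, cross-checks the design
point by simulation, and writes results/design_power.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from phenopet.pipeline import PowerSpec, anova_power, anova_power_mc

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    spec = PowerSpec(eta_squared=0.1, alpha=0.05, n_groups=3)
    rows = [{"n_per_group": n, "power": anova_power(spec, n)}
            for n in range(5, 61, 5)]
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "design_power.tsv", sep="\t", index=False,
                 float_format="%.4f")

    design = anova_power(spec, 30)
    mc = anova_power_mc(spec, 30, n_reps=10_000, seed=seed)
    first_ok = table[table.power >= 0.80].n_per_group.min()
    print(table.to_string(index=False))
    print(f"\nAt the study design point (n=30/group): analytic power "
          f"{design:.4f}, simulated {mc:.4f} (10 000 reps).")
    print(f"The smallest tabulated group size reaching 0.80 power is "
          f"n={first_ok}: 30 animals per group is just sufficient for a "
          f"medium (eta^2=0.1) behavioural effect.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
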