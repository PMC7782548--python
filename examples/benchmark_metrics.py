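"""Score a set of calculated binding free energies against experiment.

The package ships the six host-guest (OAMe / G1-G6) calculated-vs-measured
Delta G pairs as a built-in table; `sampl_metrics` reports the standard
blind-challenge regression metrics over any such table.
"""

from watercv import sampl_metrics
from watercv.sampl5 import OAME_TABLE

print(OAME_TABLE.to_string(index=False))
m = sampl_metrics(OAME_TABLE["calc"], OAME_TABLE["exp"])
print()
print(f"RMSE        = {m['rmse']:.2f} kcal/mol   (mean prediction error)")
print(f"Pearson r^2 = {m['r2']:.2f}            (fraction of variance captured)")
print(f"OLS slope   = {m['slope']:.2f}            (calc regressed on exp; >1 means"
      " the calculation spreads the ligands more than experiment)")
print(f"Kendall tau = {m['kendall_tau']:.2f}            (rank agreement over the"
      " 15 ligand pairs)")
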