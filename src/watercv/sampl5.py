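"""Published OAMe host-guest binding free energies (kcal/mol).

Six guests of the SAMPL5 octa-acid (OAMe) series: the water-CV calculation's
mean Delta G with its block error, and the experimental reference value.
These printed pairs are the input of the benchmark-metric surface.
"""

from __future__ import annotations

import pandas as pd

OAME_TABLE = pd.DataFrame(
    {
        "ligand": ["G1", "G2", "G3", "G4", "G5", "G6"],
        "calc": [-6.31, -6.19, -6.27, -2.51, -3.91, -4.97],
        "calc_err": [0.06, 0.08, 0.07, 0.07, 0.09, 0.07],
        "exp": [-5.24, -5.04, -5.94, -2.38, -3.90, -4.52],
    }
)
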