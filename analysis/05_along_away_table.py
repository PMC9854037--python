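"""Reconstruct the along-away QA dose-rate tables from the TG-43 parameters.

Forward TG-43 reconstruction (at S_k = 1 U) on the published QA grid
(-10 <= z <= 10 cm along, 0 <= y <= 10 cm away) using the packaged reference
parameter sets; writes results/alongaway_ch*.csv.

Found: the reconstruction gives Ddot(y=1, z=0) = Lambda (1.115 / 1.116
cGy h^-1 U^-1) by construction, whereas the corresponding printed QA cell is
~3.75 — the printed tables carry a near-uniform factor of ~3.4 relative to a
TG-43 reconstruction at unit air-kerma strength, so only their internal shape
(not their scale) is comparable; isolated printed outliers are flagged by the
fixture loader.
"""

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from brachydose.engine import along_away_table
from brachydose.fixtures import load_fixtures, reference_parameters
from brachydose.tableio import write_table

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

Y = [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0]
Z = [-10, -8, -7, -6, -5, -4, -3, -2, -1.5, -1, -0.75, -0.5,
     0, 0.5, 0.75, 1, 1.5, 2, 3, 4, 5, 6, 7, 8, 10]

fx = load_fixtures()
for ch in ("1_2", "3"):
    tag = ch.replace("_", "")
    params = reference_parameters(ch, fx)
    tab = along_away_table(params, Y, Z)
    write_table(tab.to_dataframe(), OUT / f"alongaway_ch{tag}.csv", "matrix")
    ref_cell = tab.values[Z.index(0), Y.index(1.0)]
    printed = fx.along_away[ch]
    printed_cell = printed[printed.z_cm == 0]["1.0"].iloc[0]
    finite = np.isfinite(tab.values)
    print(f"channel {ch}: {finite.sum()} finite cells; "
          f"Ddot(1 cm, 0) = {ref_cell:.3f} cGy/h/U "
          f"(printed table cell: {printed_cell}, ratio {printed_cell / ref_cell:.2f})")
print(f"wrote QA tables under {OUT}")
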