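"""Run the analytic verification oracles and tabulate the errors.

Covers the elastic, wave, undrained and consolidation behaviour of the
engine against closed-form references; writes results/verification.csv.
"""

import time
from pathlib import Path

import pandas as pd

from osseowave import verify as vf

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
t0 = time.time()
osc = vf.two_body_oscillator()
rows.append(("two-body oscillator frequency", osc.rel_error, 0.01))
for mat in ("Cortical", "Cancellous"):
    rec = vf.modulus_recovery(mat)
    rows.append((f"uniaxial E recovery ({mat})", rec.E_rel_error, 0.03))
    rows.append((f"Poisson ratio recovery ({mat})", rec.nu_abs_error / rec.nu_input, 0.03))
ws = vf.wave_speed()
rows.append(("P-wave first arrival", ws.rel_error, 0.05))
ud = vf.undrained_response()
rows.append(("undrained pore-pressure response", ud.rel_error, 1e-4))
tz = vf.terzaghi_benchmark()
rows.append(("Terzaghi consolidation RMS/p0", tz.rms_rel, 0.05))
rows.append(("energy drift, 1e4 steps", vf.energy_drift(), 0.01))

df = pd.DataFrame(rows, columns=["check", "relative_error", "tolerance"])
df["pass"] = df.relative_error < df.tolerance
df.to_csv(OUT / "verification.csv", index=False)
print(df.to_string(index=False))
print(f"({time.time()-t0:.0f} s)")
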