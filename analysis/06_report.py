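"""Aggregate the study outputs into one summary table.

Reads the CSVs written by the earlier drivers (run them first) and prints
the peri-implant picture per loading mode, phase and intensity band:
which fraction of the healing zone sees osteogenic conditions, and where
the fluid pressure suffices for cell transport.
"""

from pathlib import Path

import pandas as pd

RES = Path(__file__).resolve().parents[1] / "results"

def load(name: str) -> pd.DataFrame | None:
    path = RES / name
    if not path.exists():
        print(f"[missing] {path} -- run the earlier analysis drivers first")
        return None
    return pd.read_csv(path)

conv = load("convergence.csv")
if conv is not None:
    s = conv.stiffness_kN_mm
    print("== discretization convergence ==")
    print(conv.to_string(index=False))
    print(f"spread: {(s.max()-s.min())/s.min()*100:.2f}%\n")

phys = load("physio_fractions.csv")
if phys is not None:
    print("== physiological loading: peri-implant fractions ==")
    print(phys.pivot_table(index=["phase", "target_N"], columns="label",
                           values="mean_fraction").round(3).to_string(), "\n")

eswt = load("eswt_fractions.csv")
if eswt is not None:
    print("== shock wave exposure: peri-implant fractions ==")
    bands = pd.cut(eswt.efd_mJ_mm2, [0, 0.05, 0.2, 0.5],
                   labels=["low", "medium", "high"])
    eswt = eswt.assign(band=bands)
    print(eswt.pivot_table(index=["phase", "band"], columns="label",
                           values="mean_fraction", observed=True).round(3).to_string())
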