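"""Adjuvant effects on the PDT precursor states: KI with MB, ascorbate
with IR700, plus the O2 dependence of the IR700 triplet decay.

Recovers the heavy-atom ISC enhancement slope from the KI titration, the
oxygen quenching slope from the O2 series, and the re-oxidation rate and
kRED-vs-[AA] slope from the ascorbate titration. Writes
results/adjuvant_fits.csv.
"""

from pathlib import Path

import pandas as pd

from trastkit.recovery import (aa_titration_roundtrip, ki_titration_recovery,
                               o2_series_recovery)
from trastkit.units import per_mM_us_to_per_M_s

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    rt = ki_titration_recovery(seed=1)
    kq = rt.result.estimate("kQISC1")
    rows.append({"series": "KI titration (pH 4)", "symbol": "kQISC1",
                 "estimate": kq, "unit": "mM^-1 us^-1",
                 "truth": rt.truth["kQISC1"]})
    print(f"KI titration: kQISC1 = {kq:.3g} /(mM us) "
          f"= {per_mM_us_to_per_M_s(kq):.3g} /(M s)")

    rt2, slope, intercept = o2_series_recovery(seed=1)
    rows.append({"series": "O2 series", "symbol": "kq_O2", "estimate": slope,
                 "unit": "mM^-1 us^-1", "truth": rt2.truth["kq_O2"]})
    print(f"O2 series: kT = {intercept:.3g} + {slope:.3g} x [O2] "
          f"(slope = {per_mM_us_to_per_M_s(slope):.3g} /(M s))")

    rt3 = aa_titration_roundtrip(seed=1)
    for sym in ("kOX", "kRED_AA"):
        rows.append({"series": "ascorbate titration", "symbol": sym,
                     "estimate": rt3.result.estimate(sym),
                     "unit": "us^-1" if sym == "kOX" else "mM^-1 us^-1",
                     "truth": rt3.truth[sym]})
    print(f"ascorbate titration: kOX = {rt3.result.estimate('kOX'):.4g} /us, "
          f"kRED slope = {rt3.result.estimate('kRED_AA'):.3g} /(mM us)")

    pd.DataFrame(rows).to_csv(OUT / "adjuvant_fits.csv", index=False)


if __name__ == "__main__":
    main()
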