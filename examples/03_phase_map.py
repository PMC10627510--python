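"""Where does autoinhibition-driven PA live in parameter space?

Scans PA fold change over the (K_A, [RAF]) plane for the CA model and
compares the numerical PA region with the analytic condition
RAF_rel < (1 + 3 K_A)(K_A - 1)/8: PA needs the autoinhibited state to
dominate (K_A > 1) and RAF scarce relative to the dimerization constant.
"""

import numpy as np

from rafpa import Variant, phase_scan
from rafpa.analysis import phase_scan_to_csv

K_As = np.logspace(-0.5, 2, 12)
rafs = np.logspace(-3, 0.5, 10)  # uM; K_dim = 0.1 uM -> RAF_rel = 10 * raf

scan = phase_scan(Variant.CA, K_As, rafs, K_dim=0.1, K_d=0.1)

print("PA fold change (rows: K_A, cols: [RAF] uM); '.' = no PA")
print("          " + " ".join(f"{r:7.3g}" for r in rafs))
for i, K_A in enumerate(K_As):
    cells = []
    for j in range(len(rafs)):
        fc = scan.fold_change[i, j]
        cells.append(f"{fc:7.2f}" if fc > 1 + 1e-6 else "      .")
    thr = (1 + 3 * K_A) * (K_A - 1) / 8 * 0.1  # analytic boundary, uM
    print(f"{K_A:9.3g} " + " ".join(cells) + f"   | boundary {max(thr, 0):.3g} uM")

phase_scan_to_csv(scan, "phase_scan.csv")
print("\nwrote phase_scan.csv (long format: K_A, raf_total_uM, fold change, range)")
# Fold change is largest at strong autoinhibition and scarce RAF, and the
# numerical PA region ends where [RAF] crosses the analytic boundary.
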