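"""Single-marker regression with Bonferroni and local-fdr control.

Scans every SNP of a mixed-LD replicate by per-SNP OLS, then applies the
two classical multiplicity treatments: the Bonferroni family-wise
threshold 0.05/p and Efron's local false discovery rate with an
empirically estimated null, flagging SNPs with fdr < 0.2.
"""

import numpy as np

from gwaselect import (
    bonferroni_select,
    local_fdr,
    make_setting,
    marker_scan,
    z_transform,
)
from gwaselect.evaluate import score_selection

G, y, causal = make_setting("mixed", p=3000, seed=5)
scan = marker_scan(G, y)

bonf = bonferroni_select(scan, family_alpha=0.05)
n_corr, n_fp = score_selection(bonf, causal)
print(f"Bonferroni (0.05/{G.p}): {len(bonf)} SNPs selected, "
      f"{n_corr} causal, {n_fp} false positives")

z = z_transform(scan.p_value, scan.slope)
res = local_fdr(z, threshold=0.2)
n_corr, n_fp = score_selection(res.flagged, causal)
print(
    f"local fdr < 0.2: {len(res.flagged)} SNPs flagged, {n_corr} causal, "
    f"{n_fp} false positives\n"
    f"empirical null: delta0={res.delta0:+.3f} sigma0={res.sigma0:.3f} "
    f"pi0={res.pi0:.3f}"
)
print(
    "\nThe empirical null absorbs mild miscalibration of the theoretical "
    "N(0,1); with 25 strong signals among 3000 SNPs both treatments should "
    "recover the causal set. Smallest p-values:",
    np.format_float_scientific(scan.p_value.min(), precision=2),
)
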