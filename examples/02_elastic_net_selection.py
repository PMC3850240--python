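"""Lasso vs elastic net selection on one high-LD replicate.

Fits the full coordinate-descent path at two penalty weights, tunes
lambda by 10-fold cross-validation with the conservative minMSE+1SE rule,
and scores the selected SNPs against the known causal set.  The lasso
keeps a handful of representatives of the correlated causal block; the
elastic net (alpha = 0.1) spreads weight over the whole block and
recovers all 25.
"""

from gwaselect import cv_path, fit_path, lambda_path, make_setting, select_variables
from gwaselect.evaluate import score_selection

G, y, causal = make_setting("high", p=2000, seed=11)

for alpha, label in ((1.0, "lasso"), (0.1, "elastic net a=0.1")):
    lam = lambda_path(G.values, y, alpha)
    fit = fit_path(G.values, y, alpha, lam)
    cv = cv_path(G.values, y, alpha, k=10, seed=42, lambda_seq=lam)
    for criterion in ("min", "1se"):
        sel = select_variables(fit, cv, criterion)
        n_corr, n_fp = score_selection(sel.selected, causal)
        mse = cv.mean_mse[cv.index_for(criterion)]
        print(
            f"{label:>18} @ {criterion:>3}: lambda*={sel.lambda_star:8.4f}  "
            f"selected={len(sel.selected):3d}  correct={n_corr:2d}/25  "
            f"false_pos={n_fp:3d}  cv_mse={mse:.3f}"
        )

print(
    "\ncorrect/false_pos count selections inside/outside the known causal set;"
    "\ncv_mse is the held-out squared error at the tuned lambda (trait units^2)."
)
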