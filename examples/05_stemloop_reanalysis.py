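"""Reanalysis of stem-loop reporter noise data.

Per-construct fluorescence means and CVs for two reporters are turned
into Fano factors; a straight line F = intercept + slope * mean is
fitted per reporter, and the same coefficients predict the hyperbolic
CV^2(mean) curve of the two-stage model.
"""

import numpy as np

from stochexpr import (
    fit_fano_regression,
    load_stemloop_table,
    noise_metrics,
    predict_noise_curves,
)

records = load_stemloop_table()
for reporter in ("ymNeonGreen", "yEGFP"):
    subset = [r for r in records if r.reporter == reporter and r.complete]
    print(f"\n{reporter}:")
    for rec in subset:
        fano, cv2, sd_cv2, sd_f = noise_metrics(rec)
        print(f"  {rec.construct:13s} mean {rec.mean:6.0f}  F {fano:6.2f} +- {sd_f:.2f}")
    fit = fit_fano_regression(subset)
    print(f"  OLS slope {fit.slope:.4f}, intercept {fit.intercept:.2f}")
    mu = np.array([200.0, 1000.0, 3000.0])
    fano_line, cv2_curve = predict_noise_curves(fit, mu)
    for m, f, c in zip(mu, fano_line, cv2_curve):
        print(f"  predicted at mean {m:5.0f}: F {f:6.2f}, CV^2 {c:.4f}")
# The positive slope means the Fano factor falls as hairpins lower the
# mean -- the same data that show CV^2 rising.  The two-stage model
# explains both trends with one line: noise tracks the mean, with no
# evidence of active noise control by the stem-loop.
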