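"""The evaluation statistics on a worked toy comparison.

NRMSE (normalized by the reference dynamic range, in %), SSIM, Pearson r
and the intraclass correlation coefficient ICC(2,1) — the agreement
statistics used to compare an accelerated reconstruction against its
full-length reference.
"""

import numpy as np

from cestmrf import evaluate_maps, nrmse, pearson_and_icc, ssim

rng = np.random.default_rng(0)
ref = np.clip(rng.normal(0.15, 0.05, size=(48, 48)), 0, None)
pred = ref + rng.normal(0, 0.01, size=ref.shape)       # a slightly noisy copy

print(f"NRMSE : {nrmse(pred, ref):.2f} %  (0% = identical maps)")
print(f"SSIM  : {ssim(pred, ref):.3f}    (1.0 = identical structure)")
(r, p), icc = pearson_and_icc(pred.ravel(), ref.ravel())
print(f"Pearson r = {r:.3f} (p = {p:.1e}), ICC(2,1) = {icc:.3f}")

report = evaluate_maps({"volume_fraction": pred}, {"volume_fraction": ref},
                       mask=np.ones(ref.shape, bool))
print("bundled report:", {k: round(v, 3)
                          for k, v in report.per_map["volume_fraction"].items()})
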