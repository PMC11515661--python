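"""Noise metrics for the mRNA inactivation loop (stem-loop kinetics).

An active mRNA reversibly folds into a translationally silent form.
The loop model's protein noise is compared against a classical baseline
whose mRNA decay rate is adjusted so both models share the same mRNA
and protein means.
"""

from stochexpr import LoopModel, loop_derived, loop_noise_metrics, noise_reduction_map

model = LoopModel(
    lambda_m=2.0, gamma_1m=1.0, gamma_2m=1.0, q12=3.0, q21=2.0, lambda_p=4.8, gamma_p=2.0
)
d = loop_derived(model)
m = loop_noise_metrics(model)

print(f"effective mRNA decay : {d.gamma_eff:.4g}")
print(f"protein mean         : {m.protein_mean:.4g}")
print(f"Fano (loop / base)   : {m.fano:.4g} / {m.fano_baseline:.4g}")
print(f"CV^2 (loop / base)   : {m.cv2:.4g} / {m.cv2_baseline:.4g}")
print(f"noise ratio          : {m.reduction_ratio:.4g}")
# ratio < 1: the loop filters mRNA fluctuations and lowers protein noise.

for scenario in ("unstable", "stable"):
    nm = noise_reduction_map(scenario=scenario)
    print(
        f"{scenario:9s} inactive mRNA: best reduction {nm.max_reduction_percent:.1f}% "
        f"at q21={nm.argmin_q21:.3g}, gamma_p={nm.argmin_gamma_p:.3g}"
    )
# A degradable inactive form buys a moderate (~16%) reduction at fast
# activation; a protected one buys ~64% in the slow-activation limit.
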