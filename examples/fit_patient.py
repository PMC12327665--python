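"""Personalize the PBPK model against synthetic gamma-camera data.

Generates organ time-activity curves with 1% multiplicative noise from a
known ground truth, perturbs the tumor receptor density and release rate,
and recovers them by weighted nonlinear least squares.
"""

from rptsim import fit, synthesize_tac, table2_patients

truth = table2_patients()["P1"]
data = synthesize_tac(truth, noise_cv=0.01, seed=11)

start = {"tumor.R0": truth.organ("tumor").R0 * 1.6,
         "tumor.lambda_release": truth.organ("tumor").lambda_release * 0.6}
result = fit(truth, data, ["tumor.R0", "tumor.lambda_release"],
             init=start, weighted=True)

print("converged:", result.converged)
for name, got in result.parameters.items():
    organ, attr = name.split(".")
    true_val = getattr(truth.organ(organ), attr)
    print(f"{name:22s} recovered {got:.4g}  (truth {true_val:.4g}, "
          f"error {abs(got - true_val) / true_val * 100:.1f}%)")
print({k: f"{v:.3g}" for k, v in result.metrics.items()})

# With 1% measurement noise both tumor parameters come back within a few
# percent; SSE/AIC/BIC quantify the fit the way model-selection tables do.
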