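"""Sweep several modes of interest and derive the scanner safety factor.

The overall eEMM is the maximum over the per-mode values; it combines
root-sum-square with power-monitoring (15%) and inter-subject (50%)
uncertainties into the safety factor applied to predicted pSAR10g.
The sample-size heuristic says how many modes a sweep should contain to
represent the B1+ error space of a coil.
"""

from sarbound import (SyntheticSpec, generate_fieldset, make_canonical_modes,
                      qmatrices_from_fieldset, required_mode_count,
                      safety_budget, sweep_modes)
from sarbound.synthetic import draw_truth_within_bounds

fs = generate_fieldset(SyntheticSpec(seed=1))
q = qmatrices_from_fieldset(fs).pruned(0.95)
cp, alt, zero, lin, rnd = make_canonical_modes(fs.n_channels)
truth, meas = draw_truth_within_bounds(fs, cp, seed=0)

res = sweep_modes(fs, meas, q, [cp, lin, zero, rnd], n=20_000, seed=0)
print(res.table().to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\noverall eEMM = {100 * res.overall_eemm:.1f} %  (max over modes)")

budget = safety_budget(e_pm=0.15, e_isv=0.50, e_emm=res.overall_eemm)
print(f"eSAR = sqrt(0.15^2 + 0.50^2 + eEMM^2) = {budget.e_sar:.4f}")
print(f"safety factor SF = 1 + eSAR = {budget.sf:.4f}")

# how many modes would a statistically representative sweep need?
# (mean/sd of NRMSE over random modes, 95% confidence, 5% margin)
n = required_mode_count(mu=54.5, sigma=8.4, z=1.96, e=0.05)
print(f"\nmodes needed for a representative sweep: {n}")
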