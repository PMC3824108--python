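"""Pan-balance diagnostic report for a single specimen.

Each balance is judged against the published univariate confidence range of
the balanced high-yielders (which fulcrums lean out of range), and the
whole ionome is judged by its Mahalanobis distance against the calibrated
critical distance (4.08).  Back-transformed concentrations sit in the
weighing pans so relative shortages and excesses can be read in mg/kg.
"""

import numpy as np

import panbalance as pb

basis = pb.mango_basis()
norms = pb.mango_norms()
ci = pb.mango_reference_ci()

# a specimen: at the reference medians, then pushed to relative P shortage
# and Mn excess (the two misbalances flagged in low-yield mango orchards)
z = norms.center.copy()
z[list(norms.balance_names).index("[P | S,N]")] += 3 * 0.118  # ~3 SD up: S,N >> P
z[list(norms.balance_names).index("[Mn | Cu,Zn]")] -= 3 * 0.452  # ~3 SD down: Mn excess
specimen = pb.ilr_inverse(z, basis)

report = pb.diagnose(specimen, norms, ci, basis)
print(f"global distance {report.global_distance:.2f} vs critical "
      f"{report.critical_distance:.2f} -> "
      f"{'balanced' if report.balanced else 'imbalanced'}")
for b in report.balances:
    flag = "" if b.verdict == "within" else f"  <-- {b.verdict}"
    print(f"{b.name:42s} {b.value:8.3f} in [{b.ref_lower:.3f}, {b.ref_upper:.3f}]{flag}")

pans = report.pan_concentrations.round(1)
print("\nweighing pans (mg/kg dry mass):")
print(pans[[c for c in pans.columns if c != "Fv"]].to_string())
# The balance verdicts localise the trouble (protein/energy and Mn vs Cu,Zn
# contrasts); the pans show which concentrations to move, relative to the
# reference, to restore them.
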