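"""Compile the packaged foliar SBP into an orthonormal balance basis and
express a tissue sample as ilr balances.

The SBP splits the 12-part foliar composition (11 nutrients + filling
value) into nested binary contrasts; each row becomes one interpretable
balance whose sign tells which side of the contrast carries more mass.
"""

import numpy as np

import panbalance as pb

basis = pb.mango_basis()
print(f"{basis.n_balances} balances over parts: {', '.join(basis.part_labels)}")
print("orthonormality error:", np.abs(basis.psi @ basis.psi.T - np.eye(11)).max())

# a single specimen: foliar concentrations in mg/kg dry mass
nutrients = {
    "S": 1400.0, "N": 12100.0, "P": 1100.0, "K": 7900.0, "Ca": 12500.0,
    "Mg": 1600.0, "B": 85.0, "Cu": 280.0, "Zn": 18.0, "Mn": 130.0, "Fe": 95.0,
}
comp = pb.add_filling_value(
    np.array([[nutrients[p] for p in basis.part_labels[:-1]]]),
    part_labels=basis.part_labels[:-1],
)
z = pb.ilr(comp, basis)
for name, value in zip(z.balance_names, z.values[0]):
    lean = pb.balance_sign_interpretation(value, name)
    print(f"{name:42s} {value:8.3f}  ({lean})")
# A negative balance leans toward the parts left of the bar: the first
# balance is strongly negative because C/H/O dry mass (Fv) dwarfs nutrients.
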