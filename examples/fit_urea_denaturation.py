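"""Globally fit replicate urea-denaturation curves and compare two conditions.

Three synthetic replicates per condition share (dG_H2O, m) but carry their own
linear baselines; the global fit recovers the shared thermodynamics and the
difference ddG_H2O carries a quadrature-propagated error.
"""

from lumistab.denaturation import delta_delta_g, fit_two_state_global
from lumistab.simulate import DenatTruth, gen_denaturation_replicates

# ground truths emulating a Ca2+-depleted wild-type pair
dtt = fit_two_state_global(
    gen_denaturation_replicates(DenatTruth(dg=4.82, m=1.69), seed=1)
)
gsno = fit_two_state_global(
    gen_denaturation_replicates(DenatTruth(dg=5.98, m=1.92), seed=2,
                                condition="nitrosylating")
)
d = delta_delta_g(dtt, gsno)

for name, f in (("DTT", dtt), ("GSNO", gsno)):
    print(f"{name:4s} dG_H2O = {f.dg_h2o:.2f} +/- {f.se_dg:.2f} kcal/mol | "
          f"Cmid = {f.cmid:.2f} M | m = {f.m_value:.2f} +/- {f.se_m:.2f} kcal/mol/M")
print(f"ddG_H2O = {d.value:+.2f} +/- {d.error:.2f} kcal/mol")
print("A positive ddG_H2O means the modified condition is thermodynamically")
print("more stable in water; Cmid = dG/m is the urea midpoint in M.")
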