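"""Relative transcription by the double-delta Cq method.

qPCR quantification cycles for a target gene and the ACT1 reference are
turned into fold changes relative to a calibrator sample (level = 1).  We
plant fold changes (including the strong acid induction of BUD21-like
magnitude, 4.8x), add 0.1-cycle read noise, and recover them.
"""

from acidtol.quant import relative_expression
from acidtol.synthdata import simulate_expression

planted = {
    "control_unstressed": {"BUD21": 1.0},
    "control_acid": {"BUD21": 4.8},
    "overexp_unstressed": {"BUD21": 1.4},
    "overexp_acid": {"BUD21": 6.2},
}
cq, truth = simulate_expression(
    planted, reference_gene="ACT1", calibrator_sample="control_unstressed",
    noise_sd=0.1, n_replicates=3, seed=21,
)
levels = relative_expression(cq, "BUD21", "ACT1", "control_unstressed")

print("sample                 level   planted")
for lv in levels:
    print(f"{lv.sample:22s} {lv.level:5.2f}   "
          f"{truth.expression_folds[lv.sample]['BUD21']:.1f}")
print("\n(levels are 2^-ΔΔCq against ACT1; the calibrator is exactly 1)")
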