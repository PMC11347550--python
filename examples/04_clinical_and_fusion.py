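"""The clinical Cox score and bivariate fusion, including the published formulas.

The clinical score is the linear predictor of a seven-covariate Cox model; the
multimodal score is beta_rad * radiological + beta_clin * clinical with the
bivariate coefficients fitted on a training split (here: the published ones).
"""

from ctprog import (PUBLISHED_CLINICAL_COEFFS, PUBLISHED_FUSION_COEFFS,
                    clinical_score, fuse, published_clinical_fit,
                    published_fusion_fit)
from ctprog.phantom import ClinicalRecord
from ctprog.survnet import RiskScore

print("published clinical coefficients:")
for name, beta in PUBLISHED_CLINICAL_COEFFS.items():
    print(f"  {name:16s} {beta:+.4f}")

patient = ClinicalRecord(patient_id="demo", differentiation=1, nash_nafld=1,
                         surgery=1, pvtt=0, ebrt=0, tae_tace=1, rfa_mwa=0,
                         os_days=400.0, event=1)
cln = clinical_score(patient, published_clinical_fit())
print(f"\nclinical score for (diff=1, NASH=1, surgery=1, TAE/TACE=1): {cln.score:.4f}")
print("  = 0.3747 + 0.1593 - 0.1801 + 0.6482")

rad = RiskScore(patient_id="demo", score=0.21, variant="rad_d")
fused = fuse(rad, cln, published_fusion_fit())
print(f"\nfusion coefficients: {PUBLISHED_FUSION_COEFFS}")
print(f"fused score for radiological 0.21: {fused.score:.4f} (variant {fused.variant})")
print("\nHigher scores mean higher hazard; the fused score is the input to "
      "median-cutoff risk stratification and the nomogram.")
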