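"""Score one febrile adult with MEWS, qSOFA and UVA.

A 40-year-old inpatient: febrile, tachycardic, tachypnoeic, borderline
hypotensive, mildly hypoxic, fully conscious, living with HIV.
"""

from fevscore import (
    ConsciousnessAssessment,
    HIVStatus,
    MotorCategory,
    VitalSigns,
    gcs_to_avpu,
    modified_gcs,
    score_mews,
    score_qsofa,
    score_uva,
)

vitals = VitalSigns(temperature=38.9, heart_rate=124, resp_rate=28,
                    sbp=92, spo2=91)
consciousness = ConsciousnessAssessment(
    eye_response=4, verbal_response=5,
    motor_category=MotorCategory.SPONTANEOUS_OR_VERBAL,
)

gcs = modified_gcs(consciousness)
avpu = gcs_to_avpu(consciousness)
print(f"modified GCS: {gcs} (AVPU {avpu.value})")
print(f"MEWS : {score_mews(vitals, avpu)}  (0-14; >=3 flags risk)")
print(f"qSOFA: {score_qsofa(vitals, gcs)}  (0-3; >=2 suggests sepsis risk)")
print(f"UVA  : {score_uva(vitals, gcs, HIVStatus.POSITIVE)}  "
      "(0-13; HIV infection and hypoxia each add 2 points)")
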