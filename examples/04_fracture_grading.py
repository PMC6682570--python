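"""Grade vertebral deformities and ascertain incident fractures.

Height measurements give a semiquantitative grade 0-3; comparing baseline
and follow-up grades per vertebra (with consolidation and activity flags)
yields the patient's incident-fracture status.
"""

from oppqct import (
    VertebraFollowUp,
    VertebralHeights,
    genant_grade,
    incident_fracture,
    patient_incident_status,
)

for heights in [
    VertebralHeights("L1", anterior=98, middle=97, posterior=99, reference_height=100),
    VertebralHeights("L2", anterior=78, middle=92, posterior=95, reference_height=100),
    VertebralHeights("L3", anterior=55, middle=70, posterior=90, reference_height=100),
]:
    a = genant_grade(heights)
    print(f"{a.level}: height reduction {a.height_reduction:4.0%} -> grade {a.grade}")

followup = [
    VertebraFollowUp("L1", baseline_grade=0, followup_grade=0),
    VertebraFollowUp("L2", baseline_grade=0, followup_grade=1),  # new deformity
    VertebraFollowUp("L3", baseline_grade=2, followup_grade=3,
                     consolidated_at_baseline=True),              # progression after healing
    VertebraFollowUp("L4", baseline_grade=1, followup_grade=3,
                     consolidated_at_baseline=False, active_signs=True),  # still active
]
for v in followup:
    print(f"{v.level}: {v.baseline_grade} -> {v.followup_grade}, incident = {incident_fracture(v)}")

status, levels = patient_incident_status(followup)
print(f"patient incident-fracture status: {status}, contributing levels: {levels}")

# L2 and L3 count as incident fractures; L4 does not, because a vertebra with
# active fracture signs at baseline (marrow edema / callus) is excluded from
# incident ascertainment entirely.
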