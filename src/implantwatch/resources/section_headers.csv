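surface,canonical
past medical history,past_medical_history
pmh,past_medical_history
medical history,past_medical_history
past surgical history,past_medical_history
patient history,past_medical_history
history,past_medical_history
history of present illness,history_of_present_illness
hpi,history_of_present_illness
present illness,history_of_present_illness
chief complaint,history_of_present_illness
assessment and plan,assessment_plan
assessment & plan,assessment_plan
assessment/plan,assessment_plan
assessment,assessment_plan
plan,assessment_plan
impression,assessment_plan
impression and plan,assessment_plan
operative findings,operative_findings
findings,operative_findings
procedure,operative_findings
description of procedure,operative_findings
operation performed,operative_findings
implants,operative_findings
components,operative_findings
imaging,imaging
radiology,imaging
x-ray,imaging
radiographs,imaging
imaging studies,imaging
medications,medications
current medications,medications
meds,medications
allergies,medications
physical exam,body
physical examination,body
review of systems,body
social history,body
family history,past_medical_history
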