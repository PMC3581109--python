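label
OBJECTIVE
OBJECTIVES
AIM
AIMS
PURPOSE
BACKGROUND
INTRODUCTION
METHODS
METHOD
MATERIALS AND METHODS
PATIENTS AND METHODS
SUBJECTS AND METHODS
DESIGN
SETTING
PATIENTS
PARTICIPANTS
SUBJECTS
INTERVENTIONS
MEASUREMENTS
RESULTS
FINDINGS
CONCLUSION
CONCLUSIONS
INTERPRETATION
DISCUSSION
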