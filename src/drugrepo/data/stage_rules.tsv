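pattern	stage_class
(withdraw|suspend|discontinu|ter?minat).*phase	withdrawn_or_suspended_clinical
phase.*(withdraw|suspend|discontinu|ter?minat)	withdrawn_or_suspended_clinical
withdraw	withdrawn_or_suspended_clinical
suspend	withdrawn_or_suspended_clinical
discontinu	withdrawn_or_suspended_clinical
ter?minat	withdrawn_or_suspended_clinical
approv	approved
pre.?clinical	preclinical
phase	clinical
clinical	clinical
launch	approved
market	approved
registered	approved
research	research
experiment	research
discovery	research
investigative	research
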