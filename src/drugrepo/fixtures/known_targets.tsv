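target_name	note
Alpha-2A adrenergic receptor	known anti-diabetic drug target
Insulin	known anti-diabetic drug target
Lysophosphatidic acid transferase	known anti-diabetic drug target
Glucokinase	known anti-diabetic drug target
PPAR gamma	known anti-diabetic drug target
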