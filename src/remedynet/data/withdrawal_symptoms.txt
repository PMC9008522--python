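# Default withdrawal-symptom effect list (16 entries, one per line).
# Edit freely: the rank stage reads whichever file the config points at;
# entries must match canonical EFFECT names in the network.
body aches
muscle aches
diarrhea
nausea
vomiting
sweating
insomnia
anxiety
dysphoria
depression
restless leg syndrome
fever
chills
yawning
runny nose
watery eyes
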