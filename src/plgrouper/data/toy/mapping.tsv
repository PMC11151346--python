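icd_code	concept_id	is_primary
R91.1	27925004	1
C34.90	363358000	1
C44.92	254651007	1
R60.9	267038008	1
I48.91	49436004	1
J45.909	195967001	1
J18.9	233604007	1
Z79.01	182929008	1
L98.9	95320005	1
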