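child_id	parent_id	child_fsn
404684003		Clinical finding
55342001	404684003	Neoplastic disease
363346000	55342001	Malignant neoplastic disease
95320005	404684003	Disorder of skin
372130007	363346000	Malignant neoplasm of skin
372130007	95320005	Malignant neoplasm of skin
254651007	372130007	Squamous cell carcinoma of skin
50043002	404684003	Disorder of respiratory system
27925004	50043002	Nodule of lung
363358000	363346000	Malignant tumor of lung
363358000	50043002	Malignant tumor of lung
195967001	50043002	Asthma
49601007	404684003	Disorder of cardiovascular system
49436004	49601007	Atrial fibrillation
40733004	404684003	Infectious disease
233604007	40733004	Pneumonia
385093006	233604007	Community acquired pneumonia
267038008	404684003	Edema
182929008	404684003	Drug therapy finding
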