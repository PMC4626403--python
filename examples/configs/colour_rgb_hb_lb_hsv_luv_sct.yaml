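# colour-model combination study: rgb & hbb & lbb & hsv & luv & sct with the intensity bank
colour_models: [rgb, hbb, lbb, hsv, luv, sct]
descriptors: [intensity]
threshold: null
classifier: bagging
n_members: 50
folds: 10
seed: 0
paper_mode: false
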