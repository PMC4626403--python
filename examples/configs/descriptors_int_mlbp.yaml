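# descriptor combination study: intensity & mlbp over six colour models
colour_models: [cmyk, hbb, lbb, hsv, luv, sct]
descriptors: [intensity, mlbp]
threshold: null
classifier: bagging
n_members: 50
folds: 10
seed: 0
paper_mode: false
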