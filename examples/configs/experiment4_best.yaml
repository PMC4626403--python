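# best configuration: six colour models, Intensity & M-LBP & Gabor & S-Textons, correlation filter at |r| >= 0.97, 50-tree Bagging
colour_models: [cmyk, hbb, lbb, hsv, luv, sct]
descriptors: [intensity, mlbp, gabor, stextons]
threshold: 0.97
classifier: bagging
n_members: 50
folds: 10
seed: 0
paper_mode: false
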