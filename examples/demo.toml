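# Full-pipeline demo: simulate a survey-like field, compute indices,
# interpolate/classify rasters with area shares, and run the multivariate stage.
seed = 7

[simulate]
preset = "paper_like"

[grid]
cell_size = 250.0

[stages]
indices = true
spatial = true
multivariate = true
figures = false

[output]
dir = "soilrisk_out"
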