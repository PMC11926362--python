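# Full-pipeline options (RunConfig fields); defaults shown.
counts: counts.csv
out_dir: results
marker_convention: inclusive   # or: exclusive
sd_ddof: 1                     # sample SD in the mean+SD threshold
efficiency_weighted: false     # unweighted hop-count efficiency
make_figures: true
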