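# Bundled demo: full pipeline on a simulated pleiotropy dataset.
# Run with:  pleiogene run examples/demo_config.yaml
seed: 17
outdir: runs/demo
simulate:
  demo: true
assign:
  mode: plain
  pad_kb: 0
vegas:
  stages: [1000, 10000, 100000]
setscreen:
  rho: r2
crossmeta:
  alpha_nominal: 0.05
  n_phenotypes: 2
diffexpr:
  enabled: true
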