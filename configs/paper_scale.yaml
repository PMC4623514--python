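# Full-scale quench protocol (hours of CPU): 512^2 lattice, 10 independent
# runs, deep quench at T = 1 with snapshots at 100, 200, 500 MCS.
# Usage: lrising quench --n 2 --config configs/paper_scale.yaml
size: 512
temp: 1.0
mcs: 500
runs: 10
times: "100 200 500"
out: lrising_paper_scale
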