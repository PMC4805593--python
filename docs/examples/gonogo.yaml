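# Go/no-go simulation at a 2:1 direct:indirect drive ratio.
# Run: bgcompete --config docs/examples/gonogo.yaml --out-dir out simulate
network:
  tau: 100.0
  w_self: 0.8
  w_inh: 0.5
  noise_sd: 0.04
input:
  I_d: 0.667
  I_i: 0.333
decision:
  threshold: 2.5
  deadline: 1200.0
seed: 7
log_level: info
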