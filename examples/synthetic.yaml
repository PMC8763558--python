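# Full pipeline on the default synthetic diagnosis table.
# Run: swarmfs run --config examples/synthetic.yaml --out run_output
seed: 7
dataset:
  synthetic:
    n: 300
    D: 13
    m_informative: 4
    effect: 2.0
    seed: 7
sfo:
  num_sardines: 60
  percent: 0.3
  max_iter: 500
fs:
  omega: 0.99
rso:
  pop_size: 4
  max_iter: 3
bigru:
  space:
    hidden_log2: [2, 4]
    lr_log10: [-2.5, -1]
    epochs: [10, 60]
cv:
  outer_folds: 5
  inner_folds: 3
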