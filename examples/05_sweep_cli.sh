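#!/bin/sh
# Reproduce a reduced-scale valley-depth sweep from the shell.
#
# The sweep block expands to a Cartesian grid of conditions (here 2 tau
# values x 2 valley depths r1); each condition writes per-replicate results,
# a mutant-birth table and a summary row, plus a manifest with the child
# seed schedule for exact reproducibility.
set -e
cat > /tmp/valley_sweep.yaml <<'YAML'
N: 100
V: 1.0e-4
sweep:
  tau: [1, 100]
  r1: [0.95, 0.99]
YAML
valleycross sweep /tmp/valley_sweep.yaml --n-reps 100 --seed 1 --out-dir /tmp/valley_sweep
valleycross report /tmp/valley_sweep --no-plot
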