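#!/usr/bin/env bash
# Simulate a panel, fit the model, and score new data — all from the shell.
set -euo pipefail

workdir=$(mktemp -d)

poispair simulate --m 50 --t 10 --seed 7 \
    --out "$workdir/panel.csv" --truth-out "$workdir/truth.json"

poispair fit "$workdir/panel.csv" --tol 1e-4 --max-iter 300 \
    --out "$workdir/fit.json" --pred-out "$workdir/predictions.csv"

poispair predict "$workdir/fit.json" "$workdir/panel.csv" \
    --out "$workdir/scored.csv"

echo "--- fitted parameters"
python -c "import json;d=json.load(open('$workdir/fit.json'));print({k:d[k] for k in ('gamma','sigma2','tau2','rho','converged')})"
echo "artifacts in $workdir"
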