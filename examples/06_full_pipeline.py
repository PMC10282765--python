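"""Run every stage end to end on generated inputs.

Equivalent to ``n4 run --demo --seed 1 --out demo_out`` on the command
line.  All inputs are generated under the output directory; the report
is both returned and written as JSON.
"""

import json

from n4.pipeline import PipelineConfig, run

report = run(PipelineConfig(seed=1, outdir="demo_out"), demo=True)
print(json.dumps(report, indent=1, default=str))

# Stage order: DEG filtering + progressive elimination -> soft-threshold
# screening + TOM -> module detection and trait statistics -> MCC hub
# ranking on the top module's interaction network -> G4 scanning ->
# Venn/enrichment of shared genes against G4-containing genes.  The same
# seed always reproduces the same report.
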