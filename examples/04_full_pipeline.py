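"""Run the whole chain: simulate -> quantify -> fit -> model.

Simulates mock and UV-like conditions under the study design (mock:
f = 0.959, half-lives 3.1/7.2 min; UV: f = 0.653, half-lives 17.1/7.5
min, initiation reduced ~2.2-fold), then re-infers decay constants,
synthesis-rate fold changes and termination fractions from the
simulated data alone.  Artifacts and provenance sidecars are written
under ./pipeline_demo/.
"""

import logging

from ribochase.pipeline import PipelineConfig, run_pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

report = run_pipeline(PipelineConfig(seed=3, out_dir="pipeline_demo", n_boot=200))

print()
print(report.formatted())
print()
print(f"recovered termination: mock {report.mock.termination.percent:.1f}% "
      f"(truth 95.9%), UV {report.uv.termination.percent:.1f}% (truth 65.3%)")

# Each CSV/TSV under pipeline_demo/ has a .provenance.json sidecar with
# the stage, parameters, seed and input hashes that produced it.
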