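"""Generate the synthetic experiment: calcium traces with ground truth,
two-channel wounding fields, and a qPCR Ct table.

Writes results/data/ (traces.csv, truth_rois.csv, qpcr_ct.csv, images/,
truth_fields.csv, config.yaml, manifest.json). The design mirrors the
targeted study: 6 scaffolds per condition x 30 ROIs, 300 s window sampled
every 1.73 s.
"""
import sys

from osteoflow.config import SynthConfig
from osteoflow.pipeline import simulate_to_dir

if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    cfg = SynthConfig(seed=seed)
    manifest = simulate_to_dir(cfg, "results/data", images=True)
    print(f"simulated experiment with seed {manifest['seed']}")
    print(f"wrote {len(manifest['files'])} fixture files under results/data/")
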