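"""End-to-end comparative study of two synthetic paralogs x three replicates.

Runs the whole pipeline — metrics, cross-replicate verdicts, Frechet
matrices, time lags, clustering/medoids/projection, contact catalogues and
the run manifest — and lists the report bundle it writes.
"""

import dataclasses
import json
from pathlib import Path

from pincermd import (ClusterConfig, PincerSpec, ProteinInput, StudyConfig,
                      domain_map_for, generate_replicates, run_study)


def protein(name, sigma, seeds):
    spec = PincerSpec(n_domains=4, residues_per_domain=8,
                      jaw_pair=("PAZ", "L2"), amplitude=1.0, period=60,
                      fluctuation_sigma=sigma, n_frames=120)
    return ProteinInput(
        name=name,
        replicates=generate_replicates(spec, len(seeds), seeds),
        domain_map=dataclasses.replace(domain_map_for(spec), protein=name))


config = StudyConfig(
    proteins=[protein("quiet", 0.2, [1, 2, 3]),
              protein("mobile", 1.0, [4, 5, 6])],
    out_dir=Path("example_out") / "study",
    seed=0, cluster=ClusterConfig(k_range=(2, 4), seed=0),
    jaw_pair=("PAZ", "L2"), sasa_max_frames=6)

result = run_study(config)
print(f"stages completed: {result['stages']}")

verdicts = json.loads((Path(config.out_dir) / "verdicts_rmsd.json").read_text())
whole = [v for v in verdicts if v["selection"] == "whole"][0]
print(f"whole-structure RMSD comparison: {whole['outcome']} "
      f"(D per replicate: {[round(r['D'], 3) for r in whole['replicates']]})")
print("the 5x noise contrast between the paralogs is what the verdict flags")

for path in sorted(Path(config.out_dir).iterdir()):
    print(" ", path.name)
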