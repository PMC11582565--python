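"""Simulate the synthetic recording campaigns.

Generates the ATP/AMP design (6 concentration pairs) and the ADP design
(7 concentrations), 3 replicates each, 2000 ms per trace, with sporadic
open-pore and shallow artifacts injected, and writes the traces plus a
conditions manifest under results/simulated/.
"""

import json
from pathlib import Path

from nanoak.io import write_trace
from nanoak.reference import REFERENCE_RATES
from nanoak.trace_simulator import (
    ArtifactSpec,
    default_adp_design,
    default_atp_amp_design,
    simulate_experiment,
)

SEED = 2024
OUT = Path("results/simulated")


def main() -> None:
    artifacts = ArtifactSpec(n_open_pore=1, n_shallow=1, duration_ms=80.0)
    manifest = []
    for kind, maker, variant in (
        ("atp_amp", default_atp_amp_design, "V3"),
        ("adp", default_adp_design, "ADP"),
    ):
        design = maker(n_replicates=3, duration_ms=2000.0, artifacts=artifacts)
        traces = simulate_experiment(REFERENCE_RATES, variant, design, seed=SEED)
        d = OUT / kind
        d.mkdir(parents=True, exist_ok=True)
        for i, tr in enumerate(traces):
            write_trace(tr, d / f"trace_{i:03d}.tsv")
            manifest.append(
                {"file": f"{kind}/trace_{i:03d}.tsv", "label": tr.label,
                 "conc_mM": tr.conc.to_dict(), "duration_ms": tr.duration_ms}
            )
        print(f"{kind}: wrote {len(traces)} traces "
              f"({len(design.conditions)} conditions x 3 replicates)")
    (OUT / "manifest.json").write_text(json.dumps({"seed": SEED, "traces": manifest}, indent=1))
    print(f"manifest: {OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
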