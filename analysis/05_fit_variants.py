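"""Maximum-likelihood fit and endosteric model-variant comparison.

Loads the picked fit segments (one per condition, <= 1000 ms), derives rough
per-parameter bounds from event-level dwell statistics, fits V1/V2/V3 by
multistart bounded ML, and tabulates maximal log-likelihoods.  Writes
results/variant_comparison.json.  A few minutes of CPU at these reduced
settings.
"""

import json
from pathlib import Path

from nanoak.inference import FitConfig, compare_variants, derive_bound_overrides
from nanoak.io import read_trace

SEED = 2027
IN = Path("results/segments")


def main() -> None:
    traces = [read_trace(f) for f in sorted(IN.glob("fit_*.tsv"))]
    print(f"fitting {len(traces)} segments "
          f"({sum(t.duration_ms for t in traces)/1000:.1f} s of data)")
    overrides = derive_bound_overrides(traces)
    cfg = FitConfig(seed=SEED, n_starts=2, max_iter=100, fit_emissions=False,
                    bound_overrides=overrides)
    comp = compare_variants(traces, ("V1", "V2", "V3"), cfg)
    print("maximal log-likelihoods:",
          {k: round(v.loglik, 1) for k, v in comp.results.items()})
    print("best variant:", comp.best_variant)
    Path("results").mkdir(exist_ok=True)
    Path("results/variant_comparison.json").write_text(
        json.dumps(comp.to_dict(), indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
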