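"""Screen the simulated recordings for usable segments.

Applies the sliding-window amplitude filters (exclude open-pore windows below
-350 pA and shallow windows at/above -160 pA), then draws one random segment
per condition truncated to at most 1000 ms — the data layout used for
maximum-likelihood fitting.  Writes a per-trace segment table and the picked
fit segments under results/segments/.
"""

import json
from pathlib import Path

import pandas as pd

from nanoak.event_analysis import pick_fit_segments, select_segments
from nanoak.hmm_core import CurrentTrace
from nanoak.io import read_trace, write_trace

SEED = 2025
IN = Path("results/simulated/atp_amp")
OUT = Path("results/segments")


def main() -> None:
    rows = []
    by_cond: dict[str, list] = {}
    conc_of = {}
    for f in sorted(IN.glob("trace_*.tsv")):
        tr = read_trace(f)
        segs = select_segments(tr)
        cond = tr.label.split("_rep")[0]
        by_cond.setdefault(cond, []).extend(segs)
        conc_of[cond] = tr.conc
        for s in segs:
            rows.append({"file": f.name, "condition": cond, "start_ms": s.start * s.dt_ms,
                         "duration_ms": s.duration_ms})
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "segments.tsv", sep="\t", index=False)
    print(f"{len(table)} usable segments across {len(by_cond)} conditions "
          f"(total {table.duration_ms.sum()/1000:.1f} s)")

    # restrict candidates to segments at least as long as the shortest series
    # of the recording campaign (500 ms), falling back to all if none qualify
    candidates = {
        cond: ([s for s in segs if s.duration_ms >= 500.0] or segs)
        for cond, segs in by_cond.items()
    }
    picked = pick_fit_segments(candidates, max_len_ms=1000.0, seed=SEED)
    for cond, seg in picked.items():
        write_trace(CurrentTrace(seg.samples, seg.dt_ms, conc_of[cond], cond),
                    OUT / f"fit_{cond}.tsv")
    meta = {c: round(s.duration_ms, 1) for c, s in picked.items()}
    (OUT / "picked.json").write_text(json.dumps({"seed": SEED, "picked_ms": meta}, indent=1))
    print(f"picked one segment per condition, truncated to {min(meta.values())} ms")


if __name__ == "__main__":
    main()
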