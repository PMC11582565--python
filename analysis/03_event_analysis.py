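"""Event-level analysis of the picked fit segments.

Idealizes each segment into M/M1/M2/M3 level events, fits exponential dwell
distributions per level, counts ordered transitions among M, M2, M3, and
computes all-point-histogram occurrence percentages.  Writes TSV tables under
results/events/.
"""

from pathlib import Path

import pandas as pd

from nanoak.event_analysis import (
    all_point_histogram,
    count_transitions,
    dwell_exponential_fit,
    events_to_frame,
    fit_gaussian_peaks,
    idealize,
    occurrence_percent,
)
from nanoak.io import read_trace
from nanoak.reference import DEFAULT_GROUP_MEANS

IN = Path("results/segments")
OUT = Path("results/events")
LEVELS = {k: v for k, v in DEFAULT_GROUP_MEANS.items() if k != "M0"}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    all_events, dwell_rows, trans_rows, occ_rows = [], [], [], []
    for f in sorted(IN.glob("fit_*.tsv")):
        tr = read_trace(f)
        events = idealize(tr.samples, LEVELS, dt_ms=tr.dt_ms, min_dwell_ms=1.0, smooth_ms=1.0)
        df = events_to_frame(events)
        df.insert(0, "condition", tr.label)
        all_events.append(df)

        for level, grp in df.groupby("level"):
            if len(grp) >= 10:
                stats = dwell_exponential_fit(grp["dwell_ms"], mode="direct", level=level)
                dwell_rows.append({"condition": tr.label, "level": level,
                                   "n": stats.n_dwells, "tau_ms": stats.tau_ms,
                                   "rate_per_s": stats.rate_per_s})
        t = count_transitions(events)
        t.insert(0, "condition", tr.label)
        trans_rows.append(t)

        hist = all_point_histogram(tr.samples)
        peaks = fit_gaussian_peaks(hist, 2, initial_means=[-221.0, -199.3])
        pct = occurrence_percent(peaks)
        occ_rows.append({"condition": tr.label,
                         "deep_peak_pA": peaks[0].mean, "deep_pct": pct[0],
                         "shallow_peak_pA": peaks[1].mean, "shallow_pct": pct[1]})

    pd.concat(all_events).to_csv(OUT / "events.tsv", sep="\t", index=False)
    pd.DataFrame(dwell_rows).to_csv(OUT / "dwell_stats.tsv", sep="\t", index=False)
    pd.concat(trans_rows).to_csv(OUT / "transitions.tsv", sep="\t", index=False)
    pd.DataFrame(occ_rows).to_csv(OUT / "occurrence.tsv", sep="\t", index=False)
    n_ev = sum(len(d) for d in all_events)
    print(f"idealized {n_ev} events across {len(all_events)} segments")
    print(pd.DataFrame(occ_rows).to_string(index=False))


if __name__ == "__main__":
    main()
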