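#!/usr/bin/env python
"""Chromothripsis calls and double-minute candidates for the patient.

Reads the second recurrence's copy-number segments and breakpoint junctions
(01) and runs the detector: oscillating copy states, high-support
intra-chromosomal breaks and >= 20-copy amplification gate each chromosome;
supported inter-chromosomal links merge chromosomes into one event; high-copy
segments stitched by supported breakpoints become double-minute candidates.

Writes results/chromothripsis_calls.json.
"""

import json
from pathlib import Path

from longevol.chromothripsis import call_chromothripsis
from longevol.io_formats import read_breakpoints, read_segments, write_report

ROOT = Path(__file__).resolve().parents[1]
CONFIG = ROOT / "scratch" / "data" / "patient" / "config.json"
RESULTS = ROOT / "results"


class _Calls:
    def __init__(self, calls):
        self.calls = calls

    def to_jsonable(self):
        return [c.to_jsonable() for c in self.calls]


def main() -> None:
    sv = json.loads(CONFIG.read_text())["sv"]
    segs = read_segments(sv["seg"])
    bps = read_breakpoints(sv["bedpe"], sv["sample_id"])
    calls = call_chromothripsis(segs, bps)
    RESULTS.mkdir(exist_ok=True)
    write_report(_Calls(calls), RESULTS / "chromothripsis_calls")
    for c in calls:
        print(f"{c.event_type} chromothripsis on {sorted(c.chroms)} "
              f"({c.n_inter_links} inter-chromosomal links)")
        for f in c.features.values():
            print(f"  {f.chrom}: max CN {f.max_cn:.0f}, {f.n_switches} switches, "
                  f"{f.n_intra_supported} supported intra breaks")
        for dm in c.dm_candidates:
            print(f"  DM candidate spanning {sorted(dm.chroms)} "
                  f"({len(dm.segments)} segments, "
                  f"{len(dm.linking_breakpoints)} linking breakpoints)")


if __name__ == "__main__":
    main()
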