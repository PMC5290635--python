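#!/usr/bin/env python
"""Generate the showcase serial-tumor dataset.

Simulates three serial exomes of one glioblastoma patient (primary, first
recurrence, second recurrence) with four planted clones — a preserved founder,
a clone lost under targeted therapy (carrying EGFR A289V), a clone emerging at
the first recurrence, and a hypermutant C>T-dominant clone emerging at the
second recurrence (carrying MSH6 T767I) — plus the second recurrence's
chromothriptic chr7/chr1 copy-number and breakpoint profile.

Writes the VCF/SEG/coverage/meta files under scratch/data/patient/ and the
run configuration under scratch/data/patient/config.json.
"""

import json
from pathlib import Path

from longevol.io_formats import Breakpoint, write_breakpoints, write_segments
from longevol.synthetic_data import (
    showcase_patient_clones,
    simulate_chromothripsis_chrom,
    simulate_patient,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "data" / "patient"
SEED = 17


def main() -> None:
    pat = simulate_patient(showcase_patient_clones(), seed=SEED)
    cfg = pat.write(OUT)
    cfg["seed"] = SEED
    for e in cfg["timepoints"]:
        e["purity"] = 0.5
        e["subtype"] = "primary_gbm"

    # Second recurrence SV profile: chromothripsis on chr7 (EGFR locus) and
    # chr1 (MDM4 locus), joined by supported inter-chromosomal breakpoints.
    sid = pat.metas[-1].sample_id
    segs7, bps7, _ = simulate_chromothripsis_chrom("amplifying", seed=SEED, chrom="chr7", sample_id=sid)
    segs1, bps1, _ = simulate_chromothripsis_chrom("amplifying", seed=SEED + 1, chrom="chr1", sample_id=sid)
    inter = [
        Breakpoint(sid, "chr7", 2_500_000, "chr1", 3_500_000, 180),
        Breakpoint(sid, "chr7", 6_100_000, "chr1", 7_900_000, 140),
    ]
    write_segments(segs7 + segs1, OUT / "sv.seg.tsv")
    write_breakpoints(bps7 + bps1 + inter, OUT / "sv.bedpe")
    cfg["sv"] = {"sample_id": sid, "seg": str(OUT / "sv.seg.tsv"), "bedpe": str(OUT / "sv.bedpe")}

    (OUT / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    n = {t: len(v) for t, v in pat.variants_by_timepoint.items()}
    print(f"wrote {OUT}")
    print(f"called mutations per timepoint: {n}")
    print(f"planted clones: {[c.ccf_by_timepoint for c in pat.clones]}")


if __name__ == "__main__":
    main()
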