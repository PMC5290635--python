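#!/usr/bin/env python
"""Per-timepoint substitution spectra, hypermutation status and MMR screen.

Reads the simulated serial exomes (01) and reports, per timepoint, the
6-class spectrum with the C>T transition percent, the coding mutation burden
against the hypermutation threshold, and non-synonymous hits in the mismatch
repair genes.

Writes results/spectra.tsv and results/hypermutation.json.
"""

import json
from pathlib import Path

import pandas as pd

from longevol.io_formats import read_somatic_vcf
from longevol.signatures import CLASSES6, flag_hypermutation, spectrum

ROOT = Path(__file__).resolve().parents[1]
CONFIG = ROOT / "scratch" / "data" / "patient" / "config.json"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = json.loads(CONFIG.read_text())
    rows, hyper = [], {}
    for e in cfg["timepoints"]:
        t = e["timepoint"]
        variants = read_somatic_vcf(e["vcf"], e["sample_id"])
        sp = spectrum(variants)
        h = flag_hypermutation(variants)
        hyper[str(t)] = h.to_jsonable()
        rows.append(
            {"timepoint": t, "n_snv": sp.n_snv, "ct_percent": sp.ct_percent,
             **{c: sp.counts6.get(c, 0) for c in CLASSES6}}
        )
        print(f"t{t}: {h.coding_snv_count} coding SNVs "
              f"({'hypermutated' if h.is_hypermutated else 'not hypermutated'}), "
              f"C>T transition ratio {sp.ct_percent}%, MMR hits {h.mmr_hits}")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "spectra.tsv", sep="\t", index=False)
    (RESULTS / "hypermutation.json").write_text(json.dumps(hyper, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
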