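"""Cancer cell fraction (clonality rate) estimation.

The clonality rate of a somatic mutation is the fraction of tumor cells that
carry it. Under the standard purity/ploidy model the expected variant allele
frequency of a mutation present at multiplicity ``m`` (mutant copies per
tumor cell) in a fraction ``ccf`` of tumor cells is

    vaf = purity * m * ccf / (purity * cn_t + (1 - purity) * cn_n)

where ``cn_t`` is the local tumor total copy number and ``cn_n`` the normal
copy number (2 for autosomes). Inverting this for ``ccf``, with ``m``
estimated per variant by rounding the implied mutant copy count, converts
observed VAFs into clonality rates. Clonality rates across serial tumors of
one patient are assembled into a mutations x timepoints matrix — the
substrate of the mixture clustering in :mod:`longevol.evolution`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CNSegment, SampleMeta, SomaticVariant

__all__ = [
    "CcfRecord",
    "CcfMatrix",
    "estimate_multiplicity",
    "compute_ccf",
    "expected_vaf",
    "assemble_ccf_matrix",
    "CCF_CAP",
    "INCONSISTENT_CCF",
]

CCF_CAP = 1.5  # reporting cap; preserves >1 inconsistency signal without letting outliers dominate
INCONSISTENT_CCF = 1.2  # raw ccf above this flags a purity/copy-number inconsistency
NORMAL_CN = 2.0

VariantKey = tuple[str, int, str, str]

OBSERVED = "observed"
ABSENT_CONFIDENT = "absent_confident"
ABSENT_LOWDEPTH = "absent_lowdepth"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CcfRecord:
    """Clonality estimate for one variant in one sample."""

    variant_key: VariantKey
    multiplicity: int
    ccf: float
    flagged_inconsistent: bool
    ccf_raw: float


@dataclass
class CcfMatrix:
    """Union-of-mutations x timepoints matrix of clonality rates.

    ``mask`` records, per cell, whether the mutation was observed, confidently
    absent (site covered at >= min_depth but not called; ccf set to 0), or
    uncalled with no/low coverage information (``absent_lowdepth``). Rows with
    any low-depth cell are excluded from downstream clustering because absence
    cannot be distinguished from dropout there.
    """

    variant_keys: list[VariantKey]
    timepoints: list[int]
    values: np.ndarray  # (n_variants, n_timepoints)
    mask: np.ndarray  # same shape, dtype <U16

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        n, d = self.values.shape
        if len(self.variant_keys) != n or len(self.timepoints) != d:
            raise ValueError("CcfMatrix dimensions inconsistent")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        bad = (self.mask == ABSENT_CONFIDENT) & (self.values != 0.0)
        if bad.any():
            raise ValueError("absent_confident cells must have ccf exactly 0")

    @property
    def clustering_rows(self) -> np.ndarray:
        """Boolean selector of rows usable for clustering (no low-depth cell)."""
        return ~(self.mask == ABSENT_LOWDEPTH).any(axis=1)

    def clustering_matrix(self) -> tuple[list[VariantKey], np.ndarray]:
        keep = self.clustering_rows
        keys = [k for k, ok in zip(self.variant_keys, keep) if ok]
        return keys, self.values[keep]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"ccf_t{t}" for t in self.timepoints]
        )
        for j, t in enumerate(self.timepoints):
            df[f"mask_t{t}"] = self.mask[:, j]
        df.insert(0, "variant", [":".join(map(str, k)) for k in self.variant_keys])
        return df

    def to_jsonable(self) -> dict:
        return {
            "variant_keys": [":".join(map(str, k)) for k in self.variant_keys],
            "timepoints": self.timepoints,
            "values": self.values.tolist(),
            "mask": self.mask.tolist(),
        }


def estimate_multiplicity(
    vaf: float, purity: float, tumor_cn: float, normal_cn: float = NORMAL_CN
) -> int:
    """Estimate the mutant-allele multiplicity from an observed VAF.

    The implied mutant copy number per tumor cell,
    ``vaf * (purity*tumor_cn + (1-purity)*normal_cn) / purity``, is rounded
    (half away from zero) and clipped to [1, max(1, round(tumor_cn))].
    """
    if purity <= 0:
        raise ValueError(f"purity must be positive, got {purity}")
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf out of [0,1]: {vaf}")
    if tumor_cn < 0:
        raise ValueError(f"negative tumor copy number {tumor_cn}")
    implied = vaf * (purity * tumor_cn + (1.0 - purity) * normal_cn) / purity
    hi = max(1, _round_half_away(tumor_cn))
    return int(min(max(_round_half_away(implied), 1), hi))


def compute_ccf(
    variant: SomaticVariant,
    meta: SampleMeta,
    tumor_cn: float,
    multiplicity: int,
    normal_cn: float = NORMAL_CN,
    ccf_cap: float = CCF_CAP,
) -> CcfRecord:
    """Convert one variant's VAF into a clonality rate.

    Raw ccf above :data:`INCONSISTENT_CCF` is flagged; the reported value is
    capped at ``ccf_cap``.
    """
    if variant.depth == 0:
        raise ValueError(f"zero depth at {variant.chrom}:{variant.pos}")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    vaf = variant.vaf
    purity = meta.purity
    ccf_raw = vaf * (purity * tumor_cn + (1.0 - purity) * normal_cn) / (
        purity * multiplicity
    )
    return CcfRecord(
        variant_key=variant.key,
        multiplicity=multiplicity,
        ccf=min(ccf_raw, ccf_cap),
        flagged_inconsistent=ccf_raw > INCONSISTENT_CCF,
        ccf_raw=ccf_raw,
    )


def expected_vaf(
    ccf: float,
    purity: float,
    tumor_cn: float,
    multiplicity: int = 1,
    normal_cn: float = NORMAL_CN,
) -> float:
    """Forward model: expected VAF of a mutation at clonality ``ccf``."""
    denom = purity * tumor_cn + (1.0 - purity) * normal_cn
    if denom <= 0:
        raise ValueError("degenerate copy-number state")
    return purity * multiplicity * ccf / denom


def _segment_lookup(
    segments: Sequence[CNSegment],
) -> dict[str, list[CNSegment]]:
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.start)
    return by_chrom


def _find_cn(
    by_chrom: dict[str, list[CNSegment]], chrom: str, pos: int
) -> float | None:
    import bisect

    lst = by_chrom.get(chrom, [])
    starts = [s.start for s in lst]
    i = bisect.bisect_right(starts, pos) - 1
    if i >= 0 and lst[i].overlaps(pos):
        return lst[i].total_cn
    return None


def assemble_ccf_matrix(
    variants_by_timepoint: Mapping[int, Sequence[SomaticVariant]],
    segments_by_timepoint: Mapping[int, Sequence[CNSegment]],
    metas: Sequence[SampleMeta],
    min_depth: int = 20,
    site_depth: Mapping[tuple[int, VariantKey], int] | None = None,
    default_cn: float | None = None,
    ccf_cap: float = CCF_CAP,
) -> CcfMatrix:
    """Assemble the clonality matrix over the union of mutations.

    A mutation uncalled at timepoint ``t`` is scored ccf 0 with mask
    ``absent_confident`` when ``site_depth`` reports coverage >= ``min_depth``
    at that site in sample ``t``; with no (or low) coverage information the
    cell is masked ``absent_lowdepth`` and the row is excluded from
    clustering. ``site_depth`` maps ``(timepoint, variant_key) -> depth`` and
    typically comes from a pileup over the union sites (or the simulator's
    coverage table).

    Raises on a duplicate variant key within one timepoint, and on a called
    variant with no overlapping copy-number segment unless ``default_cn``
    is given.
    """
    timepoints = sorted(variants_by_timepoint)
    if len(timepoints) < 2:
        raise ValueError("need >= 2 timepoints to assemble a clonality matrix")
    meta_by_tp = {m.timepoint: m for m in metas}
    missing = [t for t in timepoints if t not in meta_by_tp]
    if missing:
        raise ValueError(f"metadata missing for timepoints {missing}")

    calls: dict[int, dict[VariantKey, SomaticVariant]] = {}
    for t in timepoints:
        d: dict[VariantKey, SomaticVariant] = {}
        for v in variants_by_timepoint[t]:
            if v.key in d:
                raise ValueError(f"duplicate variant {v.key} at timepoint {t}")
            d[v.key] = v
        calls[t] = d

    union = sorted({k for d in calls.values() for k in d})
    seg_lookup = {
        t: _segment_lookup(segments_by_timepoint.get(t, [])) for t in timepoints
    }

    values = np.zeros((len(union), len(timepoints)))
    mask = np.full((len(union), len(timepoints)), ABSENT_LOWDEPTH, dtype="<U16")
    for i, key in enumerate(union):
        chrom, pos, _, _ = key
        for j, t in enumerate(timepoints):
            v = calls[t].get(key)
            if v is not None:
                cn = _find_cn(seg_lookup[t], chrom, pos)
                if cn is None:
                    if default_cn is None:
                        raise ValueError(
                            f"no copy-number segment covers {chrom}:{pos} at "
                            f"timepoint {t} and no default_cn configured"
                        )
                    cn = default_cn
                meta = meta_by_tp[t]
                m = estimate_multiplicity(v.vaf, meta.purity, cn)
                rec = compute_ccf(v, meta, cn, m, ccf_cap=ccf_cap)
                values[i, j] = rec.ccf
                mask[i, j] = OBSERVED
            else:
                depth = None if site_depth is None else site_depth.get((t, key))
                if depth is not None and depth >= min_depth:
                    values[i, j] = 0.0
                    mask[i, j] = ABSENT_CONFIDENT
                # else: stays absent_lowdepth / 0
    return CcfMatrix(
        variant_keys=list(union), timepoints=timepoints, values=values, mask=mask
    )
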