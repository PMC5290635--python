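"""Synthetic serial-tumor data with full truth tables.

The generators emulate the statistical structure the analysis assumes, on a
miniature genome (10 Mb chromosomes) so fixtures stay tiny:

* ``simulate_patient`` — serial tumors of one patient whose mutations belong
  to planted clones with known clonality trajectories (a founding preserved
  clone, a clone lost under therapy, late-emerging clones). Read counts are
  binomially sampled at Poisson depth under the purity/ploidy VAF model;
  mutations with fewer than ``call_min`` alt reads at a timepoint are omitted
  from that timepoint's calls, mimicking caller dropout, and a per-site
  coverage table stands in for a pileup over the union sites.
* ``simulate_chromothripsis_chrom`` — oscillating high-copy (amplifying) or
  extensively deleted (deleting) chromosomes with clustered, high-support
  breakpoints, versus quiet diploid chromosomes.
* ``simulate_spectrum`` — SNVs drawn i.i.d. from a 6-class substitution
  profile with uniform compatible trinucleotide contexts and random strand
  presentation.
* ``simulate_cohort`` — a labeled cohort with exact (rounded, not sampled)
  per-subtype positive counts, so screening results are checkable exactly.

Every generator is a pure function of (specification, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clonality import expected_vaf
from .io_formats import (
    Breakpoint,
    CNSegment,
    SampleMeta,
    SomaticVariant,
    write_breakpoints,
    write_sample_meta,
    write_segments,
    write_somatic_vcf,
)
from .signatures import CLASSES6

__all__ = [
    "CloneSpec",
    "SimulatedPatient",
    "default_patient_clones",
    "showcase_patient_clones",
    "simulate_patient",
    "simulate_chromothripsis_chrom",
    "simulate_spectrum",
    "simulate_cohort",
    "DEFAULT_DEPTH_MEAN",
    "DEFAULT_PURITY",
]

DEFAULT_DEPTH_MEAN = 200.0
DEFAULT_PURITY = 0.5
DEFAULT_CALL_MIN = 3
CHROM_LENGTH = 10_000_000
_CHROM_POOL = tuple(f"chr{i}" for i in range(1, 23))

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Baseline exome substitution profile (moderate C>T excess, as in untreated
# tumors); the alkylator/MMR-deficient profile concentrates mass on C>T.
BASELINE_PROFILE = (0.10, 0.08, 0.45, 0.08, 0.17, 0.12)
ALKYLATOR_PROFILE = (0.006, 0.006, 0.970, 0.006, 0.006, 0.006)


def profile_with_ct_mass(ct: float) -> tuple[float, ...]:
    """A 6-class profile with the given C>T mass; the remaining mass is
    spread over the other classes in the baseline proportions."""
    if not (0.0 <= ct <= 1.0):
        raise ValueError("ct mass must be in [0,1]")
    others = [p for i, p in enumerate(BASELINE_PROFILE) if i != 2]
    scale = (1.0 - ct) / sum(others)
    out = [p * scale for p in others]
    out.insert(2, ct)
    return tuple(out)


@dataclass(frozen=True)
class CloneSpec:
    """A planted clone: clonality trajectory, size and mutation character."""

    clone_id: int
    ccf_by_timepoint: tuple[float, ...]
    n_mutations: int
    spectrum_profile: tuple[float, ...] = BASELINE_PROFILE
    coding_fraction: float = 0.7

    def __post_init__(self) -> None:
        if any(not (0.0 <= c <= 1.0) for c in self.ccf_by_timepoint):
            raise ValueError("clone ccf values must be in [0,1]")
        if abs(sum(self.spectrum_profile) - 1.0) > 1e-9:
            raise ValueError("spectrum_profile must sum to 1")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")


def default_patient_clones(n_mutations: int = 50) -> list[CloneSpec]:
    """Four planted clones: preserved, lost, emerged@2 and emerged@3.

    The late-emerging clone carries the alkylator-skewed C>T-dominant profile.
    """
    return [
        CloneSpec(1, (0.9, 0.9, 0.9), n_mutations, BASELINE_PROFILE),
        CloneSpec(2, (0.6, 0.0, 0.0), n_mutations, BASELINE_PROFILE),
        CloneSpec(3, (0.0, 0.6, 0.6), n_mutations, BASELINE_PROFILE),
        CloneSpec(4, (0.0, 0.0, 0.6), n_mutations, ALKYLATOR_PROFILE),
    ]


def showcase_patient_clones() -> list[CloneSpec]:
    """A showcase serial-tumor patient: tens of mutations per early clone and
    a hypermutant late clone with thousands of C>T-dominant mutations.

    Per-clone C>T masses are chosen so the emitted per-timepoint call sets
    carry the study's per-timepoint C>T transition ratios (~68% primary,
    ~54% first recurrence, >95% hypermutated second recurrence) and the late
    clone contributes ~2 000 coding calls at the final timepoint.
    """
    return [
        CloneSpec(1, (0.9, 0.9, 0.9), 60, profile_with_ct_mass(0.72)),
        CloneSpec(2, (0.6, 0.0, 0.0), 40, profile_with_ct_mass(0.62)),
        CloneSpec(3, (0.0, 0.6, 0.6), 40, profile_with_ct_mass(0.27)),
        CloneSpec(4, (0.0, 0.0, 0.6), 2900, ALKYLATOR_PROFILE),
    ]


def _draw_context(rng: np.random.Generator, cls6: str) -> str:
    mid = cls6[0]
    return rng.choice(list(_BASES)) + mid + rng.choice(list(_BASES))


def _present(rng: np.random.Generator, cls6: str, context: str) -> tuple[str, str, str]:
    """Randomly present a pyrimidine-strand class on either strand."""
    ref, alt = cls6[0], cls6[2]
    if rng.random() < 0.5:
        rc = "".join(_COMPLEMENT[b] for b in reversed(context))
        return _COMPLEMENT[ref], _COMPLEMENT[alt], rc
    return ref, alt, context


def _unique_loci(
    rng: np.random.Generator, n: int, chroms: Sequence[str] = _CHROM_POOL
) -> list[tuple[str, int]]:
    loci: set[tuple[str, int]] = set()
    while len(loci) < n:
        c = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(2, CHROM_LENGTH - 1))
        loci.add((c, p))
    return sorted(loci)


@dataclass
class SimulatedPatient:
    """In-memory serial-tumor fixture plus complete truth tables."""

    patient_id: str
    metas: list[SampleMeta]
    variants_by_timepoint: dict[int, list[SomaticVariant]]
    segments_by_timepoint: dict[int, list[CNSegment]]
    site_depth: dict[tuple[int, tuple[str, int, str, str]], int]
    truth: pd.DataFrame  # one row per mutation: clone_id, locus, true ccfs, m, class6
    clones: list[CloneSpec]

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.variants_by_timepoint)

    def write(self, out_dir: str | Path) -> dict:
        """Emit VCF/SEG/coverage/meta/truth files; returns a config mapping
        consumable by :func:`longevol.cohort_report.run_patient`."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tp_entries = []
        for m in sorted(self.metas, key=lambda m: m.timepoint):
            t = m.timepoint
            vcf = write_somatic_vcf(
                self.variants_by_timepoint[t], out / f"t{t}.vcf", m.sample_id
            )
            seg = write_segments(self.segments_by_timepoint[t], out / f"t{t}.seg.tsv")
            cov_rows = [
                {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "depth": d}
                for (tt, k), d in sorted(self.site_depth.items())
                if tt == t
            ]
            cov = out / f"t{t}.coverage.tsv"
            pd.DataFrame(cov_rows).to_csv(cov, sep="\t", index=False)
            tp_entries.append(
                {
                    "timepoint": t,
                    "sample_id": m.sample_id,
                    "vcf": str(vcf),
                    "seg": str(seg),
                    "coverage": str(cov),
                }
            )
        write_sample_meta(self.metas, out / "meta.tsv")
        self.truth.to_csv(out / "truth_mutations.tsv", sep="\t", index=False)
        return {"patient_id": self.patient_id, "timepoints": tp_entries}


def simulate_patient(
    clones: Sequence[CloneSpec] | None = None,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    purity_by_timepoint: Sequence[float] | None = None,
    seed: int = 0,
    patient_id: str = "PT1",
    call_min: int = DEFAULT_CALL_MIN,
    tumor_cn: float = 2.0,
    multiplicity: int = 1,
    subtypes: Sequence[str] | None = None,
) -> SimulatedPatient:
    """Simulate serial tumors of one patient from planted clones.

    Per mutation and timepoint: expected VAF follows the purity/ploidy model,
    depth ~ Poisson(``depth_mean``), alt reads ~ Binomial(depth, VAF).
    Mutations with fewer than ``call_min`` alt reads are omitted from that
    timepoint's call set (caller dropout); their site depth is still recorded
    in the coverage table, as a pileup would provide.
    """
    if clones is None:
        clones = default_patient_clones()
    if not clones:
        raise ValueError("need at least one clone")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    n_tp = len(clones[0].ccf_by_timepoint)
    if any(len(c.ccf_by_timepoint) != n_tp for c in clones):
        raise ValueError("all clones must cover the same timepoints")
    if purity_by_timepoint is None:
        purity_by_timepoint = [DEFAULT_PURITY] * n_tp
    if len(purity_by_timepoint) != n_tp:
        raise ValueError("purity_by_timepoint length mismatch")
    for c in clones:
        for tp, (ccf, purity) in enumerate(
            zip(c.ccf_by_timepoint, purity_by_timepoint), 1
        ):
            if expected_vaf(ccf, purity, tumor_cn, multiplicity) > 1.0:
                raise ValueError(
                    f"clone {c.clone_id} implies VAF > 1 at timepoint {tp}"
                )

    rng = np.random.default_rng(seed)
    subtypes = list(subtypes) if subtypes is not None else ["primary_gbm"] * n_tp
    metas = [
        SampleMeta(
            sample_id=f"{patient_id}_T{t}",
            patient_id=patient_id,
            timepoint=t,
            purity=float(purity_by_timepoint[t - 1]),
            subtype=subtypes[t - 1],
        )
        for t in range(1, n_tp + 1)
    ]

    total_n = sum(c.n_mutations for c in clones)
    loci = _unique_loci(rng, total_n)
    rng.shuffle(loci)

    # Planted marker mutations mirroring the biology the fixture emulates:
    # an activating EGFR mutation in the lost clone, an MMR (MSH6) missense
    # in the late hypermutant clone.
    markers: dict[int, tuple[str, int, str, str, str, str]] = {}
    lost = [c for c in clones if c.ccf_by_timepoint[0] > 0 and c.ccf_by_timepoint[-1] == 0]
    late = [
        c
        for c in clones
        if c.ccf_by_timepoint[0] == 0 and c.ccf_by_timepoint[-1] > 0
    ]
    # positions scaled onto the 10 Mb miniature chromosomes
    if lost:
        markers[lost[0].clone_id] = ("chr7", 5522182, "C", "T", "EGFR", "A289V")
    if late:
        markers[late[-1].clone_id] = ("chr2", 4803064, "C", "T", "MSH6", "T767I")

    variants_by_tp: dict[int, list[SomaticVariant]] = {t: [] for t in range(1, n_tp + 1)}
    site_depth: dict[tuple[int, tuple[str, int, str, str]], int] = {}
    truth_rows = []
    li = 0
    for clone in clones:
        profile = np.asarray(clone.spectrum_profile)
        for i in range(clone.n_mutations):
            cls6 = CLASSES6[int(rng.choice(6, p=profile))]
            context = _draw_context(rng, cls6)
            if i == 0 and clone.clone_id in markers:
                chrom, pos, ref, alt, gene, pchange = markers[clone.clone_id]
                ctx = _BASES[int(rng.integers(4))] + ref + _BASES[int(rng.integers(4))]
                coding, effect = True, "missense"
            else:
                chrom, pos = loci[li]
                li += 1
                ref, alt, ctx = _present(rng, cls6, context)
                coding = bool(rng.random() < clone.coding_fraction)
                effect = "missense" if coding else "noncoding"
                gene = f"GENE{li:05d}" if coding else ""
                pchange = ""
            key = (chrom, pos, ref, alt)
            ccfs = []
            for t in range(1, n_tp + 1):
                purity = purity_by_timepoint[t - 1]
                v = expected_vaf(
                    clone.ccf_by_timepoint[t - 1], purity, tumor_cn, multiplicity
                )
                depth = int(rng.poisson(depth_mean))
                alt_count = int(rng.binomial(depth, v)) if depth > 0 else 0
                site_depth[(t, key)] = depth
                ccfs.append(clone.ccf_by_timepoint[t - 1])
                if alt_count >= call_min:
                    variants_by_tp[t].append(
                        SomaticVariant(
                            sample_id=metas[t - 1].sample_id,
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt,
                            ref_count=depth - alt_count,
                            alt_count=alt_count,
                            gene=gene,
                            effect=effect,
                            coding=coding,
                            context=ctx,
                            protein_change=pchange,
                        )
                    )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "clone_id": clone.clone_id,
                    "multiplicity": multiplicity,
                    "class6": cls6,
                    **{f"ccf_t{t}": ccfs[t - 1] for t in range(1, n_tp + 1)},
                }
            )

    segments = {
        t: [
            CNSegment(
                sample_id=metas[t - 1].sample_id,
                chrom=c,
                start=1,
                end=CHROM_LENGTH,
                total_cn=tumor_cn,
                laf=0.5,
            )
            for c in _CHROM_POOL
        ]
        for t in range(1, n_tp + 1)
    }
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SimulatedPatient(
        patient_id=patient_id,
        metas=metas,
        variants_by_timepoint={t: sorted(v, key=lambda x: x.key) for t, v in variants_by_tp.items()},
        segments_by_timepoint=segments,
        site_depth=site_depth,
        truth=truth,
        clones=list(clones),
    )


def simulate_chromothripsis_chrom(
    mode: str,
    n_segments: int | None = None,
    seed: int = 0,
    chrom: str = "chr7",
    sample_id: str = "S1",
    partner_chrom: str | None = None,
    chrom_length: int = CHROM_LENGTH,
) -> tuple[list[CNSegment], list[Breakpoint], bool]:
    """Simulate one chromosome's copy-number and breakpoint profile.

    ``amplifying``: copy states oscillate between the diploid baseline and a
    high state >= 20 with clustered intra-chromosomal breakpoints of support
    >= 110. ``deleting``: >= 30% of the length at CN <= 1 with supported
    breaks and, when ``partner_chrom`` is given, supported inter-chromosomal
    links. ``quiet``: one diploid segment and at most two low-support
    breakpoints. Returns (segments, breakpoints, truth flag).
    """
    rng = np.random.default_rng(seed)
    if mode == "quiet":
        segs = [CNSegment(sample_id, chrom, 1, chrom_length, 2.0, laf=0.5)]
        bps = []
        for _ in range(int(rng.integers(0, 3))):
            a, b = sorted(rng.integers(1, chrom_length, size=2).tolist())
            bps.append(
                Breakpoint(sample_id, chrom, int(a) + 1, chrom, int(b) + 1,
                           support=int(rng.integers(2, 50)))
            )
        return segs, bps, False
    if mode not in ("amplifying", "deleting"):
        raise ValueError(f"unknown mode {mode!r}")

    if n_segments is None:
        n_segments = int(rng.integers(20, 61))
    if n_segments < 2:
        raise ValueError("non-quiet modes need n_segments >= 2")

    for _ in range(100):
        cuts = np.sort(rng.choice(np.arange(2, chrom_length), n_segments - 1, replace=False))
        bounds = [1, *cuts.tolist(), chrom_length]
        segs = []
        alt_len = 0
        for i in range(n_segments):
            start, end = bounds[i] + (i > 0), bounds[i + 1]
            if mode == "amplifying":
                cn = float(rng.integers(20, 31)) if i % 2 else 2.0
                laf = float(rng.uniform(0.0, 0.15)) if i % 2 else 0.5
            else:
                cn = float(rng.integers(0, 2)) if i % 2 else 2.0
                laf = 0.0 if i % 2 else 0.5
            if i % 2:
                alt_len += end - start + 1
            segs.append(CNSegment(sample_id, chrom, start, end, cn, laf=laf))
        if mode == "amplifying" or alt_len / chrom_length >= 0.32:
            break
    else:  # pragma: no cover - resampling virtually always succeeds
        raise RuntimeError("could not satisfy deleted-fraction constraint")

    bps = []
    altered = [s for s in segs if (s.total_cn >= 20) == (mode == "amplifying") and s.total_cn != 2.0]
    n_bps = n_segments + int(rng.integers(4, 10))
    for _ in range(n_bps):
        if mode == "amplifying" and len(altered) >= 2:
            i, j = rng.choice(len(altered), size=2, replace=False)
            pa = int(rng.integers(altered[i].start, altered[i].end + 1))
            pb = int(rng.integers(altered[j].start, altered[j].end + 1))
        else:
            pa, pb = sorted(rng.integers(1, chrom_length + 1, size=2).tolist())
        bps.append(
            Breakpoint(sample_id, chrom, int(pa), chrom, int(pb),
                       support=int(rng.integers(110, 301)))
        )
    if mode == "deleting" and partner_chrom is not None:
        for _ in range(int(rng.integers(2, 5))):
            bps.append(
                Breakpoint(
                    sample_id,
                    chrom,
                    int(rng.integers(1, chrom_length + 1)),
                    partner_chrom,
                    int(rng.integers(1, chrom_length + 1)),
                    support=int(rng.integers(110, 301)),
                )
            )
    return segs, bps, True


def simulate_spectrum(
    profile: Sequence[float],
    n: int,
    seed: int = 0,
    sample_id: str = "S1",
    coding_fraction: float = 0.7,
    depth: int = 200,
) -> list[SomaticVariant]:
    """Draw ``n`` SNVs i.i.d. from a 6-class substitution profile.

    Contexts are uniform over compatible trinucleotides; each variant is
    presented on a random strand (pyrimidine or purine reference).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    profile = np.asarray(profile, dtype=float)
    if abs(profile.sum() - 1.0) > 1e-9:
        raise ValueError("profile must sum to 1")
    rng = np.random.default_rng(seed)
    loci = _unique_loci(rng, n)
    rng.shuffle(loci)
    out = []
    for i in range(n):
        cls6 = CLASSES6[int(rng.choice(6, p=profile))]
        ref, alt, ctx = _present(rng, cls6, _draw_context(rng, cls6))
        chrom, pos = loci[i]
        alt_count = int(rng.binomial(depth, 0.25))
        coding = bool(rng.random() < coding_fraction)
        out.append(
            SomaticVariant(
                sample_id=sample_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                ref_count=depth - alt_count,
                alt_count=alt_count,
                gene=f"GENE{i:05d}" if coding else "",
                effect="missense" if coding else "noncoding",
                coding=coding,
                context=ctx,
            )
        )
    return out


def simulate_cohort(
    n_by_subtype: Mapping[str, int],
    positive_rate_by_subtype: Mapping[str, float],
    seed: int = 0,
    n_quiet_chroms: int = 3,
) -> tuple[
    dict[str, tuple[list[CNSegment], list[Breakpoint]]],
    list[SampleMeta],
    pd.DataFrame,
]:
    """Simulate a labeled cohort for the chromothripsis screen.

    Exactly ``round(rate * n)`` samples per subtype are planted positive
    (an amplifying chromothriptic chromosome); the remainder are quiet
    genomes. Returns (per-sample (segments, breakpoints), metas, truth).
    """
    rng = np.random.default_rng(seed)
    data: dict[str, tuple[list[CNSegment], list[Breakpoint]]] = {}
    metas: list[SampleMeta] = []
    truth_rows = []
    for subtype in sorted(n_by_subtype):
        n = int(n_by_subtype[subtype])
        rate = float(positive_rate_by_subtype.get(subtype, 0.0))
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"rate out of [0,1] for {subtype}")
        n_pos = int(round(rate * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:n_pos]] = True
        for i in range(n):
            sid = f"{subtype[:4].upper()}{i + 1:03d}"
            sub_seed = int(rng.integers(2**31 - 1))
            segs: list[CNSegment] = []
            bps: list[Breakpoint] = []
            quiet_chroms = [f"chr{c}" for c in range(1, n_quiet_chroms + 1)]
            for qi, qc in enumerate(quiet_chroms):
                s, b, _ = simulate_chromothripsis_chrom(
                    "quiet", seed=(sub_seed + qi) % (2**31 - 1), chrom=qc, sample_id=sid
                )
                segs += s
                bps += b
            if flags[i]:
                s, b, _ = simulate_chromothripsis_chrom(
                    "amplifying", seed=sub_seed, chrom="chr7", sample_id=sid
                )
                segs += s
                bps += b
            data[sid] = (segs, bps)
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    patient_id=sid,
                    timepoint=1,
                    purity=0.5,
                    subtype=subtype,
                )
            )
            truth_rows.append(
                {"sample": sid, "subtype": subtype, "chromothripsis": bool(flags[i])}
            )
    truth = pd.DataFrame(truth_rows)
    return data, metas, truth
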