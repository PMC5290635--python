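"""Readers and writers for the formats the pipeline touches.

Somatic SNV/INDEL calls come in as VCF v4.2 with per-sample allele depths
(FORMAT ``AD``), copy-number segments as a SEG-like TSV, and structural-variant
junctions as BEDPE. Everything is parsed into small immutable domain records;
coordinates are normalised to 1-based inclusive in memory (BEDPE is 0-based
half-open on disk and converted on read/write). Chromosome names are
normalised to the ``chr``-prefixed form.

Pipeline products are written as deterministic JSON (sorted keys) with a flat
TSV twin where a tabular view exists.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF, Writer  # noqa: F401  (Writer re-exported for callers)

__all__ = [
    "SomaticVariant",
    "SampleMeta",
    "CNSegment",
    "Breakpoint",
    "FormatError",
    "normalize_chrom",
    "read_somatic_vcf",
    "write_somatic_vcf",
    "read_segments",
    "write_segments",
    "read_breakpoints",
    "write_breakpoints",
    "read_sample_meta",
    "write_sample_meta",
    "write_report",
    "read_report",
]

EFFECTS = frozenset(
    {"missense", "nonsense", "synonymous", "frameshift", "splice", "noncoding", "other"}
)
SUBTYPES = frozenset({"primary_gbm", "secondary_gbm", "other"})

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_chrom(chrom: str) -> str:
    """Return the chromosome name in ``chr``-prefixed form."""
    chrom = str(chrom).strip()
    if not chrom:
        raise FormatError("empty chromosome name")
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call in one sample, with allele depths and annotation.

    ``context`` is the reference-strand trinucleotide around the site (middle
    base = ref base for SNVs); empty when unavailable.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    gene: str = ""
    effect: str = "other"
    coding: bool = False
    context: str = ""
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise FormatError(
                f"negative allele depth at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise FormatError(f"non-positive position {self.pos}")
        if self.effect not in EFFECTS:
            object.__setattr__(self, "effect", "other")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float | None:
        """Variant allele frequency; None when the site has zero depth."""
        d = self.depth
        return None if d == 0 else self.alt_count / d

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def context_valid(self) -> bool:
        return (
            self.is_snv
            and len(self.context) == 3
            and set(self.context) <= _BASES
            and self.context[1] == self.ref
        )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata: serial position, purity and subtype label.

    ``purity`` is the tumor-cell fraction of the specimen (1 − admixture rate).
    """

    sample_id: str
    patient_id: str
    timepoint: int
    purity: float
    subtype: str = "other"

    def __post_init__(self) -> None:
        if self.timepoint < 1:
            raise FormatError(f"timepoint must be >= 1, got {self.timepoint}")
        if not (0.0 < self.purity <= 1.0):
            raise FormatError(f"purity must be in (0, 1], got {self.purity}")
        if self.subtype not in SUBTYPES:
            raise FormatError(f"unknown subtype {self.subtype!r}")


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment: total copies plus optional lesser-allele frequency."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    total_cn: float
    laf: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"segment start > end at {self.chrom}:{self.start}-{self.end}"
            )
        if self.total_cn < 0:
            raise FormatError(f"negative copy number {self.total_cn}")
        if self.laf is not None and not (0.0 <= self.laf <= 0.5):
            raise FormatError(f"lesser-allele frequency out of [0,0.5]: {self.laf}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class Breakpoint:
    """An SV junction between two genomic positions, with supporting reads.

    Ends are stored canonically ordered, positions 1-based. ``kind`` is
    ``intra`` iff both ends are on the same chromosome.
    """

    sample_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    support: int

    def __post_init__(self) -> None:
        if self.support < 0:
            raise FormatError(f"negative breakpoint support {self.support}")
        if self.pos_a < 1 or self.pos_b < 1:
            raise FormatError("non-positive breakpoint position")
        a = (normalize_chrom(self.chrom_a), int(self.pos_a))
        b = (normalize_chrom(self.chrom_b), int(self.pos_b))
        if b < a:
            a, b = b, a
        object.__setattr__(self, "chrom_a", a[0])
        object.__setattr__(self, "pos_a", a[1])
        object.__setattr__(self, "chrom_b", b[0])
        object.__setattr__(self, "pos_b", b[1])

    @property
    def kind(self) -> str:
        return "intra" if self.chrom_a == self.chrom_b else "inter"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class">',
    '##INFO=<ID=TNC,Number=1,Type=String,Description="Reference-strand trinucleotide context">',
    '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">',
    '##INFO=<ID=CODING,Number=0,Type=Flag,Description="Variant is in a coding region">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
]


def read_somatic_vcf(path: str | Path, sample_id: str) -> list[SomaticVariant]:
    """Parse a somatic VCF into one :class:`SomaticVariant` per ALT allele.

    Requires a per-sample FORMAT ``AD`` field; multi-allelic records are split.
    Annotation is taken from the INFO keys ``GENE``, ``EFFECT``, ``TNC``,
    ``PCHANGE`` and the ``CODING`` flag when present.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on malformed input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    try:
        if sample_id not in vcf.samples:
            raise FormatError(
                f"sample {sample_id!r} not in VCF {path} (samples: {vcf.samples})"
            )
        si = vcf.samples.index(sample_id)
        out: list[SomaticVariant] = []
        try:
            records = list(vcf)
        except Exception as exc:
            raise FormatError(f"malformed VCF record in {path}: {exc}") from exc
        for rec in records:
            ad = rec.format("AD")
            if ad is None:
                raise FormatError(
                    f"record {rec.CHROM}:{rec.POS} in {path} lacks FORMAT AD"
                )
            row = ad[si]
            if int(row[0]) < 0:
                raise FormatError(
                    f"record {rec.CHROM}:{rec.POS} in {path} has missing AD"
                )
            info = dict(rec.INFO)
            for j, alt in enumerate(rec.ALT):
                alt_count = int(row[1 + j]) if 1 + j < len(row) else -1
                if alt_count < 0:
                    raise FormatError(
                        f"record {rec.CHROM}:{rec.POS} in {path} has missing AD"
                    )
                out.append(
                    SomaticVariant(
                        sample_id=sample_id,
                        chrom=rec.CHROM,
                        pos=int(rec.POS),
                        ref=rec.REF,
                        alt=str(alt),
                        ref_count=int(row[0]),
                        alt_count=alt_count,
                        gene=str(info.get("GENE", "") or ""),
                        effect=str(info.get("EFFECT", "other") or "other"),
                        coding=bool(info.get("CODING", False)),
                        context=str(info.get("TNC", "") or ""),
                        protein_change=str(info.get("PCHANGE", "") or ""),
                    )
                )
    finally:
        vcf.close()
    out.sort(key=lambda v: v.key)
    return out


def write_somatic_vcf(
    variants: Sequence[SomaticVariant], path: str | Path, sample_id: str
) -> Path:
    """Write variants of one sample as a minimal VCF v4.2 with GT:AD."""
    path = Path(path)
    chroms = sorted({v.chrom for v in variants})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += _VCF_HEADER_LINES
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for v in sorted(variants, key=lambda v: v.key):
        info_parts = []
        if v.gene:
            info_parts.append(f"GENE={v.gene}")
        info_parts.append(f"EFFECT={v.effect}")
        if v.context:
            info_parts.append(f"TNC={v.context}")
        if v.protein_change:
            info_parts.append(f"PCHANGE={v.protein_change}")
        if v.coding:
            info_parts.append("CODING")
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    "PASS",
                    ";".join(info_parts) or ".",
                    "GT:AD",
                    f"0/1:{v.ref_count},{v.alt_count}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# SEG-like TSV
# ---------------------------------------------------------------------------

_SEG_COLS = ["sample", "chrom", "start", "end", "total_cn"]


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read a SEG-like TSV (1-based inclusive) into sorted, validated segments.

    Overlapping segments within one sample/chromosome are a format error;
    touching segments ([1,100], [101,200]) are accepted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in _SEG_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing SEG columns {missing}")
    has_laf = "laf" in df.columns
    segs = [
        CNSegment(
            sample_id=row["sample"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            total_cn=float(row["total_cn"]),
            laf=(
                None
                if not has_laf or pd.isna(row["laf"])
                else float(row["laf"])
            ),
        )
        for _, row in df.iterrows()
    ]
    segs.sort(key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
    for prev, cur in zip(segs, segs[1:]):
        if (
            prev.sample_id == cur.sample_id
            and prev.chrom == cur.chrom
            and cur.start <= prev.end
        ):
            raise FormatError(
                f"{path}: overlapping segments {prev.chrom}:{prev.start}-{prev.end} "
                f"and {cur.chrom}:{cur.start}-{cur.end} in sample {cur.sample_id}"
            )
    return segs


def write_segments(segments: Sequence[CNSegment], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "total_cn": s.total_cn,
            "laf": "" if s.laf is None else s.laf,
        }
        for s in sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start))
    ]
    pd.DataFrame(rows, columns=_SEG_COLS + ["laf"]).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
]


def read_breakpoints(path: str | Path, sample_id: str) -> list[Breakpoint]:
    """Read BEDPE junctions (0-based half-open starts; score = supporting reads).

    Positions are converted to 1-based and end ordering is canonicalised.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=_BEDPE_COLS,
        usecols=range(8), dtype={0: str, 3: str}, comment="#",
    )
    bps: list[Breakpoint] = []
    for i, row in df.iterrows():
        if int(row["start1"]) < 0 or int(row["start2"]) < 0:
            raise FormatError(f"{path}: negative coordinate on BEDPE row {i + 1}")
        score = row["score"]
        if float(score) != int(float(score)):
            raise FormatError(f"{path}: non-integer score on BEDPE row {i + 1}")
        bps.append(
            Breakpoint(
                sample_id=sample_id,
                chrom_a=str(row["chrom1"]),
                pos_a=int(row["start1"]) + 1,
                chrom_b=str(row["chrom2"]),
                pos_b=int(row["start2"]) + 1,
                support=int(float(score)),
            )
        )
    bps.sort(key=lambda b: (b.chrom_a, b.pos_a, b.chrom_b, b.pos_b))
    return bps


def write_breakpoints(breakpoints: Sequence[Breakpoint], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for b in sorted(breakpoints, key=lambda b: (b.chrom_a, b.pos_a, b.chrom_b, b.pos_b)):
        lines.append(
            "\t".join(
                map(
                    str,
                    [
                        b.chrom_a, b.pos_a - 1, b.pos_a,
                        b.chrom_b, b.pos_b - 1, b.pos_b,
                        b.sample_id, b.support,
                    ],
                )
            )
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample": str, "patient": str})
    metas = [
        SampleMeta(
            sample_id=row["sample"],
            patient_id=row["patient"],
            timepoint=int(row["timepoint"]),
            purity=float(row["purity"]),
            subtype=str(row["subtype"]),
        )
        for _, row in df.iterrows()
    ]
    seen: dict[tuple[str, int], str] = {}
    for m in metas:
        k = (m.patient_id, m.timepoint)
        if k in seen:
            raise FormatError(f"duplicate timepoint {k} in {path}")
        seen[k] = m.sample_id
    return metas


def write_sample_meta(metas: Sequence[SampleMeta], path: str | Path) -> Path:
    rows = [
        {
            "sample": m.sample_id,
            "patient": m.patient_id,
            "timepoint": m.timepoint,
            "purity": m.purity,
            "subtype": m.subtype,
        }
        for m in sorted(metas, key=lambda m: (m.patient_id, m.timepoint))
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    """Recursively convert domain objects to JSON-serialisable structures."""
    if hasattr(obj, "to_jsonable"):
        return _jsonable(obj.to_jsonable())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {_key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_jsonable(v) for v in obj]
        return sorted(items, key=json.dumps) if isinstance(obj, (set, frozenset)) else items
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _key(k: Any) -> str:
    if isinstance(k, tuple):
        return ":".join(str(x) for x in k)
    return str(k)


def write_report(product: Any, path: str | Path) -> dict[str, Path]:
    """Write a pipeline product as ``<path>.json`` (sorted keys) and, when the
    product exposes a tabular view (``to_frame``), a ``<path>.tsv`` twin.

    The JSON is deterministic: keys sorted, no timestamps.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    jpath = base.with_suffix(base.suffix + ".json") if base.suffix != ".json" else base
    jpath.write_text(
        json.dumps(_jsonable(product), sort_keys=True, indent=2, allow_nan=False)
        + "\n"
    )
    out["json"] = jpath
    if hasattr(product, "to_frame"):
        tpath = jpath.with_suffix(".tsv")
        product.to_frame().to_csv(tpath, sep="\t", index=False)
        out["tsv"] = tpath
    return out


def read_report(path: str | Path) -> Any:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
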