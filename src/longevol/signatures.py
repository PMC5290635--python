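"""Substitution spectra, hypermutation flagging and mismatch-repair screening.

Single-nucleotide substitutions are collapsed onto the pyrimidine reference
strand (a G>A call becomes C>T with reverse-complemented context), giving the
six canonical classes C>A, C>G, C>T, T>A, T>C, T>G and, where trinucleotide
contexts are annotated, the 96-class (5' base, class, 3' base) spectrum. The
C>T transition fraction is the headline statistic: alkylating-agent exposure
under mismatch-repair (MMR) deficiency drives it toward 1.

A sample is flagged hypermutated when its coding SNV count reaches a
configurable threshold (default 500, comfortably separating thousands of
coding mutations from the tens seen in non-hypermutated exomes), and its
non-synonymous variants are screened against the canonical MMR genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SomaticVariant

__all__ = [
    "CLASSES6",
    "MutationSpectrum",
    "HypermutationResult",
    "spectrum",
    "flag_hypermutation",
    "screen_mmr",
    "collapse_to_pyrimidine",
    "MMR_GENES",
    "NONSYNONYMOUS_EFFECTS",
]

CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})
NONSYNONYMOUS_EFFECTS = frozenset({"missense", "nonsense", "frameshift", "splice"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def collapse_to_pyrimidine(
    ref: str, alt: str, context: str = ""
) -> tuple[str, str] | None:
    """Collapse a substitution to the pyrimidine strand.

    Returns ``(class6, context)`` with the context reverse-complemented when
    the input reference base is a purine; ``None`` for non-SNVs. The returned
    context is "" when no (3-base) context was supplied.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return None
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = _revcomp(context) if len(context) == 3 else ""
    cls = f"{ref}>{alt}"
    return cls, context if len(context) == 3 else ""


@dataclass
class MutationSpectrum:
    """6-class and (context-resolved) 96-class substitution spectrum."""

    counts6: dict[str, int]
    counts96: dict[tuple[str, str, str], int]
    n_snv: int
    n_ignored_non_snv: int = 0
    n_context_invalid: int = 0

    @property
    def ct_fraction(self) -> float | None:
        """Fraction of SNVs that are C>T transitions; None when n_snv = 0."""
        if self.n_snv == 0:
            return None
        return self.counts6.get("C>T", 0) / self.n_snv

    @property
    def ct_percent(self) -> int | None:
        """C>T fraction as nearest-integer percent (reporting convention)."""
        f = self.ct_fraction
        return None if f is None else int(round(100.0 * f))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "count": self.counts6.get(c, 0)} for c in CLASSES6
        ]
        return pd.DataFrame(rows)

    def to_jsonable(self) -> dict:
        return {
            "counts6": {c: self.counts6.get(c, 0) for c in CLASSES6},
            "counts96": {
                f"{k[0]}[{k[1]}]{k[2]}": v for k, v in sorted(self.counts96.items())
            },
            "n_snv": self.n_snv,
            "n_ignored_non_snv": self.n_ignored_non_snv,
            "n_context_invalid": self.n_context_invalid,
            "ct_fraction": self.ct_fraction,
        }


def spectrum(variants: Iterable[SomaticVariant]) -> MutationSpectrum:
    """Compute the substitution spectrum of a variant set.

    Non-SNVs are ignored (counted in ``n_ignored_non_snv``). Variants whose
    annotated context disagrees with the reference base contribute to the
    6-class counts but are excluded from the 96-class counts
    (``n_context_invalid``).
    """
    counts6: Counter[str] = Counter()
    counts96: Counter[tuple[str, str, str]] = Counter()
    n_snv = 0
    n_non_snv = 0
    n_bad_context = 0
    for v in variants:
        collapsed = collapse_to_pyrimidine(v.ref, v.alt, v.context)
        if collapsed is None:
            n_non_snv += 1
            continue
        cls, ctx = collapsed
        counts6[cls] += 1
        n_snv += 1
        if v.context:
            if v.context_valid:
                counts96[(ctx[0], cls, ctx[2])] += 1
            else:
                n_bad_context += 1
    return MutationSpectrum(
        counts6=dict(counts6),
        counts96=dict(counts96),
        n_snv=n_snv,
        n_ignored_non_snv=n_non_snv,
        n_context_invalid=n_bad_context,
    )


@dataclass
class HypermutationResult:
    """Coding mutation burden and MMR-gene screening outcome for one sample."""

    sample_id: str
    coding_snv_count: int
    mut_per_mb: float
    is_hypermutated: bool
    mmr_hits: list[tuple[str, str, str]]  # (gene, protein_change, effect)

    def to_jsonable(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "coding_snv_count": self.coding_snv_count,
            "mut_per_mb": self.mut_per_mb,
            "is_hypermutated": self.is_hypermutated,
            "mmr_hits": [list(h) for h in self.mmr_hits],
        }


def screen_mmr(
    variants: Iterable[SomaticVariant],
    gene_list: frozenset[str] | set[str] = MMR_GENES,
) -> list[tuple[str, str, str]]:
    """Return non-synonymous variants in the configured MMR gene list."""
    return [
        (v.gene, v.protein_change, v.effect)
        for v in variants
        if v.gene in gene_list and v.effect in NONSYNONYMOUS_EFFECTS
    ]


def flag_hypermutation(
    variants: Sequence[SomaticVariant],
    threshold: int = 500,
    capture_mb: float = 30.0,
    gene_list: frozenset[str] | set[str] = MMR_GENES,
) -> HypermutationResult:
    """Flag hypermutation from the coding SNV burden.

    ``is_hypermutated`` is True when the coding SNV count is >= ``threshold``
    (inclusive); ``mut_per_mb`` normalises by the capture footprint.
    """
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    coding_snvs = sum(1 for v in variants if v.coding and v.is_snv)
    sample_ids = {v.sample_id for v in variants}
    return HypermutationResult(
        sample_id=sample_ids.pop() if len(sample_ids) == 1 else "",
        coding_snv_count=coding_snvs,
        mut_per_mb=coding_snvs / capture_mb,
        is_hypermutated=coding_snvs >= threshold,
        mmr_hits=screen_mmr(variants, gene_list),
    )
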