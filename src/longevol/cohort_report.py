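"""Patient- and cohort-level orchestration and reporting.

``run_patient`` executes the full longitudinal pipeline for one patient —
clonality matrix assembly, mixture clustering with BIC model selection,
clone-fate classification, per-timepoint substitution spectra, hypermutation
flagging with MMR screening, and chromothripsis / double-minute detection —
and returns a single serialisable :class:`PatientReport`. ``summarize_cohort``
aggregates per-sample chromothripsis calls (and optionally hypermutation
flags) into per-subtype frequencies with printable percents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Mapping, Sequence

import math

import pandas as pd
import yaml

from . import clonality, evolution, signatures
from .chromothripsis import ChromothripsisCall, ChromothripsisParams, call_chromothripsis
from .io_formats import (
    SampleMeta,
    read_breakpoints,
    read_segments,
    read_somatic_vcf,
)

__all__ = [
    "CohortSummary",
    "PatientReport",
    "format_percent",
    "summarize_cohort",
    "run_patient",
    "load_config",
]

try:
    _VERSION = version("longevol")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


def format_percent(numerator: int, denominator: int) -> str:
    """Render a count ratio as a printable percent.

    Values at or above 10% are rounded to the nearest integer; values below
    10% keep one decimal digit (truncated, so 1/57 prints as "1.7%"); exact
    integers print without a decimal.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must be in [0, denominator]")
    value = 100.0 * numerator / denominator
    if value == int(value):
        return f"{int(value)}%"
    if value >= 10.0:
        return f"{round(value)}%"
    return f"{math.floor(value * 10) / 10:.1f}%"


@dataclass
class CohortSummary:
    """Per-subtype event frequencies (chromothripsis, hypermutation)."""

    per_subtype: dict[str, dict[str, Any]]
    hypermutated: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section, table in (("chromothripsis", self.per_subtype),
                               ("hypermutation", self.hypermutated)):
            for subtype, d in sorted(table.items()):
                rows.append({"event": section, "subtype": subtype, **d})
        return pd.DataFrame(rows)

    def to_jsonable(self) -> dict:
        return {"per_subtype": self.per_subtype, "hypermutated": self.hypermutated}


def _frequency_table(
    positive_samples: set[str], metas: Sequence[SampleMeta]
) -> dict[str, dict[str, Any]]:
    out: dict[str, dict[str, Any]] = {}
    by_subtype: dict[str, list[SampleMeta]] = {}
    for m in metas:
        by_subtype.setdefault(m.subtype, []).append(m)
    for subtype, ms in sorted(by_subtype.items()):
        n = len(ms)
        n_pos = sum(1 for m in ms if m.sample_id in positive_samples)
        out[subtype] = {
            "n_samples": n,
            "n_positive": n_pos,
            "fraction": n_pos / n,
            "percent": format_percent(n_pos, n),
        }
    return out


def summarize_cohort(
    calls_by_sample: Mapping[str, Sequence[ChromothripsisCall]],
    metas: Sequence[SampleMeta],
    hyper_by_sample: Mapping[str, signatures.HypermutationResult] | None = None,
) -> CohortSummary:
    """Aggregate per-sample calls into per-subtype frequencies.

    A sample is positive when it carries at least one chromothripsis call.
    Every sample in ``calls_by_sample`` must have metadata.
    """
    known = {m.sample_id for m in metas}
    missing = sorted(set(calls_by_sample) - known)
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    positives = {s for s, calls in calls_by_sample.items() if len(calls) > 0}
    summary = CohortSummary(per_subtype=_frequency_table(positives, metas))
    if hyper_by_sample is not None:
        extra = sorted(set(hyper_by_sample) - known)
        if extra:
            raise ValueError(f"samples without metadata: {extra}")
        hyper_pos = {s for s, h in hyper_by_sample.items() if h.is_hypermutated}
        summary.hypermutated = _frequency_table(hyper_pos, metas)
    return summary


@dataclass
class PatientReport:
    """Complete longitudinal analysis of one patient, with provenance."""

    patient_id: str
    timepoints: list[int]
    ccf_matrix: clonality.CcfMatrix
    mixture_fit: evolution.MixtureFit
    clusters: list[evolution.CloneCluster]
    spectra: dict[int, signatures.MutationSpectrum]
    hypermutation: dict[int, signatures.HypermutationResult]
    chromothripsis_calls: dict[int, list[ChromothripsisCall]]
    provenance: dict[str, Any]

    def to_jsonable(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timepoints": self.timepoints,
            "ccf_matrix": self.ccf_matrix.to_jsonable(),
            "mixture_fit": self.mixture_fit.to_jsonable(),
            "clusters": [c.to_jsonable() for c in self.clusters],
            "spectra": {
                str(t): s.to_jsonable() for t, s in sorted(self.spectra.items())
            },
            "ct_percent_by_timepoint": {
                str(t): s.ct_percent for t, s in sorted(self.spectra.items())
            },
            "hypermutation": {
                str(t): h.to_jsonable() for t, h in sorted(self.hypermutation.items())
            },
            "chromothripsis_calls": {
                str(t): [c.to_jsonable() for c in calls]
                for t, calls in sorted(self.chromothripsis_calls.items())
            },
            "provenance": self.provenance,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_jsonable() for c in self.clusters])


_DEFAULT_PARAMS: dict[str, Any] = {
    "min_depth": 20,
    "k_max": 6,
    "families": list(evolution.FAMILIES),
    "n_restarts": 10,
    "presence_threshold": 0.10,
    "hyper_threshold": 500,
    "capture_mb": 30.0,
    "default_cn": None,
}


def load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    """Load a patient config from a mapping or a YAML file path."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError("config must be a mapping or a YAML file path")
    return dict(config)


def _read_coverage(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (row["chrom"], int(row["pos"]), row["ref"], row["alt"]): int(row["depth"])
        for _, row in df.iterrows()
    }


def run_patient(config: Mapping[str, Any] | str | Path) -> PatientReport:
    """Run the full longitudinal pipeline for one patient.

    The config names, per timepoint, the sample id, VCF, SEG and (optional)
    BEDPE and coverage-table paths, plus purity/subtype, analysis parameters
    and the seed. A stage failure aborts with the stage name in the error.
    The run is deterministic given the config and seed.
    """
    cfg = load_config(config)
    patient_id = cfg.get("patient_id", "patient")
    seed = int(cfg.get("seed", 0))
    params = {**_DEFAULT_PARAMS, **cfg.get("params", {})}
    ct_params = ChromothripsisParams(**cfg.get("chromothripsis_params", {}))
    entries = cfg.get("timepoints")
    if not entries or len(entries) < 2:
        raise ValueError("config must list >= 2 timepoints")

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    metas: list[SampleMeta] = []
    variants_by_tp: dict[int, list] = {}
    segments_by_tp: dict[int, list] = {}
    breakpoints_by_tp: dict[int, list] = {}
    site_depth: dict = {}
    for e in entries:
        t = int(e["timepoint"])
        sid = e["sample_id"]
        for req in ("vcf", "seg"):
            if req not in e:
                raise ValueError(f"timepoint {t}: missing {req!r} path in config")
            if not Path(e[req]).exists():
                raise FileNotFoundError(
                    f"timepoint {t}: {req} file not found: {e[req]}"
                )
        metas.append(
            SampleMeta(
                sample_id=sid,
                patient_id=patient_id,
                timepoint=t,
                purity=float(e.get("purity", 0.5)),
                subtype=e.get("subtype", "other"),
            )
        )
        variants_by_tp[t] = _stage("read_vcf", read_somatic_vcf, e["vcf"], sid)
        segments_by_tp[t] = _stage("read_segments", read_segments, e["seg"])
        breakpoints_by_tp[t] = (
            _stage("read_breakpoints", read_breakpoints, e["bedpe"], sid)
            if e.get("bedpe")
            else []
        )
        if e.get("coverage"):
            cov = _stage("read_coverage", _read_coverage, e["coverage"])
            for key, depth in cov.items():
                site_depth[(t, key)] = depth

    matrix = _stage(
        "clonality",
        clonality.assemble_ccf_matrix,
        variants_by_tp,
        segments_by_tp,
        metas,
        min_depth=int(params["min_depth"]),
        site_depth=site_depth or None,
        default_cn=params["default_cn"],
    )
    _, rows = matrix.clustering_matrix()
    fit = _stage(
        "clustering",
        evolution.select_model,
        rows,
        k_max=int(params["k_max"]),
        families=tuple(params["families"]),
        seed=seed,
        n_restarts=int(params["n_restarts"]),
    )
    clusters = _stage(
        "classification",
        evolution.classify_clusters,
        fit,
        presence_threshold=float(params["presence_threshold"]),
    )
    spectra = {
        t: _stage("spectrum", signatures.spectrum, variants_by_tp[t])
        for t in sorted(variants_by_tp)
    }
    hyper = {
        t: _stage(
            "hypermutation",
            signatures.flag_hypermutation,
            variants_by_tp[t],
            threshold=int(params["hyper_threshold"]),
            capture_mb=float(params["capture_mb"]),
        )
        for t in sorted(variants_by_tp)
    }
    calls = {
        t: _stage(
            "chromothripsis",
            call_chromothripsis,
            segments_by_tp[t],
            breakpoints_by_tp[t],
            ct_params,
        )
        for t in sorted(segments_by_tp)
    }
    return PatientReport(
        patient_id=patient_id,
        timepoints=sorted(variants_by_tp),
        ccf_matrix=matrix,
        mixture_fit=fit,
        clusters=clusters,
        spectra=spectra,
        hypermutation=hyper,
        chromothripsis_calls=calls,
        provenance={
            "longevol_version": _VERSION,
            "seed": seed,
            "params": {k: v for k, v in params.items()},
            "chromothripsis_params": ct_params.to_jsonable(),
        },
    )
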