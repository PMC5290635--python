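"""Clonality-rate (cancer cell fraction) computation and matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longevol.clonality import (
    ABSENT_CONFIDENT,
    ABSENT_LOWDEPTH,
    OBSERVED,
    assemble_ccf_matrix,
    compute_ccf,
    estimate_multiplicity,
    expected_vaf,
)
from longevol.io_formats import CNSegment, SampleMeta, SomaticVariant


def _variant(vaf, depth=200, chrom="chr1", pos=100, sample="S1"):
    alt = round(vaf * depth)
    return SomaticVariant(sample, chrom, pos, "C", "T", depth - alt, alt)


def _meta(purity, t=1, sample="S1"):
    return SampleMeta(sample, "P1", t, purity, "primary_gbm")


class TestMultiplicity:
    @pytest.mark.parametrize(
        "vaf,purity,cn,expected",
        [
            (0.5, 1.0, 2, 1),  # diploid clonal heterozygote
            (1.0, 1.0, 1, 1),  # LOH
            (0.9, 0.8, 20, 18),  # 0.9*16.4/0.8 = 18.45 -> 18
            (0.0, 0.5, 2, 1),  # floor at 1
            (1.0, 1.0, 2, 2),  # homozygous-in-tumor
        ],
    )
    def test_known_cases(self, vaf, purity, cn, expected):
        assert estimate_multiplicity(vaf, purity, cn) == expected

    def test_half_rounds_away_from_zero(self):
        # implied copies exactly 1.5 at vaf .75, purity 1, cn 2
        assert estimate_multiplicity(0.75, 1.0, 2) == 2

    def test_clipped_to_local_copy_number(self):
        assert estimate_multiplicity(1.0, 0.1, 2) <= 2

    def test_nonpositive_purity_rejected(self):
        with pytest.raises(ValueError):
            estimate_multiplicity(0.5, 0.0, 2)


class TestComputeCcf:
    @pytest.mark.parametrize(
        "vaf,purity,cn,m,expected",
        [
            (0.5, 1.0, 2, 1, 1.0),  # fully clonal diploid het
            (0.1, 0.4, 2, 1, 0.5),  # 0.1*(0.8+1.2)/0.4
            (0.0, 0.7, 2, 1, 0.0),
        ],
    )
    def test_known_values(self, vaf, purity, cn, m, expected):
        rec = compute_ccf(_variant(vaf), _meta(purity), cn, m)
        assert rec.ccf == pytest.approx(expected)
        assert not rec.flagged_inconsistent

    def test_cap_and_inconsistency_flag(self):
        rec = compute_ccf(_variant(0.9), _meta(0.5), 2, 1)  # raw ccf 3.6
        assert rec.ccf == 1.5 and rec.flagged_inconsistent and rec.ccf_raw == pytest.approx(3.6)

    def test_zero_depth_rejected(self):
        v = SomaticVariant("S1", "chr1", 5, "C", "T", 0, 0)
        with pytest.raises(ValueError):
            compute_ccf(v, _meta(0.5), 2, 1)

    @given(
        vaf=st.floats(0.01, 0.49),
        purity=st.floats(0.1, 1.0),
        cn=st.integers(1, 8),
        m=st.integers(1, 4),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_vaf_reconstruction(self, vaf, purity, cn, m):
        """expected_vaf(ccf) inverts compute_ccf whenever no clipping occurs."""
        depth = 10**7
        rec = compute_ccf(_variant(vaf, depth=depth), _meta(purity), cn, m)
        obs_vaf = round(vaf * depth) / depth
        if rec.ccf_raw <= 1.5:
            assert expected_vaf(rec.ccf, purity, cn, m) == pytest.approx(obs_vaf, abs=1e-12)

    def test_monotone_in_vaf(self):
        ccfs = [compute_ccf(_variant(v, depth=1000), _meta(0.6), 3, 1).ccf
                for v in np.linspace(0.01, 0.3, 10)]
        assert all(a < b for a, b in zip(ccfs, ccfs[1:]))

    @given(vaf=st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_pure_diploid_limit_is_twice_vaf(self, vaf):
        depth = 10**6
        rec = compute_ccf(_variant(vaf, depth=depth), _meta(1.0), 2, 1)
        assert rec.ccf == pytest.approx(2 * round(vaf * depth) / depth, abs=1e-12)


class TestAssembleMatrix:
    def _inputs(self, variant_sets, depths=None):
        metas = [_meta(0.5, t, f"S{t}") for t in (1, 2, 3)]
        segs = {
            t: [CNSegment(f"S{t}", "chr1", 1, 10**7, 2.0)] for t in (1, 2, 3)
        }
        variants = {
            t: [_variant(0.25, pos=pos, sample=f"S{t}") for pos in poss]
            for t, poss in variant_sets.items()
        }
        return variants, segs, metas, depths

    def test_union_of_variant_keys(self):
        variants, segs, metas, _ = self._inputs({1: [10, 20], 2: [20, 30], 3: [30]})
        depth = {(t, ("chr1", p, "C", "T")): 100 for t in (1, 2, 3) for p in (10, 20, 30)}
        m = assemble_ccf_matrix(variants, segs, metas, site_depth=depth)
        assert len(m.variant_keys) == 3

    def test_covered_absence_is_confident_zero(self):
        variants, segs, metas, _ = self._inputs({1: [10], 2: [], 3: []})
        depth = {(t, ("chr1", 10, "C", "T")): 100 for t in (2, 3)}
        m = assemble_ccf_matrix(variants, segs, metas, site_depth=depth)
        assert m.mask.tolist() == [[OBSERVED, ABSENT_CONFIDENT, ABSENT_CONFIDENT]]
        assert m.values[0, 1] == 0.0 and m.values[0, 0] == pytest.approx(1.0)
        assert m.clustering_rows.all()

    def test_uncovered_absence_excluded_from_clustering(self):
        variants, segs, metas, _ = self._inputs({1: [10, 20], 2: [20], 3: [20]})
        depth = {(t, ("chr1", 20, "C", "T")): 100 for t in (1, 2, 3)}
        depth[(2, ("chr1", 10, "C", "T"))] = 5  # below min_depth
        depth[(3, ("chr1", 10, "C", "T"))] = 100
        m = assemble_ccf_matrix(variants, segs, metas, site_depth=depth)
        i = m.variant_keys.index(("chr1", 10, "C", "T"))
        assert m.mask[i, 1] == ABSENT_LOWDEPTH
        keys, rows = m.clustering_matrix()
        assert ("chr1", 10, "C", "T") not in keys and rows.shape[0] == 1

    def test_duplicate_key_rejected(self):
        variants, segs, metas, _ = self._inputs({1: [10, 10], 2: [10], 3: [10]})
        with pytest.raises(ValueError, match="duplicate"):
            assemble_ccf_matrix(variants, segs, metas)

    def test_missing_segment_needs_default_cn(self):
        variants, segs, metas, _ = self._inputs({1: [10], 2: [10], 3: [10]})
        segs[1] = []
        with pytest.raises(ValueError, match="segment"):
            assemble_ccf_matrix(variants, segs, metas)
        m = assemble_ccf_matrix(variants, segs, metas, default_cn=2.0)
        assert m.values[0, 0] == pytest.approx(1.0)


def test_simulated_patient_clone_level_accuracy(patient, ccf_matrix):
    """Clonality recovered from binomial reads matches planted clone
    trajectories to < 0.05 mean absolute error at the clone level."""
    truth = patient.truth.set_index(["chrom", "pos", "ref", "alt"])
    keys, rows = ccf_matrix.clustering_matrix()
    errs = []
    for clone in patient.clones:
        sel = [
            i for i, k in enumerate(keys)
            if truth.loc[k, "clone_id"] == clone.clone_id
        ]
        est = rows[sel].mean(axis=0)
        errs.append(np.abs(est - np.array(clone.ccf_by_timepoint)))
    assert np.mean(errs) < 0.05
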