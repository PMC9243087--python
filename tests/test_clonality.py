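"""CCF equations, clonality calls, and mutual-exclusivity analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonopanel import (
    CopySegment,
    HotspotGroup,
    assign_local_cn,
    build_exclusivity_matrix,
    classify_clonality,
    compute_ccf,
    exclusivity_permutation_test,
)

GROUPS = (
    HotspotGroup("KRAS", frozenset({("KRAS", "G12"), ("KRAS", "Q61")})),
    HotspotGroup("NRAS", frozenset({("NRAS", "Q61")})),
    HotspotGroup("BRAF", frozenset({("BRAF", "V600")})),
)


def ccf_row(sample, gene, codon, ccf):
    return {
        "sample": sample, "contig": "chr1", "pos": 1, "ref": "A", "alt": "T",
        "gene": gene, "codon": codon, "vaf": 0.2, "purity": 0.6, "local_cn": 2.0,
        "u": ccf, "m": 1.0, "ccf": ccf, "clonal": ccf >= 0.8,
    }


class TestComputeCCF:
    # direct evaluations of u = ((1-p)*2 + p*cn)/p * VAF, m = u if u>=1 else 1
    @pytest.mark.parametrize(
        "vaf,purity,cn,u,m,ccf",
        [
            (0.3, 1.0, 2, 0.6, 1.0, 0.6),
            (0.25, 0.5, 2, 1.0, 1.0, 1.0),
            (0.1, 0.6, 3, 13 / 30, 1.0, 13 / 30),
            (0.5, 0.5, 4, 3.0, 3.0, 1.0),
            (0.0, 0.7, 2, 0.0, 1.0, 0.0),
        ],
    )
    def test_direct_evaluation(self, vaf, purity, cn, u, m, ccf):
        a = compute_ccf(vaf, purity, cn)
        assert a.u == pytest.approx(u, abs=1e-12)
        assert a.m == pytest.approx(m, abs=1e-12)
        assert a.ccf == pytest.approx(ccf, abs=1e-12)

    def test_rounded_multiplicity_mode(self):
        a = compute_ccf(0.5, 0.5, 4, multiplicity_mode="rounded")
        assert a.m == 3.0 and a.ccf == pytest.approx(1.0)
        b = compute_ccf(0.35, 0.5, 4, multiplicity_mode="rounded")  # u = 2.1
        assert b.m == 2.0 and b.ccf == pytest.approx(1.0)  # capped at 1

    def test_error_and_inconsistent_cases(self):
        with pytest.raises(ValueError):
            compute_ccf(0.3, 0.0, 2)
        with pytest.raises(ValueError):
            compute_ccf(1.2, 0.5, 2)
        assert compute_ccf(0.3, 0.5, 0.0) is None  # reads on a zero-copy segment
        assert compute_ccf(0.0, 0.5, 0.0) is not None

    def test_pathological_u_is_capped_and_flagged(self):
        a = compute_ccf(1.0, 1e-3, 100)
        assert a.capped and a.u == 1e3

    @settings(max_examples=300, deadline=None)
    @given(
        st.floats(0.0, 1.0), st.floats(0.01, 1.0), st.floats(0.5, 8.0)
    )
    def test_identity_u_equals_ccf_times_m(self, vaf, purity, cn):
        a = compute_ccf(vaf, purity, cn)
        assert abs(a.ccf * a.m - a.u) < 1e-9

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.01, 1.0), st.floats(0.5, 6.0), st.floats(0, 0.5), st.floats(0, 0.5))
    def test_ccf_monotone_in_vaf(self, purity, cn, v1, dv):
        lo = compute_ccf(v1, purity, cn)
        hi = compute_ccf(min(1.0, v1 + dv), purity, cn)
        assert hi.ccf >= lo.ccf - 1e-12

    def test_pure_diploid_closed_form(self):
        for vaf in np.linspace(0, 1, 21):
            a = compute_ccf(float(vaf), 1.0, 2)
            assert a.ccf == pytest.approx(min(2 * vaf, 1.0), abs=1e-12)


class TestClonalityCall:
    def test_boundary(self):
        assert classify_clonality(0.80) == "clonal"
        assert classify_clonality(0.79) == "subclonal"
        assert classify_clonality(1.0) == "clonal"

    def test_range_check(self):
        with pytest.raises(ValueError):
            classify_clonality(1.2)


class TestLocalCN:
    SEGS = [
        CopySegment("S", "chr1", 0, 1000, 3.0),
        CopySegment("S", "chr1", 1000, 2000, 2.0),
    ]

    def test_inside_segment(self):
        assert assign_local_cn("chr1", 500, self.SEGS) == 3.0

    def test_halfopen_boundary_belongs_to_next_segment(self):
        assert assign_local_cn("chr1", 1001, self.SEGS) == 2.0  # 0-based 1000
        assert assign_local_cn("chr1", 1000, self.SEGS) == 3.0  # 0-based 999

    def test_gap_defaults_to_diploid(self):
        assert assign_local_cn("chr1", 5000, self.SEGS) == 2.0

    def test_overlapping_segments_rejected(self):
        bad = [CopySegment("S", "chr1", 0, 100, 2.0), CopySegment("S", "chr1", 50, 150, 3.0)]
        with pytest.raises(ValueError):
            assign_local_cn("chr1", 60, bad)


class TestExclusivityMatrix:
    def test_min_ccf_excludes_low_variants(self):
        table = pd.DataFrame([ccf_row("P1", "KRAS", "G12", 0.04)])
        matrix, _ = build_exclusivity_matrix(table, GROUPS, min_ccf=0.05)
        assert matrix.empty

    def test_clonal_cooccurrence_counted(self):
        table = pd.DataFrame(
            [ccf_row("P1", "KRAS", "G12", 0.9), ccf_row("P1", "NRAS", "Q61", 0.85)]
        )
        matrix, pairs = build_exclusivity_matrix(table, GROUPS)
        assert matrix.loc["P1", "KRAS"] == "clonal"
        assert int(pairs["both_clonal"].sum()) == 1

    def test_subclonal_cooccurrence_allowed_cell(self):
        table = pd.DataFrame(
            [ccf_row("P1", "KRAS", "Q61", 0.3), ccf_row("P1", "BRAF", "V600", 0.2)]
        )
        _, pairs = build_exclusivity_matrix(table, GROUPS)
        assert int(pairs["both_clonal"].sum()) == 0
        assert int(pairs["both_subclonal"].sum()) == 1

    def test_non_member_variants_do_not_qualify_patients(self):
        table = pd.DataFrame([ccf_row("P1", "TP53", "R175", 0.9)])
        matrix, _ = build_exclusivity_matrix(table, GROUPS)
        assert "P1" not in matrix.index

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            build_exclusivity_matrix(pd.DataFrame([ccf_row("P1", "KRAS", "G12", 0.9)]), ())


class TestPermutationTest:
    def _matrix(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.choice(["absent", "subclonal", "clonal"], size=(n, 3), p=[0.6, 0.2, 0.2])
        return pd.DataFrame(data, columns=["KRAS", "NRAS", "BRAF"],
                            index=[f"P{i}" for i in range(n)])

    def test_reproducible_with_seed(self):
        m = self._matrix()
        p1 = exclusivity_permutation_test(m, 200, seed=3)
        p2 = exclusivity_permutation_test(m, 200, seed=3)
        assert p1 == p2

    def test_exclusive_matrix_gives_small_p(self):
        # many clonal calls, never co-occurring
        rows = []
        for i in range(60):
            entry = {"KRAS": "absent", "NRAS": "absent", "BRAF": "absent"}
            entry[["KRAS", "NRAS", "BRAF"][i % 3]] = "clonal"
            rows.append(entry)
        m = pd.DataFrame(rows, index=[f"P{i}" for i in range(60)])
        p = exclusivity_permutation_test(m, 500, seed=1)
        assert p < 0.05

    def test_degenerate_matrix_returns_none(self):
        m = self._matrix().replace("clonal", "subclonal")
        assert exclusivity_permutation_test(m, 200, seed=0) is None

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            exclusivity_permutation_test(self._matrix(), 0, seed=0)
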