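"""APOBEC motif tabulation, enrichment test, rates and hypermutation."""

import numpy as np
import pytest

from clonopanel import (
    MotifCountTable,
    VariantCall,
    apobec_enrichment_test,
    classify_apobec,
    classify_hypermutation,
    mutation_rate,
    tabulate_motif_counts,
)
from clonopanel.panel import PanelResources
from clonopanel.signature import count_motif_opportunities


def snv(resources, contig, pos, alt, sample="S1"):
    ref = resources.base_at(contig, pos)
    return VariantCall(sample=sample, contig=contig, pos=pos, ref=ref, alt=alt,
                       alt_fwd=30, alt_rev=30, depth=300)


def find_context(reference, pattern, occurrence=0):
    """1-based position of the middle base of the n-th pattern occurrence."""
    start, found = -1, -1
    while True:
        start = reference.find(pattern, start + 1)
        if start < 0:
            raise AssertionError(f"pattern {pattern} not in reference")
        found += 1
        if found == occurrence:
            return start + 2


class TestMotifTabulation:
    def test_c_to_t_at_tca_counts_in_motif(self, tiny_resources):
        ref = tiny_resources.reference["chrT"]
        pos = find_context(ref, "TCA")
        t = tabulate_motif_counts([snv(tiny_resources, "chrT", pos, "T")], tiny_resources)
        assert (t.mut_in, t.mut_out) == (1, 0)

    def test_c_to_a_not_counted_at_all(self, tiny_resources):
        ref = tiny_resources.reference["chrT"]
        pos = find_context(ref, "TCA")
        t = tabulate_motif_counts([snv(tiny_resources, "chrT", pos, "A")], tiny_resources)
        assert (t.mut_in, t.mut_out) == (0, 0)

    def test_g_to_a_at_tga_counts_in_motif(self, tiny_resources):
        # TGA is the reverse complement of TCA: the motif on the other strand
        ref = tiny_resources.reference["chrT"]
        pos = find_context(ref, "TGA")
        t = tabulate_motif_counts([snv(tiny_resources, "chrT", pos, "A")], tiny_resources)
        assert (t.mut_in, t.mut_out) == (1, 0)

    def test_c_to_g_outside_motif_counts_out(self, tiny_resources):
        ref = tiny_resources.reference["chrT"]
        pos = find_context(ref, "GCA")  # preceding base G: not TCW
        t = tabulate_motif_counts([snv(tiny_resources, "chrT", pos, "G")], tiny_resources)
        assert (t.mut_in, t.mut_out) == (0, 1)

    def test_reference_mismatch_raises(self, tiny_resources):
        pos = find_context(tiny_resources.reference["chrT"], "TCA")
        bad = VariantCall(sample="S1", contig="chrT", pos=pos, ref="G", alt="A",
                          alt_fwd=5, alt_rev=5, depth=100)
        with pytest.raises(ValueError):
            tabulate_motif_counts([bad], tiny_resources)

    def test_opportunities_partition_cg_bases(self, tiny_resources):
        ctx_in, ctx_out = count_motif_opportunities(tiny_resources)
        seq = tiny_resources.reference["chrT"][0:59]
        assert ctx_in + ctx_out == seq.count("C") + seq.count("G")
        assert ctx_in > 0

    def test_strand_symmetry_of_counts(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        fwd = PanelResources(targets={"c": [(0, 400)]}, reference={"c": seq})
        rev = PanelResources(targets={"c": [(0, 400)]}, reference={"c": rc})
        assert count_motif_opportunities(fwd) == count_motif_opportunities(rev)
        # a batch of deamination-class SNVs mapped to the reverse strand
        positions = [p for p in range(2, 399) if seq[p - 1] in "CG"][:25]
        calls_fwd, calls_rev = [], []
        for p in positions:
            ref = seq[p - 1]
            alt = "T" if ref == "C" else "A"
            calls_fwd.append(snv(fwd, "c", p, alt))
            p_rev = 400 - p + 1
            ref_rc = rc[p_rev - 1]
            alt_rc = alt.translate(comp)
            calls_rev.append(snv(rev, "c", p_rev, alt_rc))
        t1 = tabulate_motif_counts(calls_fwd, fwd)
        t2 = tabulate_motif_counts(calls_rev, rev)
        assert (t1.mut_in, t1.mut_out) == (t2.mut_in, t2.mut_out)


class TestEnrichmentTest:
    def test_exhaustive_enumeration_examples(self):
        # [[2,0],[0,2]]: P(X>=2) with N=4, margins 2/2 -> 1/6
        assert apobec_enrichment_test(MotifCountTable("S", 2, 0, 0, 2)) == pytest.approx(1 / 6)
        # [[5,0],[0,5]]: 1/C(10,5) = 1/252
        assert apobec_enrichment_test(MotifCountTable("S", 5, 0, 0, 5)) == pytest.approx(1 / 252)
        # P(X >= 0) = 1
        assert apobec_enrichment_test(MotifCountTable("S", 0, 5, 10, 50)) == 1.0

    def test_all_zero_table_convention(self):
        assert apobec_enrichment_test(MotifCountTable("S", 0, 0, 100, 900)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MotifCountTable("S", -1, 0, 0, 0)


class TestClassification:
    def test_fdr_cutoff_is_strict(self):
        calls = classify_apobec(["a", "b", "c"], [0.001, 0.02, 0.9])
        by = {c.sample: c for c in calls}
        assert by["a"].enriched  # q = 0.003
        assert by["b"].q == pytest.approx(0.03)
        assert not by["c"].enriched

    def test_q_exactly_at_cutoff_not_enriched(self):
        from clonopanel.signature import ApobecCall
        assert not ApobecCall("s", p=0.05, q=0.05).enriched
        assert ApobecCall("s", p=0.049, q=0.049).enriched

    def test_mutation_rate(self):
        assert mutation_rate(100, 10.0) == 10.0
        assert mutation_rate(0, 5.0) == 0.0
        assert mutation_rate(50, 5.0) == 10.0
        with pytest.raises(ValueError):
            mutation_rate(10, 0.0)

    @pytest.mark.parametrize(
        "rate,enriched,hyper,mechanism",
        [
            (25.0, True, True, "APOBEC"),
            (25.0, False, True, "undefined"),
            (2.0, True, False, "none"),
        ],
    )
    def test_hypermutation_classes(self, rate, enriched, hyper, mechanism):
        cls = classify_hypermutation("s", rate, enriched, threshold=10.0)
        assert (cls.hypermutated, cls.mechanism) == (hyper, mechanism)
        with pytest.raises(ValueError):
            classify_hypermutation("s", rate, enriched, threshold=0)
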