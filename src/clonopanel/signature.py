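"""APOBEC motif enrichment, mutation rate, and hypermutation classes.

APOBEC cytidine deaminases mutate cytosines in a TpCpW context (W = A
or T), producing C>T and C>G substitutions at TCW, or equivalently G>A
and G>C at the reverse-complement WGA.  A panel does not carry enough
mutations for de novo signature extraction, but per-sample enrichment
is testable: tabulate mutations and sequence opportunities in and out
of the motif and apply a one-sided Fisher exact test, controlling the
cohort-wide FDR by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_exact_2x2
from .panel import PanelResources

APOBEC_Q_CUTOFF = 0.05
DEFAULT_HYPERMUTATION_RATE = 10.0  # point mutations per Mb; assumption, configurable

#: substitutions attributable to cytidine deamination, by reference base
_C_ALTS = {"T", "G"}
_G_ALTS = {"A", "C"}
_W = {"A", "T"}


@dataclass(frozen=True)
class MotifCountTable:
    """Per-sample 2x2 tabulation: mutations and opportunities in/out of TCW."""

    sample: str
    mut_in: int
    mut_out: int
    ctx_in: int
    ctx_out: int

    def __post_init__(self):
        if min(self.mut_in, self.mut_out, self.ctx_in, self.ctx_out) < 0:
            raise ValueError("motif counts must be non-negative")

    @property
    def table(self):
        return [[self.mut_in, self.mut_out], [self.ctx_in, self.ctx_out]]


@dataclass(frozen=True)
class ApobecCall:
    sample: str
    p: float
    q: float

    @property
    def enriched(self) -> bool:
        return self.q < APOBEC_Q_CUTOFF


@dataclass(frozen=True)
class RateClassification:
    sample: str
    rate_per_mb: float
    hypermutated: bool
    mechanism: str  # none / APOBEC / undefined


def count_motif_opportunities(resources: PanelResources) -> Tuple[int, int]:
    """Count reference C/G bases in targets, split by motif membership.

    Each C is an opportunity (in-motif when its context is TCW) and each
    G likewise on the reverse orientation (WGA).  Bases at contig edges
    with no full trinucleotide count as out-of-motif.
    """
    ctx_in = ctx_out = 0
    for contig, intervals in resources.targets.items():
        seq = np.frombuffer(resources.reference[contig].encode(), dtype="S1")
        is_c = seq == b"C"
        is_g = seq == b"G"
        prev = np.empty_like(seq)
        prev[1:] = seq[:-1]
        prev[0] = b"N"
        nxt = np.empty_like(seq)
        nxt[:-1] = seq[1:]
        nxt[-1] = b"N"
        w_next = (nxt == b"A") | (nxt == b"T")
        w_prev = (prev == b"A") | (prev == b"T")
        tcw = is_c & (prev == b"T") & w_next
        wga = is_g & (nxt == b"A") & w_prev
        mask = np.zeros(len(seq), dtype=bool)
        for s, e in intervals:
            mask[s:e] = True
        in_motif = ((tcw | wga) & mask).sum()
        total_cg = ((is_c | is_g) & mask).sum()
        ctx_in += int(in_motif)
        ctx_out += int(total_cg - in_motif)
    return ctx_in, ctx_out


def _is_apobec_class(ref: str, alt: str) -> bool:
    return (ref == "C" and alt in _C_ALTS) or (ref == "G" and alt in _G_ALTS)


def _in_motif(resources: PanelResources, contig: str, pos: int, ref: str) -> bool:
    tri = resources.trinucleotide(contig, pos)
    if tri is None:
        return False
    if ref == "C":
        return tri[0] == "T" and tri[2] in _W
    return tri[2] == "A" and tri[0] in _W  # ref == "G"


def tabulate_motif_counts(
    snvs: Sequence,
    resources: PanelResources,
    sample: Optional[str] = None,
    opportunities: Optional[Tuple[int, int]] = None,
) -> MotifCountTable:
    """Build the per-sample motif count table from somatic SNVs.

    Only C>T/C>G (and reverse-orientation G>A/G>C) substitutions inside
    the panel targets are counted as mutations; motif membership is
    decided from the reference trinucleotide.  ``opportunities`` lets
    callers reuse the (sample-independent) context counts.
    """
    if opportunities is None:
        opportunities = count_motif_opportunities(resources)
    ctx_in, ctx_out = opportunities
    mut_in = mut_out = 0
    sample_id = sample or (snvs[0].sample if snvs else "")
    for v in snvs:
        if not v.is_snv:
            continue
        if not resources.in_targets(v.contig, v.pos):
            continue
        ref = resources.base_at(v.contig, v.pos)
        if ref != v.ref:
            raise ValueError(
                f"reference mismatch at {v.contig}:{v.pos}: call says {v.ref}, reference has {ref}"
            )
        if not _is_apobec_class(v.ref, v.alt):
            continue
        if _in_motif(resources, v.contig, v.pos, v.ref):
            mut_in += 1
        else:
            mut_out += 1
    return MotifCountTable(sample=sample_id, mut_in=mut_in, mut_out=mut_out,
                           ctx_in=ctx_in, ctx_out=ctx_out)


def apobec_enrichment_test(table: MotifCountTable) -> float:
    """One-sided (enrichment-direction) Fisher exact p on the 2x2 table."""
    if table.mut_in == 0 and table.mut_out == 0:
        return 1.0
    return fisher_exact_2x2(table.table, alternative="greater")


def classify_apobec(samples: Sequence[str], pvalues: Sequence[float]) -> list:
    """Cohort-wide BH correction; enriched iff FDR < 0.05 (strict)."""
    q = bh_adjust(pvalues)
    return [ApobecCall(sample=s, p=float(p), q=float(qv))
            for s, p, qv in zip(samples, pvalues, q)]


def mutation_rate(n_point_mutations: int, footprint_mb: float) -> float:
    """Point mutations per megabase of panel footprint."""
    if footprint_mb <= 0:
        raise ValueError(f"panel footprint must be positive, got {footprint_mb}")
    return n_point_mutations / footprint_mb


def classify_hypermutation(
    sample: str,
    rate_per_mb: float,
    apobec_enriched: bool,
    threshold: float = DEFAULT_HYPERMUTATION_RATE,
) -> RateClassification:
    if threshold <= 0:
        raise ValueError(f"hypermutation threshold must be positive, got {threshold}")
    hyper = rate_per_mb >= threshold
    if not hyper:
        mechanism = "none"
    elif apobec_enriched:
        mechanism = "APOBEC"
    else:
        mechanism = "undefined"
    return RateClassification(sample=sample, rate_per_mb=rate_per_mb,
                              hypermutated=hyper, mechanism=mechanism)


def signature_report(
    somatic_by_sample: Mapping[str, Sequence],
    resources: PanelResources,
    hypermutation_threshold: float = DEFAULT_HYPERMUTATION_RATE,
) -> pd.DataFrame:
    """Full per-sample signature report for a cohort.

    Columns: motif counts, Fisher p, BH q, enriched flag, point-mutation
    rate per Mb, hypermutation flag and mechanism.
    """
    opportunities = count_motif_opportunities(resources)
    samples = sorted(somatic_by_sample)
    tables = [
        tabulate_motif_counts(
            [c for c in somatic_by_sample[s] if c.is_snv],
            resources, sample=s, opportunities=opportunities,
        )
        for s in samples
    ]
    pvals = [apobec_enrichment_test(t) for t in tables]
    calls = classify_apobec(samples, pvals)
    rows = []
    for s, t, call in zip(samples, tables, calls):
        n_point = sum(1 for c in somatic_by_sample[s] if c.is_snv)
        rate = mutation_rate(n_point, resources.footprint_mb)
        cls = classify_hypermutation(s, rate, call.enriched, hypermutation_threshold)
        rows.append(
            {
                "sample": s, "mut_in": t.mut_in, "mut_out": t.mut_out,
                "ctx_in": t.ctx_in, "ctx_out": t.ctx_out,
                "p": call.p, "q": call.q, "enriched": call.enriched,
                "rate_per_mb": rate, "hypermutated": cls.hypermutated,
                "mechanism": cls.mechanism,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "mut_in", "mut_out", "ctx_in", "ctx_out", "p", "q",
                 "enriched", "rate_per_mb", "hypermutated", "mechanism"],
    )
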