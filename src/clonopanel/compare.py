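"""Cohort-level comparison and resistance screening.

Gene-level mutation frequencies between two cohorts (e.g. relapsed vs
newly diagnosed) are compared by Fisher exact tests on per-gene patient
counts, with BH correction across genes; focal deletions (< 20 Mb
segments below diploid copy) are compared the same way.  Driver genes
are nominated by consensus over per-tool FDR tables, and patients are
screened against an editable catalog of drug-resistance alterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from ._stats import bh_adjust, fisher_exact_2x2, rank_sum_test
from .clonality import CopySegment
from .variants import NONSYNONYMOUS_TERMS, CONSEQUENCE_TERMS

logger = logging.getLogger(__name__)

FOCAL_DELETION_MAX_LEN = 20_000_000  # focal means segment < 20 Mb

#: closed vocabulary of resistance-qualifying alteration types
ALTERATION_TYPES = frozenset(
    {
        "truncating",
        "missense_in_domain",
        "homozygous_deletion",
        "hemizygous_deletion",
        "fusion",
        "exon_skipping",
    }
)


@dataclass(frozen=True)
class ComparisonResult:
    gene: str
    a: int  # mutated patients, cohort A
    total_a: int
    b: int  # mutated patients, cohort B
    total_b: int
    odds_ratio: float
    p: float


@dataclass(frozen=True)
class Alteration:
    """One patient-level alteration record for resistance screening."""

    patient: str
    gene: str
    alteration_type: str

    def __post_init__(self):
        if self.alteration_type not in ALTERATION_TYPES:
            raise ValueError(
                f"unknown alteration type {self.alteration_type!r}; "
                f"expected one of {sorted(ALTERATION_TYPES)}"
            )


def _odds_ratio(a: int, na: int, b: int, nb: int) -> float:
    num = a * (nb - b)
    den = b * (na - a)
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def gene_frequency_test(
    gene: str, a: int, total_a: int, b: int, total_b: int, sided: str = "two"
) -> ComparisonResult:
    """Fisher exact comparison of per-gene mutated-patient counts.

    ``sided`` is 'two' for the landscape scan or 'one-greater' for
    targeted enrichment claims (cohort A enriched).  Counting upstream
    must already have applied the VAF >= 5% inclusion rule.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("cohort totals must be positive")
    if not (0 <= a <= total_a and 0 <= b <= total_b):
        raise ValueError("mutated counts cannot exceed cohort totals")
    table = [[a, total_a - a], [b, total_b - b]]
    alternative = {"two": "two-sided", "one-greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'two' or 'one-greater', got {sided!r}")
    p = fisher_exact_2x2(table, alternative=alternative)
    return ComparisonResult(
        gene=gene, a=a, total_a=total_a, b=b, total_b=total_b,
        odds_ratio=_odds_ratio(a, total_a, b, total_b), p=p,
    )


def count_mutated_patients(
    calls_by_patient: Mapping[str, Sequence],
    gene: str,
    min_vaf: float = 0.05,
) -> int:
    """Patients with >= 1 qualifying non-synonymous call in the gene.

    Each patient counts at most once; a call qualifies if its VAF is at
    least ``min_vaf`` and its consequence is non-synonymous.  Unknown
    consequence terms raise, naming the term.
    """
    n = 0
    for patient, calls in calls_by_patient.items():
        for call in calls:
            if call.consequence not in CONSEQUENCE_TERMS:
                raise ValueError(f"unknown consequence term {call.consequence!r}")
            if (
                call.gene == gene
                and call.consequence in NONSYNONYMOUS_TERMS
                and call.vaf >= min_vaf
            ):
                n += 1
                break
    return n


def compare_cohorts(
    calls_a: Mapping[str, Sequence],
    calls_b: Mapping[str, Sequence],
    genes: Iterable[str],
    min_vaf: float = 0.05,
    sided: str = "two",
) -> pd.DataFrame:
    """Gene-by-gene frequency comparison with BH correction across genes."""
    results = [
        gene_frequency_test(
            g,
            count_mutated_patients(calls_a, g, min_vaf), len(calls_a),
            count_mutated_patients(calls_b, g, min_vaf), len(calls_b),
            sided=sided,
        )
        for g in genes
    ]
    df = pd.DataFrame(
        [
            {"gene": r.gene, "a": r.a, "A": r.total_a, "b": r.b, "B": r.total_b,
             "OR": r.odds_ratio, "p": r.p}
            for r in results
        ],
        columns=["gene", "a", "A", "b", "B", "OR", "p"],
    )
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def focal_deletion_test(
    segments_a: Mapping[str, Sequence[CopySegment]],
    segments_b: Mapping[str, Sequence[CopySegment]],
    gene_interval: Tuple[str, int, int],
    gene: str = "",
    max_len: int = FOCAL_DELETION_MAX_LEN,
) -> ComparisonResult:
    """Compare focal-deletion frequency at a gene between cohorts.

    A patient counts if any segment with total CN < 2 (hemizygous or
    homozygous) shorter than ``max_len`` overlaps the half-open gene
    interval by at least one base.
    """
    contig, start, end = gene_interval
    if end <= start:
        raise ValueError(f"gene interval must be non-empty, got {gene_interval}")

    def count(segmap: Mapping[str, Sequence[CopySegment]]) -> int:
        n = 0
        for patient, segs in segmap.items():
            for s in segs:
                if (
                    s.contig == contig
                    and s.total_cn < 2
                    and s.length < max_len
                    and s.start < end
                    and s.end > start
                ):
                    n += 1
                    break
        return n

    a, b = count(segments_a), count(segments_b)
    na, nb = len(segments_a), len(segments_b)
    p = fisher_exact_2x2([[a, na - a], [b, nb - b]], alternative="two-sided")
    return ComparisonResult(gene=gene, a=a, total_a=na, b=b, total_b=nb,
                           odds_ratio=_odds_ratio(a, na, b, nb), p=p)


def consensus_drivers(
    tool_q_tables: Mapping[str, Mapping[str, float]],
    q_max: float = 0.2,
    min_tools: int = 2,
) -> Set[str]:
    """Genes significant (q < q_max) in at least ``min_tools`` tools."""
    if len(tool_q_tables) < 2:
        raise ValueError("driver consensus needs at least two tool tables")
    counts: Dict[str, int] = {}
    for table in tool_q_tables.values():
        for gene, q in table.items():
            if q < q_max:
                counts[gene] = counts.get(gene, 0) + 1
    return {g for g, n in counts.items() if n >= min_tools}


# -- drug-resistance screening ------------------------------------------

#: default catalog: drug class -> {gene -> qualifying alteration types}
DEFAULT_RESISTANCE_CATALOG: Dict[str, Dict[str, Set[str]]] = {
    "iMiD": {
        "CRBN": {"truncating", "missense_in_domain", "homozygous_deletion", "hemizygous_deletion"},
        "CUL4B": {"truncating", "missense_in_domain", "homozygous_deletion", "hemizygous_deletion"},
    },
    "glucocorticoid": {
        "NR3C1": {"truncating", "missense_in_domain", "homozygous_deletion", "hemizygous_deletion"},
    },
    "anti-CD38": {
        "CD38": {"truncating", "homozygous_deletion", "fusion", "exon_skipping"},
    },
}


def load_resistance_catalog(path) -> Dict[str, Dict[str, Set[str]]]:
    """Read an editable 3-column TSV catalog (gene, drug_class, alteration_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    catalog: Dict[str, Dict[str, Set[str]]] = {}
    for _, row in df.iterrows():
        if row["alteration_type"] not in ALTERATION_TYPES:
            raise ValueError(f"unknown alteration type {row['alteration_type']!r} in catalog")
        catalog.setdefault(row["drug_class"], {}).setdefault(row["gene"], set()).add(
            row["alteration_type"]
        )
    return catalog


def annotate_resistance(
    alterations: Sequence[Alteration],
    patients: Sequence[str],
    catalog: Optional[Mapping[str, Mapping[str, Set[str]]]] = None,
    panel_genes: Optional[Set[str]] = None,
) -> Tuple[pd.DataFrame, float]:
    """Flag each patient per drug class and report the cohort fraction.

    A patient is flagged for a class iff at least one alteration matches
    a catalog gene of that class with a qualifying type.  Idempotent and
    order-independent over the alteration list.
    """
    catalog = catalog if catalog is not None else DEFAULT_RESISTANCE_CATALOG
    if panel_genes is not None:
        for cls, genes in catalog.items():
            for gene in genes:
                if gene not in panel_genes:
                    logger.warning("catalog gene %s (%s) is not on the panel", gene, cls)
    classes = sorted(catalog)
    flags = {p: {cls: False for cls in classes} for p in patients}
    qualifying: Dict[str, List[str]] = {p: [] for p in patients}
    for alt in alterations:
        if alt.patient not in flags:
            continue
        for cls in classes:
            types = catalog[cls].get(alt.gene)
            if types and alt.alteration_type in types:
                flags[alt.patient][cls] = True
                tag = f"{alt.gene}:{alt.alteration_type}"
                if tag not in qualifying[alt.patient]:
                    qualifying[alt.patient].append(tag)
    rows = [
        {"patient": p, **flags[p], "qualifying": ";".join(sorted(qualifying[p]))}
        for p in patients
    ]
    df = pd.DataFrame(rows, columns=["patient"] + classes + ["qualifying"])
    any_flag = df[classes].any(axis=1) if len(df) else pd.Series(dtype=bool)
    fraction = float(any_flag.mean()) if len(df) else 0.0
    return df, fraction


def expression_by_mutation_test(
    expression: Mapping[str, float],
    mutated_samples: Iterable[str],
    alternative: str = "less",
) -> float:
    """Rank-sum test of expression in mutated vs unmutated samples.

    ``alternative='less'`` tests whether mutated samples express lower
    (e.g. CD38 loss-of-function vs CD38 expression).
    """
    mutated = set(mutated_samples)
    x = [v for s, v in expression.items() if s in mutated]
    y = [v for s, v in expression.items() if s not in mutated]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two samples")
    return rank_sum_test(x, y, alternative=alternative)
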