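"""Synthetic tumor/normal panel cohort generator with known ground truth.

The generator emulates the statistical structure the downstream stages
assume, at the read-count level (no reads are simulated):

* a toy reference and exon-style target panel with named genes and
  white-listed oncogenic hotspot codons;
* per-patient purity, a clone tree flattened to a trunk (CCF 1) plus
  subclones with CCFs on a grid, and total-copy-number segments;
* binomial sampling of alt/total read counts at panel-like depth, with
  the expected VAF implied by purity, local copy number and clone CCF;
* leakage of tumor content into the matched normal (circulating tumor
  cells) at a per-patient contamination fraction, including blood-only
  variants absent from the biopsy;
* common population polymorphisms, recurrent strand- or
  orientation-biased sequencing artifacts shared across samples, and a
  tunable APOBEC process concentrated at TCW motifs.

Identical configuration and seed reproduce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .clonality import CopySegment
from .panel import PanelResources, PoolEntry
from .variants import VariantCall

BASES = ("A", "C", "G", "T")

#: panel genes with special roles (hotspot codons, resistance catalog)
NAMED_GENES = (
    "KRAS", "NRAS", "BRAF", "TP53", "PIK3CA", "CRBN", "CUL4B", "NR3C1",
    "CD38", "IL6ST", "LZTR1", "TRAF3", "RB1", "DIS3", "FAM46C",
)

#: hotspot codons laid out inside each gene's first exon (offset in bases)
HOTSPOT_CODONS = {
    "KRAS": ("G12", "G13", "Q61"),
    "NRAS": ("G12", "G13", "Q61"),
    "BRAF": ("V600",),
    "TP53": ("R175", "R248", "R273"),
    "PIK3CA": ("E545", "H1047"),
}

_SNV_CONSEQUENCES = ("missense", "synonymous", "stop_gain", "splice_site", "start_loss")
_SNV_CONSEQ_W = (0.62, 0.2, 0.12, 0.05, 0.01)
_INDEL_CONSEQUENCES = ("frameshift", "inframe_indel")
_INDEL_CONSEQ_W = (0.7, 0.3)

_CN_CHOICES = (1, 2, 3, 4)
_CN_WEIGHTS = (0.10, 0.70, 0.15, 0.05)

_GERMLINE_MAF_GRID = (0.001, 0.01, 0.1)


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Depth defaults mirror panel sequencing at several-hundred-fold
    coverage (tumor ~600x, normal scaled by ``normal_depth_factor``);
    the somatic burden default of 3.5 point events/Mb matches a
    relapsed-myeloma-like cohort average.
    """

    n_patients: int = 50
    mean_depth: float = 600.0
    normal_depth_factor: float = 0.75
    panel_size: int = 5_000_000  # toy panel footprint in target bases
    purity_range: Tuple[float, float] = (0.4, 0.95)
    n_clones_range: Tuple[int, int] = (2, 4)
    ccf_grid: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0)
    contamination_fraction_range: Tuple[float, float] = (0.0, 0.3)
    apobec_weight: float = 0.2
    somatic_rate_per_mb: float = 3.5
    ctcg_fraction: float = 0.5  # share of SNVs drawn as C>T/C>G-class events
    artifact_rate: float = 5.0  # expected recurrent-artifact calls per sample
    germline_snp_rate: float = 20.0  # expected common polymorphisms per sample
    indel_fraction: float = 0.1
    blood_only_rate: float = 1.0  # expected CTC-only variants when contaminated
    hotspot_freqs: Tuple[Tuple[str, float], ...] = (
        ("KRAS G12/G13/Q61", 0.26),
        ("NRAS Q61", 0.25),
        ("BRAF V600", 0.15),
    )
    hotspot_clonal_prob: float = 0.7
    enforce_clonal_exclusivity: bool = True
    noise_free: bool = False
    min_emit_alt: int = 2
    seed: int = 0

    def __post_init__(self):
        def _range_ok(name, lo, hi, bmin, bmax, open_low=False):
            if not (lo <= hi):
                raise ConfigurationError(f"{name}: empty range ({lo}, {hi})")
            if lo < bmin or hi > bmax or (open_low and lo <= bmin):
                raise ConfigurationError(f"{name}: range ({lo}, {hi}) outside bounds")

        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.mean_depth <= 0:
            raise ConfigurationError(f"mean_depth must be positive, got {self.mean_depth}")
        if self.panel_size < 10_000:
            raise ConfigurationError(f"panel_size too small: {self.panel_size}")
        _range_ok("purity_range", *self.purity_range, 0.0, 1.0, open_low=True)
        _range_ok("contamination_fraction_range", *self.contamination_fraction_range, 0.0, 0.5)
        if self.n_clones_range[0] < 1 or self.n_clones_range[0] > self.n_clones_range[1]:
            raise ConfigurationError(f"n_clones_range invalid: {self.n_clones_range}")
        if not self.ccf_grid or any(not (0.0 < c <= 1.0) for c in self.ccf_grid):
            raise ConfigurationError(f"ccf_grid values must lie in (0, 1]: {self.ccf_grid}")
        if 1.0 not in self.ccf_grid:
            raise ConfigurationError("ccf_grid must contain 1.0 (the trunk CCF)")
        for name in ("apobec_weight", "ctcg_fraction", "indel_fraction", "hotspot_clonal_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("artifact_rate", "germline_snp_rate", "somatic_rate_per_mb", "blood_only_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.min_emit_alt < 1:
            raise ConfigurationError(f"min_emit_alt must be >= 1, got {self.min_emit_alt}")


@dataclass
class PatientData:
    patient: str
    purity: float
    contamination: float
    clones: Dict[int, float]  # clone id -> CCF; clone 0 is the trunk
    tumor: List[VariantCall] = field(default_factory=list)
    normal: List[VariantCall] = field(default_factory=list)
    segments: List[CopySegment] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Generative ground truth behind a simulated cohort."""

    patients: pd.DataFrame  # patient, purity, contamination_fraction
    clones: pd.DataFrame  # patient, clone_id, ccf
    variants: pd.DataFrame  # one row per emitted variant instance
    apobec_weight: float


@dataclass
class CohortBundle:
    patients: Dict[str, PatientData]
    resources: PanelResources
    truth: SyntheticTruth
    config: SimulationConfig


class GeneCall(NamedTuple):
    """Minimal per-gene call record for cohort-level burden comparisons."""

    gene: str
    vaf: float
    consequence: str


# ----------------------------------------------------------------------
# panel construction


def build_panel(config: SimulationConfig, rng: np.random.Generator) -> PanelResources:
    """Toy reference + exon-style targets with named genes and hotspots.

    The reference is i.i.d. uniform over ACGT, so motif opportunities
    downstream are counted, never assumed.  Genes are laid out as runs
    of 5 exons x 2 kb separated by 500 b gaps across ~1.25 Mb contigs.
    """
    exon_len, gap, exons_per_gene = 2000, 500, 5
    gene_target = exon_len * exons_per_gene
    n_genes = max(len(NAMED_GENES), math.ceil(config.panel_size / gene_target))
    genes = list(NAMED_GENES) + [f"GENE{i:04d}" for i in range(len(NAMED_GENES), n_genes)]
    genes_per_contig = max(1, math.ceil(1_250_000 / (gene_target + exons_per_gene * gap)))
    targets: Dict[str, List[Tuple[int, int]]] = {}
    reference: Dict[str, str] = {}
    gene_intervals: List[Tuple[str, int, int, str]] = []
    hotspots: Dict[Tuple[str, int], Tuple[str, str]] = {}
    i = 0
    contig_idx = 0
    while i < len(genes):
        contig = f"chr{contig_idx + 1}"
        batch = genes[i : i + genes_per_contig]
        ivs: List[Tuple[int, int]] = []
        cur = gap
        for gene in batch:
            gene_start = cur
            for _ in range(exons_per_gene):
                ivs.append((cur, cur + exon_len))
                cur += exon_len + gap
            gene_intervals.append((contig, gene_start, cur - gap, gene))
            for k, codon in enumerate(HOTSPOT_CODONS.get(gene, ())):
                pos = gene_start + 10 + 10 * k + 1  # 1-based, inside the first exon
                hotspots[(contig, pos)] = (gene, codon)
        length = cur + gap
        seq = rng.integers(0, 4, size=length)
        reference[contig] = "".join(BASES[b] for b in seq)
        targets[contig] = ivs
        i += genes_per_contig
        contig_idx += 1
    return PanelResources(
        targets=targets, reference=reference, hotspots=hotspots, genes=gene_intervals
    )


class _SiteIndex:
    """Flat arrays of target positions for fast weighted site draws."""

    def __init__(self, resources: PanelResources):
        self.contig_names = resources.contig_order
        pos_parts, cid_parts, base_parts, motif_parts = [], [], [], []
        for ci, contig in enumerate(self.contig_names):
            seq = np.frombuffer(resources.reference[contig].encode(), dtype="S1")
            prev = np.roll(seq, 1)
            prev[0] = b"N"
            nxt = np.roll(seq, -1)
            nxt[-1] = b"N"
            w_prev = (prev == b"A") | (prev == b"T")
            w_next = (nxt == b"A") | (nxt == b"T")
            motif = ((seq == b"C") & (prev == b"T") & w_next) | (
                (seq == b"G") & (nxt == b"A") & w_prev
            )
            for s, e in resources.targets[contig]:
                pos_parts.append(np.arange(s, e, dtype=np.int64))
                cid_parts.append(np.full(e - s, ci, dtype=np.int32))
                base_parts.append(seq[s:e])
                motif_parts.append(motif[s:e])
        self.pos0 = np.concatenate(pos_parts)
        self.cidx = np.concatenate(cid_parts)
        base = np.concatenate(base_parts)
        in_motif = np.concatenate(motif_parts)
        self.all_idx = np.arange(self.pos0.size)
        self.cg_idx = np.flatnonzero((base == b"C") | (base == b"G"))
        self.motif_idx = np.flatnonzero(in_motif)

    def draw(self, rng: np.random.Generator, which: str) -> Tuple[str, int]:
        idx = {"any": self.all_idx, "cg": self.cg_idx, "motif": self.motif_idx}[which]
        j = int(idx[rng.integers(0, idx.size)])
        return self.contig_names[self.cidx[j]], int(self.pos0[j]) + 1


# ----------------------------------------------------------------------
# read-count sampling


def sample_counts(
    evaf: float,
    depth_mean: float,
    rng: np.random.Generator,
    noise_free: bool = False,
    strand_bias: Optional[str] = None,
    orientation_bias: Optional[str] = None,
) -> Tuple[int, int, int, int, int, Optional[float]]:
    """Draw (alt_fwd, alt_rev, depth, alt_f1r2, alt_f2r1, vaf_expected).

    Noisy mode: depth ~ Poisson(depth_mean), alt ~ Binomial(depth, evaf),
    strands and orientations split Binomial(alt, 1/2) unless biased.
    Noise-free mode uses expected counts and records the exact expected
    VAF alongside.
    """
    if noise_free:
        depth = max(1, int(round(depth_mean)))
        alt = min(depth, int(round(evaf * depth)))
        vaf_expected = evaf
    else:
        depth = max(1, int(rng.poisson(depth_mean)))
        alt = int(rng.binomial(depth, min(evaf, 1.0)))
        vaf_expected = None
    if strand_bias == "fwd":
        alt_fwd = alt
    elif strand_bias == "rev":
        alt_fwd = 0
    elif noise_free:
        alt_fwd = alt // 2
    else:
        alt_fwd = int(rng.binomial(alt, 0.5))
    alt_rev = alt - alt_fwd
    if orientation_bias == "f1r2":
        f1r2 = alt
    elif orientation_bias == "f2r1":
        f1r2 = 0
    elif noise_free:
        f1r2 = alt // 2
    else:
        f1r2 = int(rng.binomial(alt, 0.5))
    return alt_fwd, alt_rev, depth, f1r2, alt - f1r2, vaf_expected


def expected_tumor_vaf(ccf: float, m: float, purity: float, cn: float) -> float:
    """Inverse of the CCF relation: VAF implied by clone CCF and multiplicity."""
    return ccf * m * purity / ((1.0 - purity) * 2.0 + purity * cn)


def expected_contaminated_normal_vaf(ccf: float, m: float, fraction: float, cn: float) -> float:
    """Normal-library VAF of a tumor variant leaking at the given cell fraction."""
    if fraction <= 0:
        return 0.0
    return ccf * m * fraction / ((1.0 - fraction) * 2.0 + fraction * cn)


# ----------------------------------------------------------------------
# cohort simulation

_TRUTH_COLUMNS = [
    "patient", "contig", "pos", "ref", "alt", "clone_id", "multiplicity", "ccf",
    "class", "expected_vaf_tumor", "expected_vaf_normal", "gene", "consequence",
    "in_tumor", "in_normal", "whitelist_eligible",
]


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full paired tumor/normal cohort with truth table."""
    rng = np.random.default_rng(config.seed)
    resources = build_panel(config, rng)
    sites = _SiteIndex(resources)
    hotspot_sites = _group_hotspot_sites(resources, config)
    patients: Dict[str, PatientData] = {}
    truth_rows: List[dict] = []
    clone_rows: List[dict] = []

    for pi in range(config.n_patients):
        pid = f"P{pi + 1:04d}"
        patient = _simulate_patient(pid, config, resources, sites, hotspot_sites, rng, truth_rows)
        patients[pid] = patient
        for cid, ccf in sorted(patient.clones.items()):
            clone_rows.append({"patient": pid, "clone_id": cid, "ccf": ccf})

    _inject_cohort_artifacts(patients, config, resources, sites, rng, truth_rows)

    for p in patients.values():
        order = {c: i for i, c in enumerate(resources.contig_order)}
        key = lambda c: (order[c.contig], c.pos, c.ref, c.alt)
        p.tumor.sort(key=key)
        p.normal.sort(key=key)

    truth = SyntheticTruth(
        patients=pd.DataFrame(
            [
                {"patient": pid, "purity": p.purity, "contamination_fraction": p.contamination}
                for pid, p in patients.items()
            ],
            columns=["patient", "purity", "contamination_fraction"],
        ),
        clones=pd.DataFrame(clone_rows, columns=["patient", "clone_id", "ccf"]),
        variants=pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS),
        apobec_weight=config.apobec_weight,
    )
    return CohortBundle(patients=patients, resources=resources, truth=truth, config=config)


def _group_hotspot_sites(resources, config):
    """Map each configured hotspot group label to its member sites."""
    label_members = {
        "KRAS G12/G13/Q61": {("KRAS", c) for c in ("G12", "G13", "Q61")},
        "NRAS Q61": {("NRAS", c) for c in ("G12", "G13", "Q61")},
        "BRAF V600": {("BRAF", "V600")},
    }
    out: Dict[str, List[Tuple[str, int]]] = {}
    for label, _freq in config.hotspot_freqs:
        members = label_members.get(label)
        if members is None:  # custom group: match label prefix against gene names
            members = {
                (g, c) for (g, c) in resources.hotspots.values() if label.startswith(g)
            }
        out[label] = sorted(
            site for site, gc in resources.hotspots.items() if gc in members
        )
    return out


def _simulate_patient(pid, config, resources, sites, hotspot_sites, rng, truth_rows):
    purity = float(rng.uniform(*config.purity_range))
    lo, hi = config.contamination_fraction_range
    contamination = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    n_clones = int(rng.integers(config.n_clones_range[0], config.n_clones_range[1] + 1))
    sub_grid = [c for c in config.ccf_grid if c < 1.0]
    n_sub = min(n_clones - 1, len(sub_grid))
    sub_ccfs = sorted(
        (float(c) for c in rng.choice(sub_grid, size=n_sub, replace=False)), reverse=True
    ) if n_sub else []
    clones = {0: 1.0, **{i + 1: c for i, c in enumerate(sub_ccfs)}}
    clone_ids = sorted(clones)
    clone_w = np.array([0.5] + [0.5 / max(1, len(sub_ccfs))] * len(sub_ccfs))
    clone_w = clone_w / clone_w.sum()

    patient = PatientData(pid, purity, contamination, clones)
    patient.segments = _simulate_segments(pid, resources, rng)
    used: Set[tuple] = set()
    normal_depth = config.mean_depth * config.normal_depth_factor

    def local_cn(contig, pos):
        for s in patient.segments:
            if s.contig == contig and s.start <= pos - 1 < s.end:
                return s.total_cn
        return 2.0

    def add_somatic(contig, pos, ref, alt, clone_id, consequence, var_class):
        ccf = clones[clone_id]
        cn = local_cn(contig, pos)
        evaf_t = expected_tumor_vaf(ccf, 1.0, purity, cn)
        evaf_n = expected_contaminated_normal_vaf(ccf, 1.0, contamination, cn)
        tf, tr, td, t12, t21, tve = sample_counts(evaf_t, config.mean_depth, rng, config.noise_free)
        if tf + tr < 1:
            return
        gene = resources.gene_at(contig, pos) or ""
        ctx = resources.trinucleotide(contig, pos) if len(ref) == len(alt) == 1 else None
        common = dict(contig=contig, pos=pos, ref=ref, alt=alt, pop_maf=0.0, gene=gene,
                      context=ctx, hotspot=resources.is_hotspot(contig, pos),
                      consequence=consequence)
        patient.tumor.append(
            VariantCall(sample=pid, alt_fwd=tf, alt_rev=tr, depth=td,
                        alt_f1r2=t12, alt_f2r1=t21, vaf_expected=tve, **common)
        )
        in_normal = False
        if evaf_n > 0:
            nf, nr, nd, n12, n21, nve = sample_counts(evaf_n, normal_depth, rng, config.noise_free)
            if nf + nr >= config.min_emit_alt:
                patient.normal.append(
                    VariantCall(sample=pid, alt_fwd=nf, alt_rev=nr, depth=nd,
                                alt_f1r2=n12, alt_f2r1=n21, vaf_expected=nve, **common)
                )
                in_normal = True
        truth_rows.append(
            {"patient": pid, "contig": contig, "pos": pos, "ref": ref, "alt": alt,
             "clone_id": clone_id, "multiplicity": 1.0, "ccf": ccf, "class": "somatic",
             "expected_vaf_tumor": evaf_t, "expected_vaf_normal": evaf_n, "gene": gene,
             "consequence": consequence, "in_tumor": True, "in_normal": in_normal,
             "whitelist_eligible": resources.is_hotspot(contig, pos)}
        )

    # background somatic process
    footprint_mb = resources.footprint_mb
    n_som = int(rng.poisson(config.somatic_rate_per_mb * footprint_mb))
    for _ in range(n_som):
        clone_id = int(rng.choice(clone_ids, p=clone_w))
        is_indel = rng.uniform() < config.indel_fraction
        if is_indel:
            contig, pos = sites.draw(rng, "any")
            ref, alt = _draw_indel(resources, contig, pos, rng)
            if ref is None or (contig, pos, ref) in used:
                continue
            used.add((contig, pos, ref))
            conseq = _INDEL_CONSEQUENCES[int(rng.choice(2, p=_INDEL_CONSEQ_W))]
            add_somatic(contig, pos, ref, alt, clone_id, conseq, "indel")
            continue
        if rng.uniform() < config.ctcg_fraction and sites.cg_idx.size:
            which = "motif" if (sites.motif_idx.size and rng.uniform() < config.apobec_weight) else "cg"
            contig, pos = sites.draw(rng, which)
            ref = resources.base_at(contig, pos)
            alt = str(rng.choice(["T", "G"] if ref == "C" else ["A", "C"]))
        else:
            contig, pos = sites.draw(rng, "any")
            ref = resources.base_at(contig, pos)
            # exclude alts that would create a deamination-class change,
            # keeping the APOBEC weight interpretable as a conditional
            allowed = [b for b in BASES if b != ref]
            if ref == "C":
                allowed = ["A"]
            elif ref == "G":
                allowed = ["T"]
            alt = str(rng.choice(allowed))
        if (contig, pos, ref) in used:
            continue
        used.add((contig, pos, ref))
        conseq = _SNV_CONSEQUENCES[int(rng.choice(len(_SNV_CONSEQUENCES), p=_SNV_CONSEQ_W))]
        add_somatic(contig, pos, ref, alt, clone_id, conseq, "SNV")

    # hotspot-group process with optional enforced clonal exclusivity
    drawn = []
    for label, freq in config.hotspot_freqs:
        if hotspot_sites.get(label) and rng.uniform() < freq:
            clonal = rng.uniform() < config.hotspot_clonal_prob
            drawn.append([label, clonal])
    if config.enforce_clonal_exclusivity:
        clonal_idx = [i for i, (_, c) in enumerate(drawn) if c]
        if len(clonal_idx) > 1:
            keep = int(rng.choice(clonal_idx))
            for i in clonal_idx:
                if i != keep:
                    drawn[i][1] = False
    sub_ids = [cid for cid in clone_ids if cid != 0]
    for label, clonal in drawn:
        if clonal:
            clone_id = 0
        elif sub_ids:
            # demoted/subclonal hotspots sit in the lowest-CCF subclone under
            # enforcement, a random subclone otherwise
            clone_id = (
                min(sub_ids, key=lambda c: clones[c])
                if config.enforce_clonal_exclusivity
                else int(rng.choice(sub_ids))
            )
        else:
            continue
        contig, pos = hotspot_sites[label][int(rng.integers(len(hotspot_sites[label])))]
        ref = resources.base_at(contig, pos)
        if (contig, pos, ref) in used:
            continue
        used.add((contig, pos, ref))
        alt = str(rng.choice([b for b in BASES if b != ref]))
        add_somatic(contig, pos, ref, alt, clone_id, "missense", "SNV")

    # blood-only variants carried by circulating tumor cells
    if contamination > 0 and config.blood_only_rate > 0:
        for _ in range(int(rng.poisson(config.blood_only_rate))):
            contig, pos = sites.draw(rng, "any")
            ref = resources.base_at(contig, pos)
            if (contig, pos, ref) in used:
                continue
            used.add((contig, pos, ref))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            ccf = float(rng.choice(config.ccf_grid))
            cn = local_cn(contig, pos)
            evaf_n = expected_contaminated_normal_vaf(ccf, 1.0, contamination, cn)
            nf, nr, nd, n12, n21, nve = sample_counts(evaf_n, normal_depth, rng, config.noise_free)
            if nf + nr < config.min_emit_alt:
                continue
            gene = resources.gene_at(contig, pos) or ""
            patient.normal.append(
                VariantCall(sample=pid, contig=contig, pos=pos, ref=ref, alt=alt,
                            alt_fwd=nf, alt_rev=nr, depth=nd, alt_f1r2=n12, alt_f2r1=n21,
                            pop_maf=0.0, gene=gene,
                            context=resources.trinucleotide(contig, pos),
                            hotspot=resources.is_hotspot(contig, pos),
                            consequence="missense", vaf_expected=nve)
            )
            truth_rows.append(
                {"patient": pid, "contig": contig, "pos": pos, "ref": ref, "alt": alt,
                 "clone_id": -1, "multiplicity": 1.0, "ccf": ccf, "class": "contaminant_only",
                 "expected_vaf_tumor": 0.0, "expected_vaf_normal": evaf_n, "gene": gene,
                 "consequence": "missense", "in_tumor": False, "in_normal": True,
                 "whitelist_eligible": resources.is_hotspot(contig, pos)}
            )

    # common population polymorphisms, heterozygous in all cells
    for _ in range(int(rng.poisson(config.germline_snp_rate))):
        contig, pos = sites.draw(rng, "any")
        ref = resources.base_at(contig, pos)
        if (contig, pos, ref) in used:
            continue
        used.add((contig, pos, ref))
        alt = str(rng.choice([b for b in BASES if b != ref]))
        maf = float(np.float32(rng.choice(_GERMLINE_MAF_GRID)))
        gene = resources.gene_at(contig, pos) or ""
        common = dict(contig=contig, pos=pos, ref=ref, alt=alt, pop_maf=maf, gene=gene,
                      context=resources.trinucleotide(contig, pos),
                      hotspot=resources.is_hotspot(contig, pos), consequence="missense")
        emitted = {"in_tumor": False, "in_normal": False}
        for lib, depth_mean, flag in (("tumor", config.mean_depth, "in_tumor"),
                                      ("normal", normal_depth, "in_normal")):
            f, r, d, o12, o21, ve = sample_counts(0.5, depth_mean, rng, config.noise_free)
            if f + r >= config.min_emit_alt:
                call = VariantCall(sample=pid, alt_fwd=f, alt_rev=r, depth=d,
                                   alt_f1r2=o12, alt_f2r1=o21, vaf_expected=ve, **common)
                (patient.tumor if lib == "tumor" else patient.normal).append(call)
                emitted[flag] = True
        if emitted["in_tumor"] or emitted["in_normal"]:
            truth_rows.append(
                {"patient": pid, "contig": contig, "pos": pos, "ref": ref, "alt": alt,
                 "clone_id": -1, "multiplicity": 0.0, "ccf": 0.0, "class": "germline_common",
                 "expected_vaf_tumor": 0.5, "expected_vaf_normal": 0.5, "gene": gene,
                 "consequence": "missense", **emitted,
                 "whitelist_eligible": resources.is_hotspot(contig, pos)}
            )
    return patient


def _draw_indel(resources, contig, pos, rng):
    """Small (<= 5 bp) insertion or deletion anchored at pos (1-based)."""
    seq = resources.reference[contig]
    length = int(rng.integers(1, 6))
    if rng.uniform() < 0.5:  # deletion
        if pos - 1 + length + 1 > len(seq):
            return None, None
        ref = seq[pos - 1 : pos + length]
        return ref, ref[0]
    anchor = seq[pos - 1]
    ins = "".join(BASES[int(b)] for b in rng.integers(0, 4, size=length))
    return anchor, anchor + ins


def _simulate_segments(pid, resources, rng) -> List[CopySegment]:
    segments = []
    for contig in resources.contig_order:
        length = len(resources.reference[contig])
        n_seg = int(rng.integers(1, 4))
        cuts = sorted(int(c) for c in rng.integers(1, length, size=n_seg - 1)) if n_seg > 1 else []
        bounds = [0] + cuts + [length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e <= s:
                continue
            cn = float(_CN_CHOICES[int(rng.choice(len(_CN_CHOICES), p=_CN_WEIGHTS))])
            segments.append(CopySegment(sample=pid, contig=contig, start=s, end=e, total_cn=cn))
    return segments


# ----------------------------------------------------------------------
# recurrent artifacts


def _artifact_call(pid, contig, pos, ref, alt, kind, vaf, depth_mean, rng, resources,
                   noise_free, min_emit):
    strand_bias = None
    orientation_bias = None
    if kind == "strand":
        strand_bias = "fwd" if rng.uniform() < 0.5 else "rev"
    else:  # oxidative-damage mimic: orientation-biased, strands balanced
        orientation_bias = "f1r2" if rng.uniform() < 0.5 else "f2r1"
    f, r, d, o12, o21, ve = sample_counts(vaf, depth_mean, rng, noise_free,
                                          strand_bias=strand_bias,
                                          orientation_bias=orientation_bias)
    if f + r < min_emit:
        return None
    return VariantCall(sample=pid, contig=contig, pos=pos, ref=ref, alt=alt,
                       alt_fwd=f, alt_rev=r, depth=d, alt_f1r2=o12, alt_f2r1=o21,
                       pop_maf=0.0, gene=resources.gene_at(contig, pos) or "",
                       context=resources.trinucleotide(contig, pos) if len(ref) == len(alt) == 1 else None,
                       hotspot=resources.is_hotspot(contig, pos),
                       pooled_artifact=True, consequence="missense", vaf_expected=ve)


def _inject_cohort_artifacts(patients, config, resources, sites, rng, truth_rows):
    """Shared recurrent-artifact sites across tumor and normal libraries."""
    if config.artifact_rate <= 0:
        return
    per_site_prob = 0.3
    n_sites = max(1, int(round(config.artifact_rate / per_site_prob)))
    pool: List[Tuple[str, int, str, str, str]] = []
    hotspot_list = sorted(resources.hotspots)
    for k in range(n_sites):
        if k == 0 and hotspot_list:  # one pool site at a white-listed hotspot
            contig, pos = hotspot_list[int(rng.integers(len(hotspot_list)))]
        else:
            contig, pos = sites.draw(rng, "any")
        ref = resources.base_at(contig, pos)
        kind = "strand" if rng.uniform() < 0.5 else "oxog"
        if kind == "oxog":
            # force a damage-class change so the orientation rule applies
            if ref in ("C", "G"):
                alt = "A" if ref == "C" else "T"
            else:
                kind = "strand"
                alt = str(rng.choice([b for b in BASES if b != ref]))
        else:
            alt = str(rng.choice([b for b in BASES if b != ref]))
        pool.append((contig, pos, ref, alt, kind))
        resources.artifact_pool.add((contig, pos, ref, alt))

    pids = sorted(patients)
    normal_depth = config.mean_depth * config.normal_depth_factor
    for contig, pos, ref, alt, kind in pool:
        chosen = [pid for pid in pids if rng.uniform() < per_site_prob]
        while len(chosen) < min(3, len(pids)):
            extra = pids[int(rng.integers(len(pids)))]
            if extra not in chosen:
                chosen.append(extra)
        for pid in chosen:
            patient = patients[pid]
            if any(c.key == (contig, pos, ref, alt) for c in patient.tumor):
                continue
            vaf = float(rng.uniform(0.005, 0.03))
            t_call = _artifact_call(pid, contig, pos, ref, alt, kind, vaf,
                                    config.mean_depth, rng, resources,
                                    config.noise_free, 1)
            n_call = _artifact_call(pid, contig, pos, ref, alt, kind, vaf,
                                    normal_depth, rng, resources,
                                    config.noise_free, config.min_emit_alt)
            if t_call is None and n_call is None:
                continue
            if t_call is not None:
                patient.tumor.append(t_call)
            if n_call is not None:
                patient.normal.append(n_call)
            truth_rows.append(
                {"patient": pid, "contig": contig, "pos": pos, "ref": ref, "alt": alt,
                 "clone_id": -1, "multiplicity": 0.0, "ccf": 0.0, "class": "artifact",
                 "expected_vaf_tumor": vaf, "expected_vaf_normal": vaf, "gene":
                     resources.gene_at(contig, pos) or "", "consequence": "missense",
                 "in_tumor": t_call is not None, "in_normal": n_call is not None,
                 "whitelist_eligible": resources.is_hotspot(contig, pos)}
            )


def inject_artifacts(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    pool: Sequence[PoolEntry],
    rate: float,
    seed: int,
    resources: Optional[PanelResources] = None,
    depth_mean: float = 450.0,
) -> Tuple[Dict[str, List[VariantCall]], pd.DataFrame]:
    """Add recurrent artifact calls at pooled sites across call sets.

    Each pool site is injected into a random subset of samples, never
    fewer than three (so pooling at the default recurrence cutoff can
    recover it).  Returns the augmented call sets and a truth table of
    injected records; white-listed hotspot sites are eligible and marked.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if not pool:
        raise ValueError("artifact pool is empty")
    rng = np.random.default_rng(seed)
    out = {s: list(calls) for s, calls in calls_by_sample.items()}
    rows = []
    if rate == 0:
        return out, pd.DataFrame(rows, columns=["sample", "contig", "pos", "ref", "alt",
                                                "class", "whitelist_eligible"])
    samples = sorted(out)
    per_site_prob = min(1.0, rate / max(1, len(pool)))
    for contig, pos, ref, alt in pool:
        chosen = [s for s in samples if rng.uniform() < per_site_prob]
        while len(chosen) < min(3, len(samples)):
            extra = samples[int(rng.integers(len(samples)))]
            if extra not in chosen:
                chosen.append(extra)
        hotspot = bool(resources.is_hotspot(contig, pos)) if resources else False
        for s in chosen:
            vaf = float(rng.uniform(0.005, 0.03))
            f, r, d, o12, o21, _ = sample_counts(vaf, depth_mean, rng,
                                                 strand_bias="fwd" if rng.uniform() < 0.5 else "rev")
            if f + r < 2:
                continue
            out[s].append(
                VariantCall(sample=s, contig=contig, pos=pos, ref=ref, alt=alt,
                            alt_fwd=f, alt_rev=r, depth=d, alt_f1r2=o12, alt_f2r1=o21,
                            pooled_artifact=True, hotspot=hotspot, consequence="missense")
            )
            rows.append({"sample": s, "contig": contig, "pos": pos, "ref": ref,
                         "alt": alt, "class": "artifact", "whitelist_eligible": hotspot})
    return out, pd.DataFrame(rows, columns=["sample", "contig", "pos", "ref", "alt",
                                            "class", "whitelist_eligible"])


# ----------------------------------------------------------------------
# lightweight generators for cohort-level power analyses


def simulate_hotspot_status(
    n_patients: int,
    freqs: Mapping[str, float],
    clonal_prob: float,
    enforce_exclusivity: bool,
    seed: int,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Patient x group status matrix without read-level simulation.

    Mirrors the hotspot layer of :func:`simulate_cohort` for fast
    replicate studies of clonal mutual exclusivity.  ``drop_empty``
    mimics the heatmap inclusion rule (patients with no qualifying
    mutation excluded); keep all rows (``drop_empty=False``) when a
    column-exchangeable null matrix is needed, e.g. for calibrating the
    permutation test.
    """
    rng = np.random.default_rng(seed)
    labels = list(freqs)
    rows = []
    for i in range(n_patients):
        drawn = {}
        for label in labels:
            if rng.uniform() < freqs[label]:
                drawn[label] = "clonal" if rng.uniform() < clonal_prob else "subclonal"
        if enforce_exclusivity:
            clonal = [l for l, s in drawn.items() if s == "clonal"]
            if len(clonal) > 1:
                keep = clonal[int(rng.integers(len(clonal)))]
                for l in clonal:
                    if l != keep:
                        drawn[l] = "subclonal"
        if drawn or not drop_empty:
            rows.append({"sample": f"P{i + 1:04d}",
                         **{l: drawn.get(l, "absent") for l in labels}})
    return pd.DataFrame(rows, columns=["sample"] + labels).set_index("sample")


def simulate_gene_burden_cohorts(
    n_a: int,
    n_b: int,
    base_freqs: Mapping[str, float],
    enriched_gene: Optional[str] = None,
    fold: float = 2.0,
    seed: int = 0,
) -> Tuple[Dict[str, List[GeneCall]], Dict[str, List[GeneCall]]]:
    """Two cohorts of per-patient gene calls with one gene's frequency scaled.

    VAFs are drawn above the 5% inclusion floor; consequences are
    non-synonymous, so the comparison sees exactly the designed
    frequencies in expectation.
    """
    rng = np.random.default_rng(seed)

    def cohort(n, prefix, scale_gene=None):
        out = {}
        for i in range(n):
            pid = f"{prefix}{i + 1:04d}"
            calls = []
            for gene, freq in base_freqs.items():
                f = min(1.0, freq * fold) if gene == scale_gene else freq
                if rng.uniform() < f:
                    calls.append(GeneCall(gene=gene, vaf=float(rng.uniform(0.06, 0.6)),
                                          consequence="missense"))
            out[pid] = calls
        return out

    cohort_a = cohort(n_a, "A", scale_gene=enriched_gene)
    cohort_b = cohort(n_b, "B")
    return cohort_a, cohort_b
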