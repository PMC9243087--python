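"""On-disk fixture format: VCF v4.2, BED, FASTA and TSV tables.

A cohort bundle serializes to one directory: a toy reference (FASTA),
panel targets (BED), gene/hotspot/artifact-pool resources (TSV),
per-sample purity, copy segments and generative truth (TSV), and one
single-sample VCF per tumor and per normal library with per-strand and
per-orientation alt depths in FORMAT fields.  Reading the directory
back reproduces the in-memory bundle (the simulator's noise-free mode
additionally carries exact expected VAFs in memory; those are not
serialized, as VCF FORMAT floats are 32-bit).
"""

from __future__ import annotations

import dataclasses
import json
import textwrap
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO

from .clonality import CopySegment
from .panel import PanelResources
from .simulate import CohortBundle, PatientData, SimulationConfig, SyntheticTruth
from .variants import REASON_CODES, VariantCall

_VCF_HEADER_LINES = [
    ('INFO', 'GENE', '1', 'String', 'Gene symbol at the variant site'),
    ('INFO', 'PMAF', '1', 'Float', 'Population minor allele frequency'),
    ('INFO', 'CONSEQ', '1', 'String', 'Functional consequence class'),
    ('INFO', 'HS', '0', 'Flag', 'White-listed hotspot site'),
    ('INFO', 'POOLED', '0', 'Flag', 'Site in the pooled recurrent-artifact database'),
    ('FORMAT', 'DP', '1', 'Integer', 'Total read depth'),
    ('FORMAT', 'ADF', 'R', 'Integer', 'Forward-strand depths per allele'),
    ('FORMAT', 'ADR', 'R', 'Integer', 'Reverse-strand depths per allele'),
    ('FORMAT', 'F1R2', '1', 'Integer', 'Alt reads in F1R2 pair orientation'),
    ('FORMAT', 'F2R1', '1', 'Integer', 'Alt reads in F2R1 pair orientation'),
]


def _vcf_header(resources: PanelResources, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in resources.contig_order:
        header.contigs.add(contig, length=len(resources.reference[contig]))
    for kind, name, number, vtype, desc in _VCF_HEADER_LINES:
        header.add_meta(
            kind,
            items=[("ID", name), ("Number", number), ("Type", vtype), ("Description", desc)],
        )
    for code in REASON_CODES:
        header.filters.add(code, None, None, f"Rejected: {code}")
    header.add_sample(sample)
    return header


def write_calls_vcf(
    calls: Sequence[VariantCall],
    path,
    resources: PanelResources,
    sample: str,
    filters: Optional[Mapping[tuple, Sequence[str]]] = None,
) -> None:
    """Write one library's calls as a sorted single-sample VCF.

    ``filters`` optionally maps variant keys to rejection reason codes,
    written semicolon-joined into FILTER (PASS otherwise).
    """
    header = _vcf_header(resources, sample)
    order = {c: i for i, c in enumerate(resources.contig_order)}
    calls = sorted(calls, key=lambda c: (order[c.contig], c.pos, c.ref, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            rec = vcf.new_record(
                contig=call.contig, start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            if call.gene:
                rec.info["GENE"] = call.gene
            rec.info["PMAF"] = call.pop_maf
            rec.info["CONSEQ"] = call.consequence
            if call.hotspot:
                rec.info["HS"] = True
            if call.pooled_artifact:
                rec.info["POOLED"] = True
            ref_total = call.depth - call.alt_depth
            ref_fwd = ref_total // 2
            rec.samples[sample]["DP"] = call.depth
            rec.samples[sample]["ADF"] = (ref_fwd, call.alt_fwd)
            rec.samples[sample]["ADR"] = (ref_total - ref_fwd, call.alt_rev)
            rec.samples[sample]["F1R2"] = call.alt_f1r2
            rec.samples[sample]["F2R1"] = call.alt_f2r1
            reason = tuple(filters.get(call.key, ())) if filters else ()
            if reason:
                for code in reason:
                    rec.filter.add(code)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)


def read_calls_vcf(path, resources: PanelResources, sample: Optional[str] = None) -> List[VariantCall]:
    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_sample = sample or list(vcf.header.samples)[0]
        for rec in vcf:
            fmt = rec.samples[vcf_sample]
            ref, alt = rec.alleles[0], rec.alleles[1]
            is_snv = len(ref) == 1 and len(alt) == 1
            calls.append(
                VariantCall(
                    sample=vcf_sample,
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    alt_fwd=int(fmt["ADF"][1]),
                    alt_rev=int(fmt["ADR"][1]),
                    depth=int(fmt["DP"]),
                    alt_f1r2=int(fmt["F1R2"]),
                    alt_f2r1=int(fmt["F2R1"]),
                    pop_maf=float(rec.info["PMAF"]),
                    gene=rec.info.get("GENE", ""),
                    context=resources.trinucleotide(rec.contig, rec.pos) if is_snv else None,
                    hotspot=bool(rec.info.get("HS", False)),
                    pooled_artifact=bool(rec.info.get("POOLED", False)),
                    consequence=rec.info.get("CONSEQ", "missense"),
                )
            )
    return calls


# ----------------------------------------------------------------------
# flat-file helpers


def write_fasta(reference: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for contig, seq in reference.items():
            fh.write(f">{contig}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)))
            fh.write("\n")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(targets: Mapping[str, Sequence[Tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for contig, ivs in targets.items():
            for s, e in ivs:
                fh.write(f"{contig}\t{s}\t{e}\n")


def read_bed(path) -> Dict[str, List[Tuple[int, int]]]:
    targets: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, s, e = line.split()[:3]
            targets.setdefault(contig, []).append((int(s), int(e)))
    return targets


def _write_tsv(df: pd.DataFrame, path) -> None:
    # repr is the shortest exact round-trip representation of a float
    df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip", **kwargs
    )


def write_segments_tsv(segments_by_sample: Mapping[str, Sequence[CopySegment]], path) -> None:
    rows = [
        {"sample": s.sample, "contig": s.contig, "start": s.start, "end": s.end,
         "total_cn": s.total_cn}
        for sample in segments_by_sample
        for s in segments_by_sample[sample]
    ]
    _write_tsv(pd.DataFrame(rows, columns=["sample", "contig", "start", "end", "total_cn"]), path)


def read_segments_tsv(path) -> Dict[str, List[CopySegment]]:
    df = _read_tsv(path)
    out: Dict[str, List[CopySegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, []).append(
            CopySegment(sample=row.sample, contig=row.contig, start=int(row.start),
                        end=int(row.end), total_cn=float(row.total_cn))
        )
    return out


# ----------------------------------------------------------------------
# whole-bundle fixture


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    for name in ("purity_range", "contamination_fraction_range", "n_clones_range", "ccf_grid"):
        if name in d:
            d[name] = tuple(d[name])
    if "hotspot_freqs" in d:
        d["hotspot_freqs"] = tuple((str(k), float(v)) for k, v in d["hotspot_freqs"])
    return SimulationConfig(**d)


def write_fixture(bundle: CohortBundle, directory) -> Path:
    """Serialize a cohort bundle; see the module docstring for layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    res = bundle.resources
    write_fasta(res.reference, directory / "reference.fa")
    write_bed(res.targets, directory / "targets.bed")
    _write_tsv(
        pd.DataFrame(res.genes, columns=["contig", "start", "end", "gene"]),
        directory / "genes.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [{"contig": c, "pos": p, "gene": g, "codon": cod}
             for (c, p), (g, cod) in sorted(res.hotspots.items())],
            columns=["contig", "pos", "gene", "codon"],
        ),
        directory / "hotspots.tsv",
    )
    _write_tsv(
        pd.DataFrame(sorted(res.artifact_pool), columns=["contig", "pos", "ref", "alt"]),
        directory / "artifact_pool.tsv",
    )
    _write_tsv(bundle.truth.patients, directory / "patients.tsv")
    _write_tsv(bundle.truth.clones, directory / "clones.tsv")
    _write_tsv(bundle.truth.variants, directory / "truth.tsv")
    write_segments_tsv(
        {pid: p.segments for pid, p in bundle.patients.items()}, directory / "segments.tsv"
    )
    _write_tsv(
        pd.DataFrame(
            [{"sample": pid, "purity": p.purity} for pid, p in bundle.patients.items()],
            columns=["sample", "purity"],
        ),
        directory / "purity.tsv",
    )
    with open(directory / "config.json", "w") as fh:
        json.dump(config_to_dict(bundle.config), fh, indent=2, sort_keys=True)
    for pid, p in bundle.patients.items():
        write_calls_vcf(p.tumor, directory / f"{pid}.tumor.vcf", res, sample=pid)
        write_calls_vcf(p.normal, directory / f"{pid}.normal.vcf", res, sample=pid)
    return directory


def read_resources(directory) -> PanelResources:
    directory = Path(directory)
    hotspots_df = _read_tsv(directory / "hotspots.tsv")
    pool_df = _read_tsv(directory / "artifact_pool.tsv")
    genes_df = _read_tsv(directory / "genes.tsv")
    return PanelResources(
        targets=read_bed(directory / "targets.bed"),
        reference=read_fasta(directory / "reference.fa"),
        hotspots={
            (r.contig, int(r.pos)): (r.gene, r.codon)
            for r in hotspots_df.itertuples(index=False)
        },
        artifact_pool={
            (r.contig, int(r.pos), r.ref, r.alt) for r in pool_df.itertuples(index=False)
        },
        genes=[
            (r.contig, int(r.start), int(r.end), r.gene)
            for r in genes_df.itertuples(index=False)
        ],
    )


def read_fixture(directory) -> CohortBundle:
    """Load a cohort bundle written by :func:`write_fixture`."""
    directory = Path(directory)
    resources = read_resources(directory)
    with open(directory / "config.json") as fh:
        config = config_from_dict(json.load(fh))
    patients_df = _read_tsv(directory / "patients.tsv")
    clones_df = _read_tsv(directory / "clones.tsv")
    truth_df = _read_tsv(directory / "truth.tsv")
    segments = read_segments_tsv(directory / "segments.tsv")
    patients: Dict[str, PatientData] = {}
    for row in patients_df.itertuples(index=False):
        pid = row.patient
        clones = {
            int(r.clone_id): float(r.ccf)
            for r in clones_df[clones_df["patient"] == pid].itertuples(index=False)
        }
        patients[pid] = PatientData(
            patient=pid,
            purity=float(row.purity),
            contamination=float(row.contamination_fraction),
            clones=clones,
            tumor=read_calls_vcf(directory / f"{pid}.tumor.vcf", resources, sample=pid),
            normal=read_calls_vcf(directory / f"{pid}.normal.vcf", resources, sample=pid),
            segments=segments.get(pid, []),
        )
    truth = SyntheticTruth(
        patients=patients_df, clones=clones_df, variants=truth_df,
        apobec_weight=config.apobec_weight,
    )
    return CohortBundle(patients=patients, resources=resources, truth=truth, config=config)


def bundles_equal(a: CohortBundle, b: CohortBundle) -> bool:
    """Structural equality of two bundles (DataFrames compared by value)."""
    if sorted(a.patients) != sorted(b.patients):
        return False
    for pid in a.patients:
        pa, pb = a.patients[pid], b.patients[pid]
        if (pa.purity, pa.contamination, pa.clones) != (pb.purity, pb.contamination, pb.clones):
            return False
        if pa.tumor != pb.tumor or pa.normal != pb.normal or pa.segments != pb.segments:
            return False
    ra, rb = a.resources, b.resources
    if (ra.targets, ra.reference, ra.hotspots, ra.artifact_pool, ra.genes) != (
        rb.targets, rb.reference, rb.hotspots, rb.artifact_pool, rb.genes
    ):
        return False
    if a.config != b.config:
        return False
    return (
        a.truth.patients.equals(b.truth.patients)
        and a.truth.clones.equals(b.truth.clones)
        and a.truth.variants.equals(b.truth.variants)
    )
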