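"""Reading and normalizing somatic mutation catalogues (VCF / MAF).

Every input row becomes a :class:`MutationRecord` with fully normalized
alleles: upper-cased, shared leading anchor base (and any shared trailing
bases) stripped, so an insertion has an empty ``ref`` and a deletion an empty
``alt``.  Records are then assigned an event class:

* ``SBS``   — single base substitution (|ref| == |alt| == 1),
* ``DBS``   — doublet base substitution (|ref| == |alt| == 2, both differ),
* ``ID_INS`` / ``ID_DEL`` — pure insertion / deletion,
* ``COMPLEX`` — everything else (e.g. deletion plus insertion at one locus).

Conventions: ``position`` is the 1-based first affected reference base; for
insertions it is the base *after which* the inserted sequence occurs.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .reference import GenomeBuild, normalize_chrom

logger = logging.getLogger(__name__)

SBS = "SBS"
DBS = "DBS"
ID_INS = "ID_INS"
ID_DEL = "ID_DEL"
COMPLEX = "COMPLEX"

MAF_COLUMNS = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
)


@dataclass(frozen=True)
class MutationRecord:
    sample: str
    chromosome: str
    position: int  # 1-based first affected reference base
    ref: str
    alt: str
    event_class: str


def classify_event(ref: str, alt: str) -> str:
    if ref == alt:
        raise ValueError("ref == alt is not a mutation")
    if len(ref) == 1 and len(alt) == 1:
        return SBS
    if len(ref) == 2 and len(alt) == 2 and ref[0] != alt[0] and ref[1] != alt[1]:
        return DBS
    if ref == "":
        return ID_INS
    if alt == "":
        return ID_DEL
    return COMPLEX


def normalize_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared leading, then trailing, bases from an allele pair.

    Returns the adjusted position of the first affected reference base; for a
    pure insertion, the base after which the insertion occurs.
    """
    ref, alt = ref.upper(), alt.upper()
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    ref, alt = ref[k:], alt[k:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    position += k
    if ref == "" and k > 0:  # insertion: anchor base was stripped
        position -= 1
    return position, ref, alt


def make_record(
    sample: str, chromosome: str, position: int, ref: str, alt: str
) -> MutationRecord:
    """Normalize one raw variant into a MutationRecord (raises ValueError on
    non-mutations such as ref == alt)."""
    ref = "" if ref in ("-", ".", "") else ref.upper()
    alt = "" if alt in ("-", ".", "") else alt.upper()
    position, ref, alt = normalize_alleles(position, ref, alt)
    return MutationRecord(
        sample=sample,
        chromosome=normalize_chrom(chromosome),
        position=position,
        ref=ref,
        alt=alt,
        event_class=classify_event(ref, alt),
    )


def _read_vcf(path: Path, stats: Counter) -> Iterator[MutationRecord]:
    import pysam

    default_sample = path.name
    for suffix in (".gz", ".vcf"):
        if default_sample.endswith(suffix):
            default_sample = default_sample[: -len(suffix)]
    with pysam.VariantFile(str(path)) as vf:
        file_samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if alt is None or set(alt) - set("ACGTNacgtn"):
                    stats["malformed"] += 1
                    logger.warning("skipping non-sequence ALT %r at %s:%s", alt, rec.chrom, rec.pos)
                    continue
                if file_samples:
                    carriers = []
                    for sname in file_samples:
                        gt = rec.samples[sname].get("GT")
                        if gt is None or all(a is None for a in gt):
                            carriers.append(sname)  # no genotype: assign to all
                        elif (i + 1) in gt:
                            carriers.append(sname)
                else:
                    carriers = [default_sample]
                for sname in carriers:
                    try:
                        yield make_record(sname, rec.chrom, rec.pos, rec.ref, alt)
                    except ValueError:
                        stats["malformed"] += 1
                        logger.warning(
                            "skipping non-mutation %s>%s at %s:%s", rec.ref, alt, rec.chrom, rec.pos
                        )


def _read_maf(path: Path, stats: Counter) -> Iterator[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {path} missing required columns: {missing}")
    for row in df.itertuples(index=False):
        try:
            yield make_record(
                getattr(row, "Tumor_Sample_Barcode"),
                getattr(row, "Chromosome"),
                int(getattr(row, "Start_Position")),
                getattr(row, "Reference_Allele"),
                getattr(row, "Tumor_Seq_Allele2"),
            )
        except (ValueError, TypeError):
            stats["malformed"] += 1
            logger.warning("skipping malformed MAF row in %s", path)


def read_catalogue(
    paths: Iterable[str | Path],
    format: str = "auto",
    stats: Counter | None = None,
) -> list[MutationRecord]:
    """Read one or more VCF/MAF files into normalized records.

    ``format`` is ``vcf``, ``maf`` or ``auto`` (by file extension).  In
    one-VCF-per-sample mode (a VCF without sample columns) the sample name is
    the file name stem; multi-sample VCFs assign records per genotype; MAF
    uses ``Tumor_Sample_Barcode``.  Duplicate identical records within a
    sample are counted once (logged).
    """
    stats = stats if stats is not None else Counter()
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    for path in paths:
        path = Path(path)
        fmt = format
        if fmt == "auto":
            low = path.name.lower()
            fmt = "maf" if (low.endswith(".maf") or low.endswith(".maf.gz")) else "vcf"
        reader = _read_vcf if fmt == "vcf" else _read_maf
        for rec in reader(path, stats):
            key = (rec.sample, rec.chromosome, rec.position, rec.ref, rec.alt)
            if key in seen:
                stats["duplicate"] += 1
                continue
            seen.add(key)
            records.append(rec)
            stats["read"] += 1
    if stats["duplicate"]:
        logger.info("dropped %d duplicate records", stats["duplicate"])
    return records


def merge_adjacent_sbs(
    records: Iterable[MutationRecord],
    enabled: bool = True,
    stats: Counter | None = None,
) -> list[MutationRecord]:
    """Merge pairs of same-sample SBS records at consecutive positions into a
    single DBS record (a true doublet is one event, not two coincidental
    substitutions).  Runs of three or more adjacent SBSs are left as
    individual SBS records with a logged notice.
    """
    stats = stats if stats is not None else Counter()
    records = list(records)
    if not enabled:
        return records
    groups: dict[tuple[str, str], list[MutationRecord]] = defaultdict(list)
    order: list[MutationRecord] = []
    for rec in records:
        if rec.event_class == SBS:
            groups[(rec.sample, rec.chromosome)].append(rec)
        order.append(rec)

    merged: dict[int, MutationRecord] = {}
    drop: set[int] = set()
    for (_, _), group in groups.items():
        group.sort(key=lambda r: r.position)
        i = 0
        while i < len(group):
            j = i
            while j + 1 < len(group) and group[j + 1].position == group[j].position + 1:
                j += 1
            run = group[i : j + 1]
            if len(run) == 2:
                a, b = run
                dbs = MutationRecord(
                    sample=a.sample,
                    chromosome=a.chromosome,
                    position=a.position,
                    ref=a.ref + b.ref,
                    alt=a.alt + b.alt,
                    event_class=DBS,
                )
                merged[id(a)] = dbs
                drop.add(id(b))
                stats["sbs_pairs_merged"] += 1
            elif len(run) >= 3:
                stats["adjacent_run_unmerged"] += 1
                logger.info(
                    "run of %d adjacent SBSs at %s:%d left unmerged",
                    len(run), run[0].chromosome, run[0].position,
                )
            i = j + 1

    out = []
    for rec in order:
        if id(rec) in drop:
            continue
        out.append(merged.get(id(rec), rec))
    return out


def partition_by_chromosome(
    records: Iterable[MutationRecord],
    build: GenomeBuild,
    workdir: str | Path,
    stats: Counter | None = None,
) -> list[Path]:
    """Write one position-sorted TSV per build chromosome that has records.

    Columns: sample, position, ref, alt, event_class.  Records on chromosomes
    absent from the build are dropped (logged, counted).  Files are returned
    in build-manifest chromosome order.
    """
    stats = stats if stats is not None else Counter()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    known = set(build.chromosome_names())
    per_chrom: dict[str, list[MutationRecord]] = defaultdict(list)
    for rec in records:
        if rec.chromosome not in known:
            stats["unknown_chromosome"] += 1
            continue
        per_chrom[rec.chromosome].append(rec)
    if stats["unknown_chromosome"]:
        logger.warning(
            "dropped %d records on chromosomes absent from the build",
            stats["unknown_chromosome"],
        )
    paths = []
    for chrom in build.chromosome_names():
        if chrom not in per_chrom:
            continue
        rows = sorted(
            per_chrom[chrom], key=lambda r: (r.position, r.sample, r.ref, r.alt)
        )
        path = workdir / f"{chrom}.tsv"
        with open(path, "w") as fh:
            fh.write("sample\tposition\tref\talt\tevent_class\n")
            for r in rows:
                fh.write(
                    f"{r.sample}\t{r.position}\t{r.ref or '-'}\t{r.alt or '-'}\t{r.event_class}\n"
                )
        paths.append(path)
    return paths


def read_partition(path: str | Path) -> list[MutationRecord]:
    """Read back one per-chromosome intermediate file."""
    path = Path(path)
    chrom = path.stem
    out = []
    for ln in path.read_text().splitlines()[1:]:
        sample, pos, ref, alt, ec = ln.split("\t")
        out.append(
            MutationRecord(
                sample=sample,
                chromosome=chrom,
                position=int(pos),
                ref="" if ref == "-" else ref,
                alt="" if alt == "-" else alt,
                event_class=ec,
            )
        )
    return out
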