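"""Matrix accumulation, collapse chains, region subsetting, strand-bias test.

The pipeline accumulates counts at the finest resolution of each event class
while streaming one chromosome at a time (SBS-6144, strand-labeled
tetranucleotide DBS, strand-labeled ID plus the sequence-extended ID
channels), then iteratively collapses to every coarser classification:

    SBS-6144 -> SBS-1536 -> SBS-96 -> SBS-6
             -> SBS-384  -> SBS-24 -> SBS-6
    DBS-2976 -> DBS-1248
             -> DBS-186  -> DBS-78
    ID-415   -> ID-83    -> ID-28      (ID-8628 -> ID-83 as a cross-check)

Events whose context window is unavailable (chromosome edge or N) are routed
to the context-free levels only (SBS-24/6, DBS-186/78); the run log records
these exclusions so every collapse conserves counts up to the ledger.
"""
from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from . import dbs as _dbs
from . import indels as _indels
from . import sbs as _sbs
from . import variant_io as vio
from .reference import GenomeBuild
from .util import ClassificationError
from .variant_io import MutationRecord

logger = logging.getLogger(__name__)

#: the Table-1 output inventory: fourteen matrices
SCHEMES = (
    "SBS6", "SBS24", "SBS96", "SBS384", "SBS1536", "SBS6144",
    "DBS78", "DBS186", "DBS1248", "DBS2976",
    "ID28", "ID83", "ID415", "ID8628",
)

PLOTTABLE_SCHEMES = (
    "SBS6", "SBS24", "SBS96", "SBS384", "SBS1536",
    "DBS78", "DBS186", "ID28", "ID83", "ID415",
)


def channels(scheme: str) -> list[str]:
    """The ordered channel list of a classification scheme."""
    if scheme.startswith("SBS"):
        return _sbs.enumerate_channels(scheme)
    if scheme.startswith("DBS"):
        return _dbs.enumerate_channels(scheme)
    if scheme.startswith("ID"):
        return _indels.enumerate_channels(scheme)
    raise KeyError(f"unknown scheme {scheme!r}")


#: (parent, child) -> channel-label map
_COLLAPSE_MAPS = {
    ("SBS6144", "SBS1536"): _sbs.strip_strand,
    ("SBS6144", "SBS384"): _sbs.trim_flanks,
    ("SBS1536", "SBS96"): _sbs.trim_flanks,
    ("SBS384", "SBS24"): _sbs.trim_flanks,
    ("SBS96", "SBS6"): _sbs.trim_flanks,
    ("SBS24", "SBS6"): _sbs.strip_strand,
    ("DBS2976", "DBS1248"): _dbs.strip_strand,
    ("DBS2976", "DBS186"): _dbs.trim_flanks,
    ("DBS186", "DBS78"): _dbs.strip_strand,
    ("ID415", "ID83"): _indels.strip_strand,
    ("ID8628", "ID83"): _indels.strip_motif,
    ("ID83", "ID28"): _indels.id28_label,
}


def empty_matrix(scheme: str, samples: Sequence[str]) -> pd.DataFrame:
    df = pd.DataFrame(
        0, index=pd.Index(channels(scheme), name="MutationType"),
        columns=sorted(samples), dtype="int64",
    )
    return df


def counts_to_matrix(
    counts: Counter, scheme: str, samples: Sequence[str]
) -> pd.DataFrame:
    df = empty_matrix(scheme, samples)
    for (label, sample), n in counts.items():
        df.loc[label, sample] += n
    return df


def collapse(matrix: pd.DataFrame, scheme_from: str, scheme_to: str) -> pd.DataFrame:
    """Collapse a matrix to the next coarser scheme by summing each child
    channel's parent cells; the defined parent→child pairs partition the
    parent channels."""
    key = (scheme_from, scheme_to)
    if key not in _COLLAPSE_MAPS:
        raise KeyError(f"no collapse defined from {scheme_from} to {scheme_to}")
    fn = _COLLAPSE_MAPS[key]
    mapped = matrix.groupby([fn(c) for c in matrix.index]).sum()
    out = mapped.reindex(channels(scheme_to), fill_value=0)
    out.index.name = "MutationType"
    return out.astype("int64")


# ---- region subsetting ---------------------------------------------------

def _trees_from_intervals(
    intervals: dict[str, list[tuple[int, int]]]
) -> dict[str, IntervalTree]:
    """1-based inclusive intervals -> interval trees (internally half-open)."""
    trees = {}
    for chrom, ivs in intervals.items():
        tree = IntervalTree()
        for start, end in ivs:
            if end >= start:
                tree[start : end + 1] = True
        trees[chrom] = tree
    return trees


def read_bed(path: str | Path, build: GenomeBuild) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open, the BED standard) into per
    chromosome interval trees keyed by normalized names; intervals on
    chromosomes unknown to the build are ignored with a warning."""
    from .reference import normalize_chrom

    known = set(build.chromosome_names())
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        cols = ln.split("\t")
        chrom = normalize_chrom(cols[0])
        if chrom not in known:
            logger.warning("ignoring BED interval on unknown chromosome %r", cols[0])
            continue
        start, end = int(cols[1]), int(cols[2])
        if end > start:
            trees[chrom][start + 1 : end + 1] = True  # convert to 1-based inclusive
    return dict(trees)


def subset_records(
    records: Iterable[MutationRecord],
    trees: dict[str, IntervalTree],
    stats: Counter | None = None,
) -> list[MutationRecord]:
    """Keep records whose first affected position falls in the region set."""
    stats = stats if stats is not None else Counter()
    kept = []
    for rec in records:
        tree = trees.get(rec.chromosome)
        if tree is not None and tree[rec.position]:
            kept.append(rec)
        else:
            stats["outside_region"] += 1
    return kept


def exome_trees(build: GenomeBuild) -> dict[str, IntervalTree]:
    return _trees_from_intervals(build.exon_intervals())


# ---- accumulation --------------------------------------------------------

FINEST = ("SBS6144", "SBS24", "DBS2976", "DBS186", "ID415", "ID8628")


def accumulate(
    build: GenomeBuild,
    partition_files: Sequence[Path],
    stats: Counter | None = None,
) -> dict[str, Counter]:
    """Stream per-chromosome record files and count events at the finest
    resolution.  Exactly one chromosome's encoded data is resident at a time.

    Returns counters keyed by (channel label, sample) for each finest scheme;
    drops and exclusions are tallied in ``stats``.
    """
    stats = stats if stats is not None else Counter()
    counts: dict[str, Counter] = {s: Counter() for s in FINEST}
    for path in partition_files:
        records = vio.read_partition(path)
        if not records:
            continue
        ec = build.load_chromosome(records[0].chromosome)
        seq = ec.seq
        for rec in records:
            if not 1 <= rec.position <= len(ec):
                stats["off_chromosome"] += 1
                continue
            try:
                _classify_one(rec, seq, ec, counts, stats)
            except ClassificationError as err:
                stats[err.reason] += 1
                logger.warning(
                    "dropping %s %s:%d %s>%s (%s)",
                    rec.sample, rec.chromosome, rec.position,
                    rec.ref or "-", rec.alt or "-", err.reason,
                )
    return counts


def _classify_one(rec, seq, ec, counts, stats):
    if rec.event_class == vio.SBS:
        level, label = _sbs.classify_sbs(
            seq, ec.state(rec.position), rec.position, rec.ref, rec.alt
        )
        counts[level][(label, rec.sample)] += 1
        if level == "SBS24":
            stats["sbs_context_unavailable"] += 1
    elif rec.event_class == vio.DBS:
        if rec.position + 1 > len(ec):
            stats["off_chromosome"] += 1
            return
        level, label = _dbs.classify_dbs(
            seq, ec.state(rec.position), rec.position, rec.ref, rec.alt
        )
        counts[level][(label, rec.sample)] += 1
        if level == "DBS186":
            stats["dbs_context_unavailable"] += 1
    elif rec.event_class in (vio.ID_INS, vio.ID_DEL):
        kind = _indels.INS if rec.event_class == vio.ID_INS else _indels.DEL
        motif = rec.alt if kind == _indels.INS else rec.ref
        event = _indels.IndelEvent(kind, rec.chromosome, rec.position, motif)
        if len(motif) >= _indels.LONG_INDEL_NOTICE:
            stats["long_indel"] += 1
            logger.info("indel of length %d at %s:%d classified in the 5+ bin",
                        len(motif), rec.chromosome, rec.position)
        stranded, _core, extended = _indels.classify_indel(seq, ec.state, event)
        counts["ID415"][(stranded, rec.sample)] += 1
        counts["ID8628"][(extended, rec.sample)] += 1
    else:
        stats["complex"] += 1


def assemble_matrices(
    counts: dict[str, Counter], samples: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Collapse finest counters into the full fourteen-matrix inventory."""
    samples = sorted(samples)
    m: dict[str, pd.DataFrame] = {}
    m["SBS6144"] = counts_to_matrix(counts["SBS6144"], "SBS6144", samples)
    m["SBS1536"] = collapse(m["SBS6144"], "SBS6144", "SBS1536")
    m["SBS384"] = collapse(m["SBS6144"], "SBS6144", "SBS384")
    m["SBS96"] = collapse(m["SBS1536"], "SBS1536", "SBS96")
    m["SBS24"] = collapse(m["SBS384"], "SBS384", "SBS24") + counts_to_matrix(
        counts["SBS24"], "SBS24", samples
    )
    m["SBS6"] = collapse(m["SBS24"], "SBS24", "SBS6")
    m["DBS2976"] = counts_to_matrix(counts["DBS2976"], "DBS2976", samples)
    m["DBS1248"] = collapse(m["DBS2976"], "DBS2976", "DBS1248")
    m["DBS186"] = collapse(m["DBS2976"], "DBS2976", "DBS186") + counts_to_matrix(
        counts["DBS186"], "DBS186", samples
    )
    m["DBS78"] = collapse(m["DBS186"], "DBS186", "DBS78")
    m["ID415"] = counts_to_matrix(counts["ID415"], "ID415", samples)
    m["ID83"] = collapse(m["ID415"], "ID415", "ID83")
    m["ID28"] = collapse(m["ID83"], "ID83", "ID28")
    m["ID8628"] = counts_to_matrix(counts["ID8628"], "ID8628", samples)
    return m


def write_matrices(
    matrices: dict[str, pd.DataFrame], out_dir: str | Path, project: str
) -> list[Path]:
    """Write one TSV per scheme as ``output/<class>/<project>.<scheme>.all``."""
    out_dir = Path(out_dir)
    paths = []
    for scheme, df in matrices.items():
        family = "SBS" if scheme.startswith("SBS") else (
            "DBS" if scheme.startswith("DBS") else "ID"
        )
        subdir = out_dir / family
        subdir.mkdir(parents=True, exist_ok=True)
        path = subdir / f"{project}.{scheme}.all"
        df.to_csv(path, sep="\t", lineterminator="\n")
        paths.append(path)
    return paths


# ---- strand bias ---------------------------------------------------------

_TSB_SOURCES = {  # strand-labeled scheme -> core scheme reported
    "SBS384": "SBS96",
    "DBS186": "DBS78",
    "ID415": "ID83",
}


def strand_bias_test(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Exact two-sided binomial test of transcribed vs untranscribed counts
    (p = 1/2) per channel core per sample, with Benjamini-Hochberg FDR
    adjustment within each (sample, scheme) family.  B/N/Q counts are not
    part of the test; channels with T+U == 0 are skipped."""
    rows = []
    for scheme, core_scheme in _TSB_SOURCES.items():
        if scheme not in matrices:
            continue
        df = matrices[scheme]
        strands = pd.Series([lbl.split(":", 1)[0] for lbl in df.index], index=df.index)
        cores = pd.Series([lbl.split(":", 1)[1] for lbl in df.index], index=df.index)
        t = df[strands == "T"].groupby(cores[strands == "T"].values).sum()
        u = df[strands == "U"].groupby(cores[strands == "U"].values).sum()
        for sample in df.columns:
            for core in t.index:
                tc = int(t.loc[core, sample])
                uc = int(u.loc[core, sample]) if core in u.index else 0
                if tc + uc == 0:
                    continue
                p = binomtest(tc, tc + uc, 0.5).pvalue
                rows.append(
                    {
                        "scheme": core_scheme,
                        "channel": core,
                        "sample": sample,
                        "transcribed": tc,
                        "untranscribed": uc,
                        "p_value": p,
                    }
                )
    result = pd.DataFrame(
        rows,
        columns=["scheme", "channel", "sample", "transcribed", "untranscribed", "p_value"],
    )
    result["q_value"] = 1.0
    for (_, _), idx in result.groupby(["sample", "scheme"]).groups.items():
        result.loc[idx, "q_value"] = multipletests(
            result.loc[idx, "p_value"], method="fdr_bh"
        )[1]
    return result


# ---- top-level pipeline --------------------------------------------------

def generate_matrices(
    project: str,
    input_paths: str | Path | Sequence[str | Path],
    build: GenomeBuild | str | Path,
    out_dir: str | Path,
    input_format: str = "auto",
    merge_dbs: bool = True,
    exome: bool = False,
    bed: str | Path | None = None,
    per_chromosome: bool = False,
    tsb_test: bool = False,
    workdir: str | Path | None = None,
) -> dict:
    """Run the full catalogue-to-matrices pipeline.

    Returns a dict with ``matrices`` (scheme -> DataFrame), ``paths`` (the
    fourteen written matrix files), ``partition_files``, ``stats`` (drop and
    exclusion counts), and optionally ``strand_bias`` and
    ``per_chromosome`` (chromosome -> scheme -> DataFrame).
    """
    if not isinstance(build, GenomeBuild):
        build = GenomeBuild.load(build)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    workdir = Path(workdir) if workdir else out_dir / "intermediate"

    if isinstance(input_paths, (str, Path)) and Path(input_paths).is_dir():
        input_paths = sorted(
            p
            for p in Path(input_paths).iterdir()
            if p.suffix.lower() in (".vcf", ".maf") or p.name.lower().endswith(".vcf.gz")
        )
    elif isinstance(input_paths, (str, Path)):
        input_paths = [input_paths]

    stats: Counter = Counter()
    records = vio.read_catalogue(input_paths, format=input_format, stats=stats)
    samples = sorted({r.sample for r in records})
    records = vio.merge_adjacent_sbs(records, enabled=merge_dbs, stats=stats)

    if exome and bed:
        raise ValueError("choose either exome mode or a BED file, not both")
    if exome:
        trees = exome_trees(build)
        if not trees:
            raise ValueError("exome mode requires exon intervals in the annotation")
        records = subset_records(records, trees, stats)
    elif bed:
        records = subset_records(records, read_bed(bed, build), stats)

    partition_files = vio.partition_by_chromosome(records, build, workdir, stats)

    result: dict = {"partition_files": partition_files, "stats": stats}
    if per_chromosome:
        per_chrom: dict[str, dict[str, pd.DataFrame]] = {}
        totals: dict[str, Counter] = {s: Counter() for s in FINEST}
        for path in partition_files:
            counts = accumulate(build, [path], stats)
            per_chrom[path.stem] = assemble_matrices(counts, samples)
            for s in FINEST:
                totals[s].update(counts[s])
        counts = totals
        result["per_chromosome"] = per_chrom
        for chrom, mats in per_chrom.items():
            write_matrices(mats, out_dir / "chromosomes" / chrom, project)
    else:
        counts = accumulate(build, partition_files, stats)

    matrices = assemble_matrices(counts, samples)
    result["matrices"] = matrices
    result["paths"] = write_matrices(matrices, out_dir, project)

    if tsb_test:
        sb = strand_bias_test(matrices)
        tsb_dir = out_dir / "TSB"
        tsb_dir.mkdir(parents=True, exist_ok=True)
        sb.to_csv(tsb_dir / f"{project}.strand_bias.tsv", sep="\t", index=False)
        result["strand_bias"] = sb

    log = {k: int(v) for k, v in sorted(stats.items())}
    (out_dir / f"{project}.run_log.json").write_text(json.dumps(log, indent=1))
    logger.info("run log: %s", log)
    return result
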