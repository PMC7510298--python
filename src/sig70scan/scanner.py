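"""Genome-scale promoter prediction.

Pipeline: extract intergenic regions from an annotated genome, enumerate
-35/spacer/-10 candidate windows on both strands over a spacer range,
score every candidate with the classifier, keep candidates passing the
empirical p-value cutoff (default 2e-4), collapse overlapping same-strand
survivors to the best candidate, and write GFF3/BED/TSV.

Coordinate conventions, stated bit-exactly: internal and BED coordinates
are 0-based half-open on the forward strand; GFF3 output is 1-based
inclusive (a site starting at internal coordinate 912 is written with GFF3
start 913).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import seqcore
from .datasets import CANDIDATE, PromoterSite
from .intervals import Interval, complement_intervals
from .neuralmodel import TrainedClassifier
from .significance import DEFAULT_P_CUTOFF, NullDistribution, significance_filter

logger = logging.getLogger(__name__)

#: Canonical sigma-70 spacer range scanned by default, centred on 17 nt.
DEFAULT_SPACER_RANGE = (15, 19)
DEFAULT_MERGE_DISTANCE = 5

#: Annotation feature types treated as genic when extracting intergenic space.
GENIC_FEATURE_TYPES = frozenset({"gene", "CDS"})


class ScanError(ValueError):
    """Raised for unresolvable genome/annotation input."""


@dataclass(frozen=True)
class GenomicRegion:
    """A forward-strand slice of a contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ScanError(f"invalid region {self.contig}:{self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start:
            raise ScanError(
                f"region {self.contig}:{self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != span"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Prediction:
    """A scored (and optionally p-valued) candidate promoter site."""

    site: PromoterSite
    score: float
    p: Optional[float] = None
    region_id: str = ""

    def with_p(self, p: float) -> "Prediction":
        return replace(self, p=p)


# ---------------------------------------------------------------------------
# Input readers


def read_genome_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Contig name -> uppercase sequence."""
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise ScanError(f"no sequences found in {path}")
    return genome


def read_annotation(
    path: Union[str, Path],
    fmt: Optional[str] = None,
    feature_types: Iterable[str] = GENIC_FEATURE_TYPES,
) -> Dict[str, List[Interval]]:
    """Genic intervals per contig from a GenBank or GFF3 file.

    Returns 0-based half-open intervals for the requested feature types.
    Format is inferred from the suffix when *fmt* is None.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "genbank" if suffix in (".gb", ".gbk", ".gbff", ".genbank") else "gff3"
    types = set(feature_types)
    out: Dict[str, List[Interval]] = {}
    if fmt == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            ivs = [
                (int(f.location.start), int(f.location.end))
                for f in rec.features
                if f.type in types
            ]
            out.setdefault(rec.id, []).extend(ivs)
    elif fmt == "gff3":
        import pyranges

        df = pyranges.read_gff3(str(path)).df
        df = df[df["Feature"].isin(types)]
        for contig, grp in df.groupby("Chromosome", observed=True):
            out.setdefault(str(contig), []).extend(
                zip(grp["Start"].astype(int), grp["End"].astype(int))
            )
    else:
        raise ScanError(f"unknown annotation format {fmt!r}")
    return out


# ---------------------------------------------------------------------------
# Intergenic extraction


def extract_intergenic(
    genome: Mapping[str, str],
    annotation: Mapping[str, Sequence[Interval]],
    min_length: int = 1,
) -> List[GenomicRegion]:
    """Maximal regions of each contig not covered by any annotated feature.

    Contig ends before the first and after the last feature are included;
    regions shorter than *min_length* are dropped. Annotation referring to
    contigs absent from the genome is an error (naming the contigs).
    """
    unknown = sorted(set(annotation) - set(genome))
    if unknown:
        raise ScanError(f"annotation contigs not found in genome: {unknown}")
    regions: List[GenomicRegion] = []
    for contig in genome:
        seq = genome[contig]
        for a, b in complement_intervals(len(seq), annotation.get(contig, [])):
            if b - a >= min_length:
                regions.append(GenomicRegion(contig, a, b, seq[a:b]))
    return regions


# ---------------------------------------------------------------------------
# Candidate enumeration


def enumerate_candidates(
    region: GenomicRegion,
    spacer_range: Tuple[int, int] = DEFAULT_SPACER_RANGE,
) -> List[PromoterSite]:
    """Every -35/spacer/-10 window on both strands of *region*.

    For each spacer s in the inclusive range, each window of length 12+s
    yields one candidate per strand: the first six window bases (5'->3' on
    that strand) are the -35 box, the last six the -10 box. Windows with
    non-ACGT characters are skipped. Coordinates are forward-strand
    half-open regardless of strand. A region too short for the smallest
    window yields an empty list.
    """
    lo, hi = spacer_range
    if hi < lo:
        raise ScanError(f"empty spacer range {spacer_range}")
    seq = region.sequence.upper()
    out: List[PromoterSite] = []
    for spacer in range(lo, hi + 1):
        w = 12 + spacer
        for i in range(0, len(seq) - w + 1):
            window = seq[i : i + w]
            if not seqcore.is_acgt(window):
                continue
            start = region.start + i
            for strand in "+-":
                oriented = window if strand == "+" else seqcore.reverse_complement(window)
                out.append(
                    PromoterSite(
                        pair=seqcore.BoxPair(oriented[:6], oriented[-6:]),
                        spacer_length=spacer,
                        source_id=f"{region.contig}:{start}-{start + w}({strand})",
                        contig=region.contig,
                        start=start,
                        end=start + w,
                        strand=strand,
                        label=CANDIDATE,
                    )
                )
    return out


def candidate_count(length: int, spacer_range: Tuple[int, int] = DEFAULT_SPACER_RANGE) -> int:
    """Closed-form candidate count for an ACGT-clean region of *length* nt:
    sum over spacers of 2 * max(0, L - 12 - s + 1)."""
    lo, hi = spacer_range
    return sum(2 * max(0, length - 12 - s + 1) for s in range(lo, hi + 1))


# ---------------------------------------------------------------------------
# Scanning


def _merge_overlaps(preds: List[Prediction], merge_distance: int) -> List[Prediction]:
    """Collapse same-strand survivors with midpoints within *merge_distance*
    nt to the best (lowest-p, then highest-score) candidate."""
    def sort_key(p: Prediction):
        return (p.site.contig, p.site.strand, (p.site.start + p.site.end) / 2)

    kept: List[Prediction] = []
    for pred in sorted(preds, key=sort_key):
        if kept:
            last = kept[-1]
            same = (
                last.site.contig == pred.site.contig
                and last.site.strand == pred.site.strand
            )
            mid_last = (last.site.start + last.site.end) / 2
            mid_new = (pred.site.start + pred.site.end) / 2
            if same and abs(mid_new - mid_last) <= merge_distance:
                better = (pred.p, -pred.score) < (last.p, -last.score)
                if better:
                    kept[-1] = pred
                continue
        kept.append(pred)
    return kept


def scan_genome(
    model: TrainedClassifier,
    null: NullDistribution,
    genome: Mapping[str, str],
    annotation: Mapping[str, Sequence[Interval]],
    spacer_range: Tuple[int, int] = DEFAULT_SPACER_RANGE,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    min_region_length: int = 1,
    batch_size: int = 8192,
) -> List[Prediction]:
    """Predict promoters in the intergenic regions of *genome*.

    Streams region by region: enumerate candidates, score in bounded
    batches, keep candidates with empirical p <= *p_cutoff*, collapse
    overlapping same-strand survivors, and return predictions sorted by
    (contig, start, strand). The model and null fingerprints must match.
    """
    if not genome:
        raise ScanError("empty genome")
    if model.fingerprint != null.model_fingerprint:
        raise ScanError(
            "null distribution was built for different model weights; "
            "rebuild the null"
        )
    survivors: List[Prediction] = []
    for region in extract_intergenic(genome, annotation, min_region_length):
        candidates = enumerate_candidates(region, spacer_range)
        region_id = f"{region.contig}:{region.start}-{region.end}"
        for start in range(0, len(candidates), batch_size):
            chunk = candidates[start : start + batch_size]
            scores = model.score([c.pair for c in chunk])
            preds = [
                Prediction(site=c, score=float(s), region_id=region_id)
                for c, s in zip(chunk, np.atleast_1d(scores))
            ]
            survivors.extend(significance_filter(preds, null, p_cutoff))
    merged = _merge_overlaps(survivors, merge_distance)
    merged.sort(key=lambda p: (p.site.contig, p.site.start, p.site.strand))
    logger.info("scan: %d predictions at p <= %g", len(merged), p_cutoff)
    return merged


# ---------------------------------------------------------------------------
# Output writers

PREDICTION_COLUMNS = [
    "contig", "start", "end", "strand", "score", "p_value",
    "box35", "box10", "spacer_length", "region_id",
]


def predictions_to_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    rows = [
        {
            "contig": p.site.contig,
            "start": p.site.start,
            "end": p.site.end,
            "strand": p.site.strand,
            "score": p.score,
            "p_value": p.p,
            "box35": p.site.pair.box35,
            "box10": p.site.pair.box10,
            "spacer_length": p.site.spacer_length,
            "region_id": p.region_id,
        }
        for p in predictions
    ]
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_predictions(
    predictions: Sequence[Prediction],
    fmt: str,
    destination: Union[str, Path],
    source: str = "sig70scan",
) -> None:
    """Write predictions as GFF3 (1-based inclusive), BED (0-based
    half-open) or TSV (all fields; read back with
    :func:`read_predictions_tsv` for an exact round trip)."""
    dest = Path(destination)
    if fmt == "tsv":
        predictions_to_frame(predictions).to_csv(dest, sep="\t", index=False)
    elif fmt == "bed":
        with open(dest, "w") as fh:
            fh.write('track name="sig70_promoters"\n')
            for i, p in enumerate(predictions):
                bed_score = int(round(1000 * p.score))
                fh.write(
                    f"{p.site.contig}\t{p.site.start}\t{p.site.end}\t"
                    f"promoter_{i}\t{bed_score}\t{p.site.strand}\n"
                )
    elif fmt == "gff3":
        with open(dest, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, p in enumerate(predictions):
                attrs = (
                    f"ID=promoter_{i};p_value={p.p:.3g};box35={p.site.pair.box35};"
                    f"box10={p.site.pair.box10};spacer={p.site.spacer_length}"
                    if p.p is not None
                    else f"ID=promoter_{i};box35={p.site.pair.box35};"
                    f"box10={p.site.pair.box10};spacer={p.site.spacer_length}"
                )
                fh.write(
                    f"{p.site.contig}\t{source}\tpromoter\t{p.site.start + 1}\t"
                    f"{p.site.end}\t{p.score:.6f}\t{p.site.strand}\t.\t{attrs}\n"
                )
    else:
        raise ScanError(f"unknown output format {fmt!r}; use gff3, bed, or tsv")


def read_predictions_tsv(path: Union[str, Path]) -> List[Prediction]:
    """Inverse of the TSV writer; coordinates round-trip exactly."""
    df = pd.read_csv(path, sep="\t")
    preds = []
    for _, row in df.iterrows():
        site = PromoterSite(
            pair=seqcore.BoxPair(row["box35"], row["box10"]),
            spacer_length=int(row["spacer_length"]),
            source_id=str(row["region_id"]),
            contig=str(row["contig"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            label=CANDIDATE,
        )
        p = row["p_value"]
        preds.append(
            Prediction(
                site=site,
                score=float(row["score"]),
                p=None if pd.isna(p) else float(p),
                region_id=str(row["region_id"]),
            )
        )
    return preds
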