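"""Labelled promoter datasets: construction, loading, synthesis, QC.

A dataset is an ordered collection of :class:`PromoterSite` records, each a
-35/-10 box pair with spacer length, provenance and a positive/negative
label. Sources supported: GenBank records annotated with minus_35_signal /
minus_10_signal features, delimited site tables (supplementary-file style),
background sampling from intergenic genome regions, and a seeded synthetic
generator that emulates the statistics of the curated Pseudomonas set
(~170 positives at ~47% GC and ~5.6/12 mean pairwise box conservation;
background at ~61% GC, conservation near the 3/12 random-sequence level).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from . import seqcore
from .intervals import Interval, complement_intervals
from .seqcore import BoxPair, SequenceError

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
CANDIDATE = "candidate"

#: Canonical sigma-70 spacer length (nt between -35 box end and -10 box start).
DEFAULT_SPACER = 17

#: Calibrated defaults for the synthetic generator (see docs/methods.md):
#: each box position emits the consensus base with probability
#: CONSENSUS_WEIGHT, otherwise a draw from a background at POSITIVE_OFF_GC.
#: These jointly give expected positive conservation 5.6/12 and GC 47%.
CONSENSUS_WEIGHT = 0.5811
POSITIVE_OFF_GC = 0.8909
NEGATIVE_GC = 0.61


class DatasetError(ValueError):
    """Raised for structurally invalid datasets or configs."""


@dataclass(frozen=True)
class PromoterSite:
    """One candidate or labelled promoter: boxes + spacer + provenance.

    ``start``/``end`` (when present) are 0-based half-open forward-strand
    coordinates spanning the -35 box through the -10 box, so
    ``end - start == 12 + spacer_length``.
    """

    pair: BoxPair
    spacer_length: int = DEFAULT_SPACER
    source_id: str = ""
    contig: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: str = "+"
    label: str = CANDIDATE

    def __post_init__(self) -> None:
        if self.spacer_length < 0:
            raise DatasetError(f"spacer_length must be >= 0, got {self.spacer_length}")
        if self.strand not in ("+", "-"):
            raise DatasetError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.label not in (POSITIVE, NEGATIVE, CANDIDATE):
            raise DatasetError(f"unknown label {self.label!r}")
        if (self.start is None) != (self.end is None):
            raise DatasetError("start and end must be given together")
        if self.start is not None:
            span = self.end - self.start
            expected = 12 + self.spacer_length
            if span != expected:
                raise DatasetError(
                    f"coordinate span {span} != 12 + spacer {expected} "
                    f"({self.contig}:{self.start}-{self.end})"
                )

    @property
    def twelve_mer(self) -> str:
        return self.pair.concatenated


class PromoterDataset:
    """Ordered collection of sites with label bookkeeping.

    Positive sites must be unique on their concatenated 12-mer — the feature
    the classifier actually sees — mirroring the uniqueness requirement of
    the curated promoter set.
    """

    def __init__(self, sites: Iterable[PromoterSite], *, dedup: bool = False):
        sites = list(sites)
        seen: Dict[str, PromoterSite] = {}
        kept: List[PromoterSite] = []
        for s in sites:
            if s.label == POSITIVE:
                key = s.twelve_mer
                if key in seen:
                    if dedup:
                        logger.warning(
                            "dropping duplicate positive 12-mer %s (%s)", key, s.source_id
                        )
                        continue
                    raise DatasetError(f"duplicate positive 12-mer {key}")
                seen[key] = s
            kept.append(s)
        self.sites: List[PromoterSite] = kept

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def positives(self) -> List[PromoterSite]:
        return [s for s in self.sites if s.label == POSITIVE]

    @property
    def negatives(self) -> List[PromoterSite]:
        return [s for s in self.sites if s.label == NEGATIVE]

    @property
    def positives_count(self) -> int:
        return len(self.positives)

    @property
    def negatives_count(self) -> int:
        return len(self.negatives)

    def feature_matrix(self) -> Tuple[np.ndarray, np.ndarray]:
        """One-hot features (n, 12, 4) and binary labels (n,) for training."""
        labelled = [s for s in self.sites if s.label in (POSITIVE, NEGATIVE)]
        X = seqcore.encode_batch([s.pair for s in labelled])
        y = np.array([1 if s.label == POSITIVE else 0 for s in labelled], dtype=np.int8)
        return X, y

    def subset(self, indices: Sequence[int]) -> "PromoterDataset":
        return PromoterDataset([self.sites[i] for i in indices])

    def spacer_lengths(self, label: str = POSITIVE) -> List[int]:
        return [s.spacer_length for s in self.sites if s.label == label]


# ---------------------------------------------------------------------------
# Train/test splitting


@dataclass(frozen=True)
class DatasetSplit:
    train: PromoterDataset
    test: PromoterDataset
    test_fraction: float
    seed: int


def stratified_split(
    data: PromoterDataset, test_fraction: float = 0.1, seed: int = 0
) -> DatasetSplit:
    """Random class-stratified split, default 9:1 train:test.

    Stratification keeps the class proportions of both partitions within one
    item of the input proportions — important when the positive class is two
    orders of magnitude smaller than the background.
    """
    from sklearn.model_selection import train_test_split

    if not 0.0 < test_fraction < 1.0:
        raise DatasetError(f"test_fraction must be in (0, 1), got {test_fraction}")
    _, y = data.feature_matrix()
    labelled_idx = [i for i, s in enumerate(data.sites) if s.label in (POSITIVE, NEGATIVE)]
    for cls, cnt in zip((POSITIVE, NEGATIVE), (data.positives_count, data.negatives_count)):
        if cnt < 2:
            raise DatasetError(f"class {cls!r} has {cnt} members; need >= 2 to split")
    train_idx, test_idx = train_test_split(
        labelled_idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    return DatasetSplit(
        train=data.subset(sorted(train_idx)),
        test=data.subset(sorted(test_idx)),
        test_fraction=test_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic generation


def base_probabilities_from_gc(gc: float) -> np.ndarray:
    """Per-base probabilities (A,C,G,T order) with G=C=gc/2, A=T=(1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise DatasetError(f"gc must be in (0, 1), got {gc}")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def consensus_pwm(
    consensus: str = seqcore.CONSENSUS_35 + seqcore.CONSENSUS_10,
    consensus_weight: float = CONSENSUS_WEIGHT,
    off_gc: float = POSITIVE_OFF_GC,
) -> np.ndarray:
    """12 x 4 position probability matrix anchored on the consensus.

    Each position emits its consensus base with probability
    ``consensus_weight`` and otherwise draws from a background of GC fraction
    ``off_gc`` (the consensus base may be redrawn). Rows sum to 1.
    """
    cons = seqcore.clean_sequence(consensus, name="consensus")
    if len(cons) != seqcore.PAIR_LENGTH:
        raise DatasetError(f"consensus must be 12 nt, got {len(cons)}")
    if not 0.0 <= consensus_weight <= 1.0:
        raise DatasetError("consensus_weight must be in [0, 1]")
    bg = base_probabilities_from_gc(off_gc)
    pwm = np.tile((1 - consensus_weight) * bg, (seqcore.PAIR_LENGTH, 1))
    for i, ch in enumerate(cons):
        pwm[i, seqcore.ALPHABET.index(ch)] += consensus_weight
    return pwm


@dataclass
class SyntheticConfig:
    """Parameters of the seeded synthetic dataset generator.

    Defaults emulate the curated study conditions: 170 positives drawn from
    the consensus-anchored PWM (expected conservation 5.6/12, GC 47%) against
    16,000 background sites at 61% GC with a fixed 17 nt spacer.
    """

    n_positive: int = 170
    n_negative: int = 16000
    positive_pwm: Optional[np.ndarray] = None  # defaults to consensus_pwm()
    consensus_weight: float = CONSENSUS_WEIGHT
    negative_gc: float = NEGATIVE_GC
    spacer_distribution: Union[int, Sequence[int]] = DEFAULT_SPACER
    seed: int = 0

    def resolved_pwm(self) -> np.ndarray:
        pwm = (
            consensus_pwm(consensus_weight=self.consensus_weight)
            if self.positive_pwm is None
            else np.asarray(self.positive_pwm, dtype=float)
        )
        if pwm.shape != (seqcore.PAIR_LENGTH, 4):
            raise DatasetError(f"PWM must be 12 x 4, got {pwm.shape}")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise DatasetError("each PWM position must sum to 1 (+-1e-9)")
        if (pwm < 0).any():
            raise DatasetError("PWM probabilities must be non-negative")
        return pwm


def _sample_spacer(dist: Union[int, Sequence[int]], rng: np.random.Generator) -> int:
    if isinstance(dist, (int, np.integer)):
        return int(dist)
    dist = list(dist)
    return int(dist[rng.integers(len(dist))])


def _draw_kmer(probs_per_pos: np.ndarray, rng: np.random.Generator) -> str:
    cum = probs_per_pos.cumsum(axis=1)
    u = rng.random(probs_per_pos.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(seqcore.ALPHABET[j] for j in idx)


def synthesize_dataset(config: SyntheticConfig) -> PromoterDataset:
    """Draw a labelled dataset from the configured generative model.

    Positives are sampled position-wise from the PWM and deduplicated on the
    12-mer (bounded resampling); negatives are i.i.d. draws at the background
    GC. Bit-reproducible for a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    pwm = config.resolved_pwm()
    neg_bg = np.tile(base_probabilities_from_gc(config.negative_gc), (seqcore.PAIR_LENGTH, 1))

    sites: List[PromoterSite] = []
    seen: set = set()
    attempts = 0
    max_attempts = 100 * max(config.n_positive, 1)
    while len(seen) < config.n_positive:
        if attempts >= max_attempts:
            raise DatasetError(
                f"could not draw {config.n_positive} unique positives in "
                f"{max_attempts} attempts; PWM too concentrated"
            )
        attempts += 1
        kmer = _draw_kmer(pwm, rng)
        if kmer in seen:
            continue
        seen.add(kmer)
        sites.append(
            PromoterSite(
                pair=BoxPair.from_concatenated(kmer),
                spacer_length=_sample_spacer(config.spacer_distribution, rng),
                source_id=f"synthetic_pos_{len(seen) - 1}",
                label=POSITIVE,
            )
        )
    for i in range(config.n_negative):
        kmer = _draw_kmer(neg_bg, rng)
        sites.append(
            PromoterSite(
                pair=BoxPair.from_concatenated(kmer),
                spacer_length=_sample_spacer(config.spacer_distribution, rng),
                source_id=f"synthetic_neg_{i}",
                label=NEGATIVE,
            )
        )
    return PromoterDataset(sites)


# ---------------------------------------------------------------------------
# GenBank promoter extraction

MINUS_35 = "minus_35_signal"
MINUS_10 = "minus_10_signal"

#: Spacer window used to pair a -35 feature with its -10 partner.
DEFAULT_SPACER_WINDOW = (10, 25)


def _feature_box(record: SeqRecord, feature) -> Optional[str]:
    seq = str(feature.extract(record.seq)).upper()
    return seq if seqcore.is_acgt(seq) else None


def parse_genbank_promoters(
    records: Union[str, Path, Iterable[SeqRecord]],
    spacer_window: Tuple[int, int] = DEFAULT_SPACER_WINDOW,
) -> PromoterDataset:
    """Extract positive promoter sites from annotated GenBank records.

    Each minus_35_signal feature is paired with the nearest downstream
    (strand-aware) minus_10_signal on the same strand whose spacer falls in
    ``spacer_window``; each -10 feature is consumed at most once. Boxes are
    read 5'->3' on the coding strand, so minus-strand features come back
    reverse-complemented. Features with non-6-nt boxes, ambiguous bases, or
    no partner are skipped with a logged reason.
    """
    if isinstance(records, (str, Path)):
        records = SeqIO.parse(str(records), "genbank")

    sites: List[PromoterSite] = []
    lo, hi = spacer_window
    for record in records:
        f35 = [f for f in record.features if f.type == MINUS_35]
        f10 = [f for f in record.features if f.type == MINUS_10]
        used10: set = set()
        for feat35 in f35:
            strand = 1 if (feat35.location.strand or 1) >= 0 else -1
            s35, e35 = int(feat35.location.start), int(feat35.location.end)
            best = None
            for j, feat10 in enumerate(f10):
                if j in used10:
                    continue
                st10 = 1 if (feat10.location.strand or 1) >= 0 else -1
                if st10 != strand:
                    continue
                s10, e10 = int(feat10.location.start), int(feat10.location.end)
                # spacer measured 5'->3': -10 lies downstream of -35
                spacer = (s10 - e35) if strand == 1 else (s35 - e10)
                if lo <= spacer <= hi and (best is None or spacer < best[0]):
                    best = (spacer, j, s10, e10)
            if best is None:
                logger.info(
                    "%s: unpaired %s at %d..%d skipped", record.id, MINUS_35, s35, e35
                )
                continue
            spacer, j, s10, e10 = best
            box35 = _feature_box(record, feat35)
            box10 = _feature_box(record, f10[j])
            if box35 is None or box10 is None or len(box35) != 6 or len(box10) != 6:
                logger.info(
                    "%s: pair at %d..%d skipped (boxes not clean 6-mers)",
                    record.id, s35, e10,
                )
                continue
            used10.add(j)
            start = min(s35, s10)
            end = max(e35, e10)
            sites.append(
                PromoterSite(
                    pair=BoxPair(box35, box10),
                    spacer_length=spacer,
                    source_id=record.id,
                    contig=record.id,
                    start=start,
                    end=end,
                    strand="+" if strand == 1 else "-",
                    label=POSITIVE,
                )
            )
    if not sites:
        logger.warning("no promoter feature pairs found in GenBank input")
    return PromoterDataset(sites, dedup=True)


# ---------------------------------------------------------------------------
# Background sampling from intergenic regions


def sample_background(
    genome: Mapping[str, str],
    annotation: Mapping[str, Sequence[Interval]],
    n: int,
    spacer_distribution: Union[int, Sequence[int]] = DEFAULT_SPACER,
    seed: int = 0,
) -> PromoterDataset:
    """Draw *n* negative sites from intergenic stretches of *genome*.

    Positions and strands are sampled uniformly over the intergenic space;
    each draw takes a 6-mer + spacer + 6-mer window (spacer from
    ``spacer_distribution``). Windows crossing region ends or containing
    non-ACGT characters are rejected and resampled. Reproducible under
    *seed*; raises if the intergenic space cannot supply *n* sites.
    """
    unknown = set(annotation) - set(genome)
    if unknown:
        raise DatasetError(f"annotation contigs not in genome: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    regions: List[Tuple[str, int, int]] = []
    for contig, seq in genome.items():
        for a, b in complement_intervals(len(seq), annotation.get(contig, [])):
            regions.append((contig, a, b))
    total = sum(b - a for _, a, b in regions)
    if total < 12:
        raise DatasetError(
            f"insufficient intergenic sequence ({total} nt) to sample from"
        )
    weights = np.array([b - a for _, a, b in regions], dtype=float)
    weights /= weights.sum()

    sites: List[PromoterSite] = []
    attempts = 0
    max_attempts = max(1000, 200 * n)
    while len(sites) < n:
        if attempts >= max_attempts:
            raise DatasetError(
                f"drew only {len(sites)}/{n} background sites after "
                f"{max_attempts} attempts; intergenic space too small"
            )
        attempts += 1
        ridx = rng.choice(len(regions), p=weights)
        contig, a, b = regions[ridx]
        spacer = _sample_spacer(spacer_distribution, rng)
        w = 12 + spacer
        if b - a < w:
            continue
        start = int(rng.integers(a, b - w + 1))
        window = genome[contig][start : start + w].upper()
        if not seqcore.is_acgt(window):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            window = seqcore.reverse_complement(window)
        sites.append(
            PromoterSite(
                pair=BoxPair(window[:6], window[-6:]),
                spacer_length=spacer,
                source_id=f"bg_{len(sites)}",
                contig=contig,
                start=start,
                end=start + w,
                strand=strand,
                label=NEGATIVE,
            )
        )
    return PromoterDataset(sites)


# ---------------------------------------------------------------------------
# Delimited site tables (supplementary-file style)

REQUIRED_TABLE_COLUMNS = ("box35", "box10")


def load_site_table(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
    label: str = POSITIVE,
) -> PromoterDataset:
    """Load promoter sites from a delimited table (TSV/CSV).

    The table must provide -35 and -10 box columns; ``column_map`` renames
    table columns onto the expected names (box35, box10, optional
    spacer_length, source_id). Duplicate 12-mers are collapsed with a
    warning. An empty table yields an empty dataset with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(
            f"{path.name}: missing columns {missing}; expected at least "
            f"{list(REQUIRED_TABLE_COLUMNS)} (use column_map to rename)"
        )
    if df.empty:
        logger.warning("%s: empty site table", path.name)
        return PromoterDataset([])
    sites = []
    for i, row in df.iterrows():
        row_label = str(row["label"]) if "label" in df.columns else label
        sites.append(
            PromoterSite(
                pair=BoxPair(str(row["box35"]), str(row["box10"])),
                spacer_length=int(row.get("spacer_length", DEFAULT_SPACER)),
                source_id=str(row.get("source_id", f"{path.name}:{i}")),
                label=row_label,
            )
        )
    return PromoterDataset(sites, dedup=True)


def write_site_table(data: PromoterDataset, path: Union[str, Path]) -> None:
    """TSV inverse of :func:`load_site_table` (boxes, spacer, id, label)."""
    pd.DataFrame(
        {
            "box35": [s.pair.box35 for s in data.sites],
            "box10": [s.pair.box10 for s in data.sites],
            "spacer_length": [s.spacer_length for s in data.sites],
            "source_id": [s.source_id for s in data.sites],
            "label": [s.label for s in data.sites],
        }
    ).to_csv(path, sep="\t", index=False)


def write_fasta(data: PromoterDataset, path: Union[str, Path]) -> None:
    """Write each site's concatenated 12-mer with metadata in the header."""
    with open(path, "w") as fh:
        for i, s in enumerate(data.sites):
            fh.write(
                f">{s.source_id or f'site_{i}'} label={s.label} "
                f"spacer={s.spacer_length} strand={s.strand}\n{s.twelve_mer}\n"
            )


# ---------------------------------------------------------------------------
# QC report


@dataclass(frozen=True)
class QCReport:
    """The four dataset statistics used for QC, plus counts.

    GC means are fractions in [0,1]; conservation is mean pairwise positional
    identity out of 12. A missing class leaves its statistics as None.
    """

    positives_count: int
    negatives_count: int
    positive_gc: Optional[float]
    negative_gc: Optional[float]
    positive_conservation: Optional[float]
    negative_conservation: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "positives_count", "negatives_count",
                    "positive_gc", "negative_gc",
                    "positive_conservation", "negative_conservation",
                ],
                "value": [
                    self.positives_count, self.negatives_count,
                    self.positive_gc, self.negative_gc,
                    self.positive_conservation, self.negative_conservation,
                ],
            }
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _class_stats(sites: List[PromoterSite]) -> Tuple[Optional[float], Optional[float]]:
    if not sites:
        return None, None
    gc = float(np.mean([seqcore.gc_fraction(s.twelve_mer) for s in sites]))
    cons = (
        seqcore.mean_pairwise_conservation([s.pair for s in sites])
        if len(sites) >= 2
        else None
    )
    return gc, cons


def dataset_qc_report(data: PromoterDataset) -> QCReport:
    """Per-class GC means and mean pairwise box conservation.

    For a dataset resembling the curated study set this should show positives
    near 47% GC / 5.6 of 12 conserved and background near 61% GC / the 3.2 of
    12 level expected of compositionally biased random sequence.
    """
    pos_gc, pos_cons = _class_stats(data.positives)
    neg_gc, neg_cons = _class_stats(data.negatives)
    if not data.positives or not data.negatives:
        logger.warning("single-class dataset: QC report has absent statistics")
    return QCReport(
        positives_count=data.positives_count,
        negatives_count=data.negatives_count,
        positive_gc=pos_gc,
        negative_gc=neg_gc,
        positive_conservation=pos_cons,
        negative_conservation=neg_cons,
    )
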