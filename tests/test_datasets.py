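"""Dataset construction, splitting, synthesis, GenBank extraction, QC."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

import sig70scan as s
from sig70scan import seqcore
from sig70scan.datasets import (
    DatasetError,
    PromoterDataset,
    PromoterSite,
    SyntheticConfig,
    base_probabilities_from_gc,
    consensus_pwm,
    dataset_qc_report,
    load_site_table,
    parse_genbank_promoters,
    sample_background,
    stratified_split,
    synthesize_dataset,
    write_site_table,
)
from sig70scan.seqcore import BoxPair


def make_site(kmer, label="positive", **kw):
    return PromoterSite(pair=BoxPair.from_concatenated(kmer), label=label, **kw)


class TestPromoterSite:
    def test_coordinate_span_invariant(self):
        site = make_site(
            "TTGACATATAAT", contig="c", start=100, end=129, spacer_length=17
        )
        assert site.end - site.start == 12 + site.spacer_length

    def test_inconsistent_span_rejected(self):
        with pytest.raises(DatasetError, match="span"):
            make_site("TTGACATATAAT", contig="c", start=100, end=120, spacer_length=17)

    def test_negative_spacer_rejected(self):
        with pytest.raises(DatasetError):
            make_site("TTGACATATAAT", spacer_length=-1)


class TestPromoterDataset:
    def test_duplicate_positive_rejected(self):
        with pytest.raises(DatasetError, match="duplicate"):
            PromoterDataset([make_site("TTGACATATAAT"), make_site("TTGACATATAAT")])

    def test_duplicate_negatives_allowed(self):
        data = PromoterDataset(
            [make_site("AAAAAACCCCCC", "negative")] * 3 + [make_site("TTGACATATAAT")]
        )
        assert data.negatives_count == 3
        assert data.positives_count == 1


class TestStratifiedSplit:
    def test_9_to_1_split_counts(self):
        data = synthesize_dataset(SyntheticConfig(n_positive=170, n_negative=1600, seed=3))
        split = stratified_split(data, 0.1, seed=0)
        assert split.test.positives_count == 17
        assert split.test.negatives_count == 160
        assert split.train.positives_count == 153

    def test_disjoint_union_by_identity(self):
        data = synthesize_dataset(SyntheticConfig(n_positive=20, n_negative=100, seed=4))
        split = stratified_split(data, 0.1, seed=1)
        train_ids = {id(x) for x in split.train.sites}
        test_ids = {id(x) for x in split.test.sites}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {id(x) for x in data.sites}

    def test_deterministic_under_seed(self):
        data = synthesize_dataset(SyntheticConfig(n_positive=20, n_negative=100, seed=4))
        a = stratified_split(data, 0.1, seed=7)
        b = stratified_split(data, 0.1, seed=7)
        assert [x.source_id for x in a.test.sites] == [x.source_id for x in b.test.sites]

    def test_degenerate_fraction_rejected(self):
        data = synthesize_dataset(SyntheticConfig(n_positive=20, n_negative=100, seed=4))
        with pytest.raises(DatasetError):
            stratified_split(data, 0.0, seed=0)

    def test_tiny_class_rejected(self):
        data = PromoterDataset(
            [make_site("TTGACATATAAT")]
            + [make_site("AAAAAACCCCCC", "negative")] * 5
        )
        with pytest.raises(DatasetError, match="positive"):
            stratified_split(data, 0.1, seed=0)


class TestSynthesize:
    def test_bit_reproducible(self):
        cfg = SyntheticConfig(n_positive=30, n_negative=50, seed=9)
        a = synthesize_dataset(cfg)
        b = synthesize_dataset(cfg)
        assert [x.twelve_mer for x in a.sites] == [x.twelve_mer for x in b.sites]

    def test_negative_gc_converges(self):
        data = synthesize_dataset(SyntheticConfig(n_positive=2, n_negative=5000, seed=5))
        gc = np.mean([seqcore.gc_fraction(x.twelve_mer) for x in data.negatives])
        assert abs(gc - 0.61) < 0.01

    def test_calibrated_positive_statistics(self):
        """Generator emulates the curated set: ~47% GC, ~5.6/12 conservation."""
        data = synthesize_dataset(SyntheticConfig(n_positive=170, n_negative=2, seed=6))
        qc = dataset_qc_report(data)
        assert 5.4 <= qc.positive_conservation <= 5.8
        assert 0.44 <= qc.positive_gc <= 0.50

    def test_degenerate_pwm_single_positive(self):
        data = synthesize_dataset(
            SyntheticConfig(n_positive=1, n_negative=2, consensus_weight=1.0, seed=0)
        )
        assert data.positives[0].twelve_mer == "TTGACATATAAT"

    def test_degenerate_pwm_cannot_fill_uniques(self):
        with pytest.raises(DatasetError, match="unique"):
            synthesize_dataset(
                SyntheticConfig(n_positive=5, n_negative=0, consensus_weight=1.0, seed=0)
            )

    def test_invalid_pwm_rejected(self):
        pwm = consensus_pwm()
        pwm[3, 0] += 0.1
        with pytest.raises(DatasetError, match="sum"):
            synthesize_dataset(SyntheticConfig(n_positive=5, n_negative=5, positive_pwm=pwm))

    def test_bad_gc_rejected(self):
        with pytest.raises(DatasetError):
            base_probabilities_from_gc(1.5)


GENOME_LEN = 4000


@pytest.fixture()
def fixture_genome(rng):
    probs = base_probabilities_from_gc(0.61)
    seq = "".join(rng.choice(list("ACGT"), p=probs, size=GENOME_LEN))
    return {"ctgA": seq}


class TestSampleBackground:
    annotation = {"ctgA": [(1000, 2000), (2500, 3000)]}

    def test_sites_fall_in_intergenic_space(self, fixture_genome):
        data = sample_background(fixture_genome, self.annotation, n=50, seed=1)
        assert data.negatives_count == 50
        genic = self.annotation["ctgA"]
        for site in data.sites:
            assert not any(site.start < b and site.end > a for a, b in genic)

    def test_boxes_match_reference_slice(self, fixture_genome):
        data = sample_background(fixture_genome, self.annotation, n=20, seed=2)
        for site in data.sites:
            window = fixture_genome["ctgA"][site.start : site.end]
            if site.strand == "-":
                window = seqcore.reverse_complement(window)
            assert site.pair.box35 == window[:6]
            assert site.pair.box10 == window[-6:]

    def test_deterministic_under_seed(self, fixture_genome):
        a = sample_background(fixture_genome, self.annotation, n=30, seed=3)
        b = sample_background(fixture_genome, self.annotation, n=30, seed=3)
        assert [(x.start, x.strand) for x in a.sites] == [
            (x.start, x.strand) for x in b.sites
        ]

    def test_fully_annotated_contig_rejected(self, fixture_genome):
        with pytest.raises(DatasetError, match="insufficient"):
            sample_background(fixture_genome, {"ctgA": [(0, GENOME_LEN)]}, n=5)

    def test_unknown_contig_rejected(self, fixture_genome):
        with pytest.raises(DatasetError, match="ctgB"):
            sample_background(fixture_genome, {"ctgB": [(0, 10)]}, n=5)


def _genbank_record():
    """200 nt record with a forward promoter pair, a reverse pair, and one
    unpaired -35 feature."""
    rng = np.random.default_rng(42)
    seq = list(rng.choice(list("ACGT"), size=200))
    # forward: -35 at [99,105), -10 at [122,128), spacer 17
    seq[99:105] = "TTGACA"
    seq[122:128] = "TATAAT"
    # reverse-strand pair: on the minus strand the -10 box sits at lower
    # forward coordinates; plant reverse complements of a non-consensus pair
    seq[10:16] = seqcore.reverse_complement("TACAAT")  # -10 feature at [10,16)
    seq[33:39] = seqcore.reverse_complement("TTGACC")  # -35 feature at [33,39)
    record = SeqRecord(Seq("".join(seq)), id="FIX1")
    record.annotations["molecule_type"] = "DNA"
    record.features = [
        SeqFeature(SimpleLocation(99, 105, strand=1), type="minus_35_signal"),
        SeqFeature(SimpleLocation(122, 128, strand=1), type="minus_10_signal"),
        SeqFeature(SimpleLocation(33, 39, strand=-1), type="minus_35_signal"),
        SeqFeature(SimpleLocation(10, 16, strand=-1), type="minus_10_signal"),
        SeqFeature(SimpleLocation(150, 156, strand=1), type="minus_35_signal"),
    ]
    return record


class TestParseGenbank:
    def test_forward_pair_coordinates_and_spacer(self):
        data = parse_genbank_promoters([_genbank_record()])
        fwd = [x for x in data.sites if x.strand == "+"]
        assert len(fwd) == 1
        site = fwd[0]
        assert (site.start, site.end, site.spacer_length) == (99, 128, 17)
        assert site.pair.box35 == "TTGACA"
        assert site.pair.box10 == "TATAAT"

    def test_reverse_pair_reverse_complemented(self):
        data = parse_genbank_promoters([_genbank_record()])
        rev = [x for x in data.sites if x.strand == "-"]
        assert len(rev) == 1
        assert rev[0].pair.box35 == "TTGACC"
        assert rev[0].pair.box10 == "TACAAT"
        assert rev[0].spacer_length == 33 - 16

    def test_unpaired_feature_skipped(self):
        data = parse_genbank_promoters([_genbank_record()])
        assert len(data.sites) == 2  # the lone -35 at [150,156) found no partner

    def test_round_trip_through_genbank_file(self, tmp_path):
        from Bio import SeqIO

        path = tmp_path / "fixture.gb"
        SeqIO.write([_genbank_record()], str(path), "genbank")
        data = parse_genbank_promoters(path)
        assert data.positives_count == 2

    def test_empty_record_warns(self, caplog):
        rec = SeqRecord(Seq("ACGT" * 20), id="EMPTY")
        rec.annotations["molecule_type"] = "DNA"
        with caplog.at_level("WARNING"):
            data = parse_genbank_promoters([rec])
        assert len(data.sites) == 0
        assert "no promoter" in caplog.text


class TestSiteTable:
    def test_round_trip(self, tmp_path):
        data = synthesize_dataset(SyntheticConfig(n_positive=10, n_negative=10, seed=1))
        path = tmp_path / "sites.tsv"
        write_site_table(data, path)
        back = load_site_table(path)
        assert [x.twelve_mer for x in back.sites] == [x.twelve_mer for x in data.sites]
        assert back.positives_count == 10

    def test_duplicate_collapsed_with_warning(self, tmp_path, caplog):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "box35\tbox10\nTTGACA\tTATAAT\nTTGACA\tTATAAT\nTTGACC\tTATAAT\n"
        )
        with caplog.at_level("WARNING"):
            data = load_site_table(path)
        assert data.positives_count == 2
        assert "duplicate" in caplog.text

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("minus35\tminus10\nTTGACA\tTATAAT\n")
        with pytest.raises(DatasetError, match="box35"):
            load_site_table(path)
        # column_map fixes it
        data = load_site_table(path, column_map={"minus35": "box35", "minus10": "box10"})
        assert data.positives_count == 1

    def test_empty_table_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        path.write_text("box35\tbox10\n")
        with caplog.at_level("WARNING"):
            data = load_site_table(path)
        assert len(data.sites) == 0


class TestQCReport:
    def test_calibrated_statistics(self):
        data = synthesize_dataset(SyntheticConfig(n_positive=170, n_negative=5000, seed=8))
        qc = dataset_qc_report(data)
        assert abs(qc.positive_gc - 0.47) < 0.03
        assert abs(qc.negative_gc - 0.61) < 0.01
        assert 5.4 <= qc.positive_conservation <= 5.8
        # background at 61% GC: expected 12*sum(p^2) = 3.15, near the 3.2 level
        assert 3.0 <= qc.negative_conservation <= 3.3

    def test_single_class_partial_report(self, caplog):
        data = PromoterDataset([make_site("TTGACATATAAT")])
        with caplog.at_level("WARNING"):
            qc = dataset_qc_report(data)
        assert qc.negative_gc is None
        assert qc.negatives_count == 0

    def test_tsv_round_trip(self, tmp_path):
        data = synthesize_dataset(SyntheticConfig(n_positive=5, n_negative=5, seed=2))
        path = tmp_path / "qc.tsv"
        dataset_qc_report(data).to_tsv(path)
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        assert set(frame["statistic"]) >= {"positive_gc", "negative_conservation"}
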