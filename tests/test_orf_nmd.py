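"""CDS construction and the 50-nt NMD rule, checked against a brute-force
codon-walking oracle."""

import pytest

from nmdkit.genome import DictGenome
from nmdkit.orf import annotate_nmd, build_cds, predict_nmd

from conftest import make_tx, oracle_nmd_call


def _two_exon_tx_with_stop_at(dist: int, threshold_exon=200):
    """Plus-strand two-exon transcript whose stop codon ends exactly `dist`
    nt upstream of the last junction (junction at spliced offset 200)."""
    stop_end = threshold_exon - dist
    return make_tx(
        "t",
        [(0, 200), (300, 500)],
        cds=[(0, stop_end)],
    )


@pytest.mark.parametrize(
    "dist,expected",
    [(49, False), (50, False), (51, True), (120, True), (0, False)],
)
def test_strict_50nt_boundary(dist, expected):
    v = predict_nmd(_two_exon_tx_with_stop_at(dist))
    assert v.dist_stop_to_last_junction == dist
    assert v.is_nmd is expected


def test_stop_in_last_exon_is_not_nmd():
    tx = make_tx("t", [(0, 200), (300, 500)], cds=[(0, 200), (300, 420)])
    v = predict_nmd(tx)
    assert v.has_cds and not v.is_nmd
    assert v.dist_stop_to_last_junction < 0


def test_single_exon_transcript_is_never_nmd():
    tx = make_tx("t", [(0, 500)], cds=[(10, 100)])
    v = predict_nmd(tx)
    assert v.has_cds and not v.is_nmd and v.reason == "single-exon"


def test_missing_cds_yields_uncallable_verdict():
    v = predict_nmd(make_tx("t", [(0, 100), (200, 300)]))
    assert not v.has_cds and not v.is_nmd and v.reason == "no-cds"


def test_stop_anchor_option_shifts_distance_by_codon_length():
    tx = _two_exon_tx_with_stop_at(49)
    assert predict_nmd(tx, anchor="stop_end").is_nmd is False
    # measuring from the stop start adds 3 nt: 52 > 50
    assert predict_nmd(tx, anchor="stop_start").is_nmd is True


# -- build_cds on a hand-crafted locus -------------------------------------


@pytest.fixture(scope="module")
def mini_locus():
    seq = list("C" * 500)
    exonic = list(range(0, 60)) + list(range(120, 300))
    coding = "ATG" + "GGC" * 29 + "TAA"  # 90 coding nt + stop, from offset 10
    for k, base in enumerate(coding):
        seq[exonic[10 + k]] = base
    # in-frame TAA inside a 37-nt cassette at (70,107): spliced offset 61
    seq[71:74] = list("TAA")
    genome = DictGenome({"chrT": "".join(seq)})
    ref = make_tx(
        "ref", [(0, 60), (120, 300)], cds=[(10, 60), (120, 163)]
    )
    return genome, ref


def test_projected_start_reaches_reference_stop(mini_locus):
    genome, ref = mini_locus
    novel = make_tx("n", [(5, 60), (120, 300)])
    built, flag = build_cds(novel, [ref], genome)
    assert flag == "" and built.cds is not None
    # same stop codon as the reference: CDS 3' boundary at genomic 163
    assert built.cds[-1].end == 163


def test_cassette_with_inframe_stop_truncates_cds(mini_locus):
    genome, ref = mini_locus
    inclusion = make_tx("n", [(0, 60), (70, 107), (120, 200), (220, 300)])
    built, flag = build_cds(inclusion, [ref], genome)
    assert flag == ""
    assert built.cds[-1].end == 74  # stop inside the cassette exon
    assert predict_nmd(built).is_nmd  # PTC far upstream of last junction


def test_no_projectable_start_means_no_cds(mini_locus):
    genome, ref = mini_locus
    novel = make_tx("n", [(120, 300)])
    built, flag = build_cds(novel, [ref], genome)
    assert built.cds is None and flag == "no-start-projected"


def test_stop_not_found_is_flagged(mini_locus):
    genome, ref = mini_locus
    # exclude the exon carrying the stop: translation runs off the end
    novel = make_tx("n", [(0, 60), (120, 160)])
    built, flag = build_cds(novel, [ref], genome)
    assert built.cds is None and flag == "stop-not-found"


def test_appending_downstream_exon_can_only_create_nmd(mini_locus):
    genome, ref = mini_locus
    assert not predict_nmd(ref).is_nmd  # stop lies in the last exon
    extended = make_tx(
        "ext", [(0, 60), (120, 300), (350, 400)], cds=[(10, 60), (120, 163)]
    )
    assert predict_nmd(extended).is_nmd


# -- fixture-wide properties ------------------------------------------------


def test_predictions_match_codon_walking_oracle(toy_data, annotated):
    aset, verdicts = annotated
    n_checked = 0
    for tx in aset.transcripts():
        want_nmd, want_dist = oracle_nmd_call(tx, toy_data.genome)
        v = verdicts[tx.transcript_id]
        assert v.is_nmd == want_nmd, tx.transcript_id
        if tx.cds and want_dist is not None:
            assert v.dist_stop_to_last_junction == want_dist
        n_checked += 1
    assert n_checked == aset.n_transcripts


def test_raising_threshold_never_creates_nmd(annotated):
    aset, _ = annotated
    for tx in aset.transcripts():
        calls = [
            predict_nmd(tx, threshold=th).is_nmd
            for th in range(0, 301, 25)
        ]
        # monotone non-increasing in the threshold
        assert all(a or not b for a, b in zip(calls, calls[1:]))


def test_planted_poison_exon_verdicts(toy_data, annotated):
    _, verdicts = annotated
    for ev in toy_data.truth:
        if ev.label == "NS":
            assert verdicts[ev.inclusion_tx].is_nmd
            assert not verdicts[ev.skipping_tx].is_nmd
        elif ev.label == "NR":
            assert not verdicts[ev.inclusion_tx].is_nmd
            assert verdicts[ev.skipping_tx].is_nmd


def test_annotate_nmd_is_deterministic(toy_data):
    _, v1 = annotate_nmd(toy_data.annotation, toy_data.genome)
    _, v2 = annotate_nmd(toy_data.annotation, toy_data.genome)
    assert {k: (v.is_nmd, v.dist_stop_to_last_junction) for k, v in v1.items()} == {
        k: (v.is_nmd, v.dist_stop_to_last_junction) for k, v in v2.items()
    }


def test_annotation_without_cds_is_fully_uncallable():
    from nmdkit.models import AnnotationSet

    aset = AnnotationSet()
    aset.add_transcript(make_tx("a", [(0, 100), (200, 300)]))
    aset.add_transcript(make_tx("b", [(0, 100)], gene_id="G2"))
    genome = DictGenome({"chrT": "A" * 400})
    _, verdicts = annotate_nmd(aset, genome)
    assert all(not v.has_cds for v in verdicts.values())
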