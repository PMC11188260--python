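"""Splicing-event calculus: chain diffing, NMD-effect labels, catalog."""

import pytest

from nmdkit.events import (
    build_event_catalog,
    classify_event_nmd,
    diff_splice_chains,
    ASEvent,
)
from nmdkit.orf import NMDVerdict, predict_nmd

from conftest import make_tx


def _ids(events):
    return [(e.event_type, e.start, e.end) for e in events]


def test_cassette_exon_between_shared_junctions():
    a = make_tx("a", [(0, 100), (500, 600), (900, 1000)])
    b = make_tx("b", [(0, 100), (900, 1000)])
    events = diff_splice_chains(a, b)
    assert _ids(events) == [("CE", 500, 600)]
    assert events[0].inclusion_tx == "a" and events[0].skipping_tx == "b"


def test_alternative_donor_plus_strand():
    # A's exon [1,120] vs B's exon [1,100] with shared acceptor at 201 (GTF)
    a = make_tx("a", [(0, 120), (200, 300)])
    b = make_tx("b", [(0, 100), (200, 300)])
    events = diff_splice_chains(a, b)
    assert _ids(events) == [("AD", 100, 120)]
    assert events[0].inclusion_tx == "a"


def test_alternative_acceptor_plus_strand():
    a = make_tx("a", [(0, 100), (180, 300)])
    b = make_tx("b", [(0, 100), (200, 300)])
    events = diff_splice_chains(a, b)
    assert _ids(events) == [("AA", 180, 200)]
    assert events[0].inclusion_tx == "a"


def test_retained_intron():
    a = make_tx("a", [(0, 300)])
    b = make_tx("b", [(0, 100), (200, 300)])
    events = diff_splice_chains(a, b)
    assert _ids(events) == [("RI", 100, 200)]
    assert events[0].inclusion_tx == "a"


def test_minus_strand_acceptor_extension_is_AA():
    # middle exon extends at its genomically-right edge; on the minus strand
    # that edge is the exon's 3' splice site (acceptor), donor at 1400 shared
    a = make_tx("a", [(1000, 1100), (1200, 1300), (1400, 1500)], "-")
    b = make_tx("b", [(1000, 1100), (1200, 1324), (1400, 1500)], "-")
    events = diff_splice_chains(a, b)
    assert _ids(events) == [("AA", 1300, 1324)]
    assert events[0].inclusion_tx == "b"


def test_minus_strand_donor_extension_is_AD():
    # middle exon extends at its genomically-left edge: 5' splice site on "-"
    a = make_tx("a", [(1000, 1100), (1200, 1300), (1400, 1500)], "-")
    b = make_tx("b", [(1000, 1100), (1176, 1300), (1400, 1500)], "-")
    events = diff_splice_chains(a, b)
    assert _ids(events) == [("AD", 1176, 1200)]
    assert events[0].inclusion_tx == "b"


def test_diff_is_symmetric_with_sides_swapped():
    a = make_tx("a", [(0, 100), (500, 600), (900, 1000)])
    b = make_tx("b", [(0, 100), (900, 1000)])
    fwd = diff_splice_chains(a, b)
    rev = diff_splice_chains(b, a)
    assert _ids(fwd) == _ids(rev)
    assert [(e.inclusion_tx, e.skipping_tx) for e in fwd] == [
        (e.inclusion_tx, e.skipping_tx) for e in rev
    ]


def test_multi_exon_skip_is_complex_not_ce():
    a = make_tx(
        "a", [(0, 100), (300, 400), (500, 600), (900, 1000)]
    )
    b = make_tx("b", [(0, 100), (900, 1000)])
    events = diff_splice_chains(a, b)
    assert all(e.event_type == "complex" for e in events)


def test_different_strand_is_an_error():
    a = make_tx("a", [(0, 100)], "+")
    b = make_tx("b", [(0, 100)], "-")
    with pytest.raises(ValueError):
        diff_splice_chains(a, b)


# -- NMD-effect classification ---------------------------------------------


def _verdict(tid, nmd, has_cds=True):
    return NMDVerdict(tid, has_cds, nmd)


def test_poison_exon_is_ns():
    ev = ASEvent("CE", "c", "+", 10, 20, inclusion_tx="i", skipping_tx="s")
    label = classify_event_nmd(
        ev, {"i": _verdict("i", True), "s": _verdict("s", False)}
    )
    assert label == "NS"


def test_protective_exon_is_nr():
    ev = ASEvent("CE", "c", "+", 10, 20, inclusion_tx="i", skipping_tx="s")
    label = classify_event_nmd(
        ev, {"i": _verdict("i", False), "s": _verdict("s", True)}
    )
    assert label == "NR"


def test_conflicting_pairs_are_ambiguous():
    ev = ASEvent(
        "CE", "c", "+", 10, 20,
        supporting_pairs=[("i1", "s1"), ("i2", "s2")],
    )
    verdicts = {
        "i1": _verdict("i1", True),
        "s1": _verdict("s1", False),
        "i2": _verdict("i2", False),
        "s2": _verdict("s2", True),
    }
    assert classify_event_nmd(ev, verdicts) == "ambiguous"


def test_uninformative_pair_is_none():
    ev = ASEvent("CE", "c", "+", 10, 20, inclusion_tx="i", skipping_tx="s")
    label = classify_event_nmd(
        ev, {"i": _verdict("i", False), "s": _verdict("s", False)}
    )
    assert label == "none"


# -- catalog ----------------------------------------------------------------


def test_catalog_recovers_exactly_the_planted_events(toy_data, annotated):
    aset, verdicts = annotated
    catalog = build_event_catalog(aset, verdicts)
    got = {(e.event_type, e.chrom, e.start, e.end, e.nmd_effect) for e in catalog}
    want = {
        (t.event_type, t.chrom, t.start, t.end, t.label)
        for t in toy_data.truth
        if t.label in ("NS", "NR")
    }
    assert got == want  # recall and precision both 1.0


def test_catalog_labels_reproducible_from_supporting_pairs(annotated):
    aset, verdicts = annotated
    for ev in build_event_catalog(aset, verdicts):
        for inc, skp in ev.supporting_pairs:
            vi, vs = verdicts[inc], verdicts[skp]
            if ev.nmd_effect == "NS":
                assert vi.is_nmd and not vs.is_nmd
            elif ev.nmd_effect == "NR":
                assert not vi.is_nmd and vs.is_nmd


def test_catalog_deduplicates_and_pools_supporting_pairs():
    from nmdkit.models import AnnotationSet

    aset = AnnotationSet()
    # three inclusion isoforms of the same cassette vs one skipping isoform
    incs = []
    for k, tail in enumerate((1000, 1050, 1100)):
        incs.append(
            make_tx(f"i{k}", [(0, 100), (500, 600), (900, tail)])
        )
    skp = make_tx("s", [(0, 100), (900, 1000)])
    for tx in incs + [skp]:
        aset.add_transcript(tx)
    verdicts = {f"i{k}": _verdict(f"i{k}", True) for k in range(3)}
    verdicts["s"] = _verdict("s", False)
    catalog = build_event_catalog(aset, verdicts)
    ces = [e for e in catalog if e.event_type == "CE"]
    assert len(ces) == 1
    assert len(ces[0].supporting_pairs) == 3
    assert ces[0].nmd_effect == "NS"


def test_all_productive_gene_contributes_nothing():
    from nmdkit.models import AnnotationSet

    aset = AnnotationSet()
    aset.add_transcript(make_tx("a", [(0, 100), (500, 600), (900, 1000)]))
    aset.add_transcript(make_tx("b", [(0, 100), (900, 1000)]))
    verdicts = {"a": _verdict("a", False), "b": _verdict("b", False)}
    assert build_event_catalog(aset, verdicts) == []


def test_catalog_is_order_invariant(toy_data, annotated):
    from nmdkit.models import AnnotationSet

    aset, verdicts = annotated
    reordered = AnnotationSet()
    for tx in sorted(
        aset.transcripts(), key=lambda t: t.transcript_id, reverse=True
    ):
        reordered.add_transcript(tx)
    cat1 = build_event_catalog(aset, verdicts)
    cat2 = build_event_catalog(reordered, verdicts)
    key = lambda e: (e.key, e.nmd_effect, sorted(e.supporting_pairs))
    assert sorted(map(key, cat1)) == sorted(map(key, cat2))
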