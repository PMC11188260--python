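"""Synthetic genomes, annotations and quantification tables with planted
AS-NMD structure.

Every generator is a pure function of its plan and seed. Each toy gene has
a five-exon productive isoform (annotated CDS, stop codon in the last exon)
and one alternative isoform realizing a planted event:

* ``NS-CE`` — a 37-nt poison cassette exon with an in-frame stop codon,
* ``NR-CE`` — a frame-disrupting cassette whose *skipping* exposes a stop,
* ``NS-AD``/``NS-AA`` — donor/acceptor extensions carrying an in-frame stop,
* ``NS-RI`` — a retained intron with an in-frame stop,
* ``none`` — a frame-preserving cassette leaving both isoforms productive.

Coding sequence is assembled from non-stop codons with stops inserted
explicitly, so planted verdicts hold by construction; each gene is verified
against the 50-nt rule with a >= 10-nt margin before being emitted, and
re-randomized otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import flank_intervals
from .events import ASEvent, diff_splice_chains
from .genome import DictGenome, reverse_complement, write_fasta
from .gtf import export_annotation
from .models import AnnotationSet, GenomicInterval, TranscriptModel
from .orf import DEFAULT_PTC_THRESHOLD, build_cds, predict_nmd
from .stats import inverse_vst_psi, vst_psi

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

EVENT_KINDS = ("NS-CE", "NR-CE", "NS-AD", "NS-AA", "NS-RI", "none")


@dataclass(frozen=True)
class FixturePlan:
    seed: int = 7
    n_genes: int = 12
    event_cycle: tuple[str, ...] = EVENT_KINDS
    threshold: int = DEFAULT_PTC_THRESHOLD
    margin: int = 10
    genes_per_chrom: int = 25
    intergenic: int = 1000


@dataclass
class PlantedEvent:
    gene_id: str
    kind: str  # plan label, e.g. NS-CE
    event_type: str  # CE | AD | AA | RI
    label: str  # NS | NR | none
    chrom: str
    start: int  # 0-based half-open genomic
    end: int
    strand: str
    inclusion_tx: str
    skipping_tx: str
    annotated_tx: str

    @property
    def event_id(self) -> str:
        return f"{self.event_type}:{self.chrom}:{self.start + 1}-{self.end}:{self.strand}"


@dataclass
class ToyData:
    genome: DictGenome
    annotation: AnnotationSet
    truth: list[PlantedEvent]
    plan: FixturePlan


# -- gene construction in transcription-oriented "design" coordinates ------

_SEGS = (
    ("E1", 150),
    ("i1", 300),
    ("E2", 120),
    ("i2a", 300),
    ("P", 37),
    ("i2b", 300),
    ("E3", 90),  # 91 for NR-CE genes
    ("i3", 300),
    ("E4", 100),
    ("i4", 300),
    ("E5", 200),
)
_UTR5 = 30
_EXT = 24


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(SAFE_CODONS, size=n))


def _design_gene(rng: np.random.Generator, kind: str):
    """Return (design_seq, exon layout, novel exon layout, event design iv)."""
    segs = dict(_SEGS)
    if kind == "NR-CE":
        segs["E3"] = 91
    pos: dict[str, tuple[int, int]] = {}
    off = 0
    for name, _ in _SEGS:
        ln = segs[name]
        pos[name] = (off, off + ln)
        off += ln
    total = off
    seq = list(rng.choice(_BASES, size=total))

    # productive coding path: ATG at E1+30, stop codon planted inside E5
    coding_before_e5 = (150 - _UTR5 - 3) + 120 + segs["E3"] + 100
    stop_in_e5 = (3 - (coding_before_e5 + 3) % 3) % 3 + 60
    n_fill = (coding_before_e5 + stop_in_e5) // 3
    cds_seq = "ATG" + _safe_codons(rng, n_fill) + "TAA"
    path = (
        list(range(pos["E1"][0] + _UTR5, pos["E1"][1]))
        + list(range(*pos["E2"]))
        + list(range(*pos["E3"]))
        + list(range(*pos["E4"]))
        + list(range(pos["E5"][0], pos["E5"][0] + stop_in_e5 + 3))
    )
    assert len(path) == len(cds_seq)
    for p, base in zip(path, cds_seq):
        seq[p] = base

    def write(start: int, content: str) -> None:
        seq[start : start + len(content)] = list(content)

    # phase entering the alternative region is 0 by construction
    # (E1 coding 120 nt + E2 120 nt)
    prod = ["E1", "E2", "E3", "E4", "E5"]
    if kind == "NS-CE":
        write(pos["P"][0], _safe_codons(rng, 4)[:9] + "TAA")
        novel = ["E1", "E2", "P", "E3", "E4", "E5"]
        ev = ("CE", pos["P"], "alt")
    elif kind == "none":
        novel = ["E1", "E2", "E4", "E5"]
        ev = ("CE", pos["E3"], "ref")
    elif kind == "NR-CE":
        write(pos["E4"][0] + 9, "TAA")  # stop in the frame of the skip isoform
        novel = ["E1", "E2", "E4", "E5"]
        ev = ("CE", pos["E3"], "ref")
    elif kind == "NS-AD":
        write(pos["E2"][1], _safe_codons(rng, 4)[:9] + "TAA")
        novel = ["E1", "E2+", "E3", "E4", "E5"]
        ev = ("AD", (pos["E2"][1], pos["E2"][1] + _EXT), "alt")
    elif kind == "NS-AA":
        write(pos["E3"][0] - _EXT, _safe_codons(rng, 4)[:9] + "TAA")
        novel = ["E1", "E2", "-E3", "E4", "E5"]
        ev = ("AA", (pos["E3"][0] - _EXT, pos["E3"][0]), "alt")
    elif kind == "NS-RI":
        write(pos["E2"][1], _safe_codons(rng, 4)[:9] + "TAA")
        novel = ["E1", "E2~E3", "E4", "E5"]
        ev = ("RI", (pos["E2"][1], pos["E3"][0]), "alt")
    else:
        raise ValueError(f"unknown event kind {kind!r}")

    def layout(names: list[str]) -> list[tuple[int, int]]:
        out = []
        for n in names:
            if n == "E2+":
                out.append((pos["E2"][0], pos["E2"][1] + _EXT))
            elif n == "-E3":
                out.append((pos["E3"][0] - _EXT, pos["E3"][1]))
            elif n == "E2~E3":
                out.append((pos["E2"][0], pos["E3"][1]))
            else:
                out.append(pos[n])
        return out

    return "".join(seq), layout(prod), layout(novel), ev, total


def _to_genomic(iv: tuple[int, int], g0: int, length: int, strand: str):
    if strand == "+":
        return (g0 + iv[0], g0 + iv[1])
    return (g0 + length - iv[1], g0 + length - iv[0])


def _verify_gene(
    genome: DictGenome,
    annotated: TranscriptModel,
    novel: TranscriptModel,
    label: str,
    event_type: str,
    interval: tuple[int, int],
    threshold: int,
    margin: int,
) -> bool:
    built, flag = build_cds(novel, [annotated], genome)
    if flag:
        return False
    v_ref = predict_nmd(annotated, threshold=threshold)
    v_alt = predict_nmd(built, threshold=threshold)
    events = diff_splice_chains(annotated, novel)
    if len(events) != 1:
        return False
    ev = events[0]
    if ev.event_type != event_type or (ev.start, ev.end) != interval:
        return False

    def solid(v, want_nmd: bool) -> bool:
        if not v.has_cds:
            return False
        d = v.dist_stop_to_last_junction
        if want_nmd:
            return v.is_nmd and d is not None and d >= threshold + margin
        return not v.is_nmd and (d is None or d <= threshold - margin)

    inc_is_novel = ev.inclusion_tx == novel.transcript_id
    if label == "NS":  # inclusion isoform is the NMD target
        v_inc = v_alt if inc_is_novel else v_ref
        v_skp = v_ref if inc_is_novel else v_alt
        return solid(v_inc, True) and solid(v_skp, False)
    if label == "NR":
        v_inc = v_alt if inc_is_novel else v_ref
        v_skp = v_ref if inc_is_novel else v_alt
        return solid(v_inc, False) and solid(v_skp, True)
    return solid(v_ref, False) and solid(v_alt, False)


def make_toy_annotation(plan: FixturePlan) -> ToyData:
    """Generate the toy genome, annotation and planted ground truth."""
    chrom_seqs: dict[str, list[str]] = {}
    aset = AnnotationSet(provenance=f"fixture(seed={plan.seed})")
    truth: list[PlantedEvent] = []

    for gi in range(plan.n_genes):
        kind = plan.event_cycle[gi % len(plan.event_cycle)]
        chrom = f"chr{gi // plan.genes_per_chrom + 1}"
        parts = chrom_seqs.setdefault(chrom, [])
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"GFIX{gi:04d}"

        for attempt in range(60):
            rng = np.random.default_rng([plan.seed % (2**31), gi, attempt])
            design, prod, novel, (etype, eiv, _side), length = _design_gene(
                rng, kind
            )
            gap = plan.intergenic
            g0 = sum(len(p) for p in parts) + gap
            locus = design if strand == "+" else reverse_complement(design)
            probe = DictGenome({chrom: "N" * g0 + locus})

            def tx(tid: str, layout, cds=None):
                exons = [
                    GenomicInterval(
                        chrom, *_to_genomic(iv, g0, length, strand), strand
                    )
                    for iv in layout
                ]
                return TranscriptModel(
                    tid, gene_id, chrom, strand, exons, cds
                )

            ref_tx = tx(f"{gene_id}.ref", prod)
            # attach the annotated CDS: ATG..stop projected to genomic space
            spl = _cds_span_design(prod, design)
            cds_ivs = [
                GenomicInterval(
                    chrom, *_to_genomic(iv, g0, length, strand), strand
                )
                for iv in spl
            ]
            ref_tx = ref_tx.with_cds(cds_ivs)
            alt_tx = tx(f"{gene_id}.alt", novel)
            g_iv = _to_genomic(eiv, g0, length, strand)
            label = {"none": "none"}.get(kind, kind.split("-")[0])
            if _verify_gene(
                probe, ref_tx, alt_tx, label, etype, g_iv,
                plan.threshold, plan.margin,
            ):
                parts.append("N" * gap + locus)
                aset.add_transcript(ref_tx)
                aset.add_transcript(alt_tx)
                ann_is_inclusion = kind in ("NR-CE", "none")
                inc, skp = (
                    (ref_tx.transcript_id, alt_tx.transcript_id)
                    if ann_is_inclusion
                    else (alt_tx.transcript_id, ref_tx.transcript_id)
                )
                truth.append(
                    PlantedEvent(
                        gene_id, kind, etype, label, chrom, g_iv[0], g_iv[1],
                        strand, inc, skp, ref_tx.transcript_id,
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not realize a valid {kind} gene for {gene_id}"
            )

    sequences = {c: "".join(p) + "N" * plan.intergenic for c, p in chrom_seqs.items()}
    return ToyData(DictGenome(sequences), aset, truth, plan)


def _cds_span_design(prod_layout, design: str):
    """Design-space CDS intervals of the productive isoform (stop included)."""
    # coding runs from E1+30 through the first in-frame stop planted in E5
    exonic = []
    first = prod_layout[0]
    exonic.append((first[0] + _UTR5, first[1]))
    exonic.extend(prod_layout[1:])
    # walk codons to locate the stop (it was planted, but recompute honestly)
    mrna = "".join(design[a:b] for a, b in exonic)
    stop_end = None
    for p in range(0, len(mrna) - 2, 3):
        if mrna[p : p + 3] in _STOPS:
            stop_end = p + 3
            break
    assert stop_end is not None
    out = []
    off = 0
    for a, b in exonic:
        take = min(b - a, stop_end - off)
        if take <= 0:
            break
        out.append((a, a + take))
        off += b - a
    return out


# -- quantification simulation ---------------------------------------------


@dataclass(frozen=True)
class QuantDesign:
    """Study design for the simulated Whippet-style tables.

    Timepoints follow the differentiation series (days); responsive events
    receive a CHX-minus-DMSO shift of ``dpsi`` at high posterior
    probability, null events stay near zero, near-constitutive events sit
    at inclusion > 0.9 (NS) or < 0.1 (NR). The expression series of each
    AS-NMD gene is constructed to correlate with the observed
    NMD-protective splicing pattern at exactly ``rho`` in-sample.
    """

    timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 24.0)
    dpsi: float = 0.3
    probability: float = 0.99
    rho: float = 0.6
    noise_sd: float = 0.02
    roles: dict = field(default_factory=dict)  # event_id -> role override


def plant_correlation(target, rho: float, rng: np.random.Generator):
    """A vector whose sample Pearson correlation with ``target`` is exactly
    ``rho`` (orthogonalized-noise construction); affine-scaled to (0, 1)."""
    v = np.asarray(target, dtype=float)
    if v.size < 3 or np.ptp(v) == 0:
        raise ValueError("target must vary and have length >= 3")
    z = v - v.mean()
    z /= np.linalg.norm(z)
    for _ in range(100):
        g = rng.normal(size=v.size)
        g -= g.mean()
        g -= (g @ z) * z
        nrm = np.linalg.norm(g)
        if nrm > 1e-12:
            break
    else:
        raise RuntimeError("could not draw a noise direction")
    y = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * (g / nrm)
    scale = np.abs(y).max()
    return 0.5 + 0.45 * y / (scale if scale > 0 else 1.0)


def _noisy_psi(psi, sd, rng):
    v = vst_psi(np.clip(psi, 0.0, 1.0))
    v = np.clip(v + rng.normal(0.0, sd, size=np.shape(psi)), 0.0, 1.0)
    return inverse_vst_psi(v)


def simulate_quantification(
    truth: list[PlantedEvent],
    design: QuantDesign,
    seed: int,
):
    """PSI table, ΔPSI table and an expression matrix for the planted events.

    Returns ``(psi_df, dpsi_df, expr_df)``. The probability column is
    simulated as a near-1 (responsive) or mid-range (null) confidence
    stand-in rather than a real posterior.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(design.timepoints, dtype=float)
    frac = (t - t[0]) / (t[-1] - t[0]) if t.size > 1 else np.zeros_like(t)

    psi_rows, dpsi_rows, expr = [], [], {}
    for idx, ev in enumerate(truth):
        if ev.label not in ("NS", "NR"):
            expr[ev.gene_id] = 0.5 + 0.1 * rng.standard_normal(t.size)
            continue
        role = design.roles.get(ev.event_id, "responsive")
        if role == "near-constitutive":
            base = np.full(t.size, 0.95 if ev.label == "NS" else 0.05)
            shift = 0.02 if ev.label == "NS" else -0.02
        elif role == "null":
            base = np.full(t.size, 0.5)
            shift = 0.0
        else:
            # inclusion of NS events rises during differentiation; NR falls
            base = (
                0.1 + 0.5 * frac if ev.label == "NS" else 0.9 - 0.5 * frac
            )
            shift = design.dpsi if ev.label == "NS" else -design.dpsi
        dmso = _noisy_psi(base, design.noise_sd, rng)
        chx = _noisy_psi(base + shift, design.noise_sd, rng)
        for cond, series in (("DMSO", dmso), ("CHX", chx)):
            for tp, p in zip(t, series):
                psi_rows.append(
                    {
                        "event_id": ev.event_id,
                        "sample_id": f"{cond}_d{tp:g}",
                        "condition": cond,
                        "timepoint": tp,
                        "psi": float(p),
                    }
                )
        for tp, pd_, pc in zip(t, dmso, chx):
            prob = (
                design.probability - abs(rng.normal(0.0, 0.005))
                if role != "null"
                else 0.3 + 0.3 * rng.random()
            )
            dpsi_rows.append(
                {
                    "event_id": ev.event_id,
                    "contrast": f"CHX-DMSO:d{tp:g}",
                    "dpsi": float(pc - pd_),
                    "probability": float(np.clip(prob, 0.0, 1.0)),
                    "psi_mean": float((pc + pd_) / 2.0),
                }
            )
        v = vst_psi(dmso)
        protective = 1.0 - v if ev.label == "NS" else v
        if np.ptp(protective) == 0:
            expr[ev.gene_id] = 0.5 + 0.1 * rng.standard_normal(t.size)
        else:
            expr[ev.gene_id] = plant_correlation(protective, design.rho, rng)

    psi_df = pd.DataFrame(psi_rows)
    dpsi_df = pd.DataFrame(dpsi_rows)
    expr_df = pd.DataFrame(
        expr, index=[f"d{tp:g}" for tp in t]
    ).T.rename_axis("gene_id")
    return psi_df, dpsi_df, expr_df


# -- conservation track -----------------------------------------------------


def make_toy_track(
    data: ToyData,
    padding: int = 100,
    high: float = 0.9,
    background: float = 0.1,
    gap_events: tuple[str, ...] = (),
) -> list[tuple[str, int, int, float]]:
    """bedGraph rows: background over gene loci, ``high`` over the intronic
    flank windows of planted NS/NR events; for event ids in ``gap_events``
    the second half of each window is left uncovered."""
    arrays = {
        chrom: np.full(len(seq), np.nan)
        for chrom, seq in data.genome.sequences.items()
    }
    for gene in data.annotation.genes.values():
        arrays[gene.chrom][gene.start : gene.end] = background
    for ev in data.truth:
        if ev.label not in ("NS", "NR"):
            continue
        ivs, _ = flank_intervals(
            ASEvent(ev.event_type, ev.chrom, ev.strand, ev.start, ev.end),
            padding=padding,
        )
        for iv in ivs:
            arrays[ev.chrom][iv.start : iv.end] = high
            if ev.event_id in gap_events:
                mid = iv.start + len(iv) // 2
                arrays[ev.chrom][mid : iv.end] = np.nan
    rows = []
    for chrom in sorted(arrays):
        arr = arrays[chrom]
        covered = np.nonzero(~np.isnan(arr))[0]
        if covered.size == 0:
            continue
        run_start = covered[0]
        for prev, cur in zip(covered, covered[1:]):
            if cur != prev + 1 or arr[cur] != arr[prev]:
                rows.append((chrom, int(run_start), int(prev + 1), float(arr[prev])))
                run_start = cur
        rows.append((chrom, int(run_start), int(covered[-1] + 1), float(arr[covered[-1]])))
    return rows


def write_track(rows, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def truth_table(truth: list[PlantedEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "kind": ev.kind,
                "event_type": ev.event_type,
                "label": ev.label,
                "chrom": ev.chrom,
                "start": ev.start + 1,
                "end": ev.end,
                "strand": ev.strand,
                "inclusion_tx": ev.inclusion_tx,
                "skipping_tx": ev.skipping_tx,
            }
            for ev in truth
        ]
    )


def write_fixture_dir(
    plan: FixturePlan,
    out_dir: str | Path,
    design: QuantDesign | None = None,
) -> ToyData:
    """Materialize a full fixture set: genome.fa, annotation.gtf, truth.tsv,
    psi.tsv, dpsi.tsv, expr.tsv, cons.bedGraph."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = make_toy_annotation(plan)
    write_fasta(data.genome.sequences, out / "genome.fa")
    export_annotation(data.annotation, out / "annotation.gtf")
    truth_table(data.truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    psi, dpsi, expr = simulate_quantification(
        data.truth, design or QuantDesign(), seed=plan.seed
    )
    psi.to_csv(out / "psi.tsv", sep="\t", index=False)
    dpsi.to_csv(out / "dpsi.tsv", sep="\t", index=False)
    expr.to_csv(out / "expr.tsv", sep="\t")
    write_track(make_toy_track(data), out / "cons.bedGraph")
    return data
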