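"""pegRNA construction: protospacer enumeration, RTT x PBS grid, features,
filters, composite score and per-variant ranking.

Nick coordinate convention: "+1" is the first nucleotide 3' of the nick on
the PAM strand, i.e. protospacer position 18 of 20 (the nick sits 3 nt 5' of
the NGG PAM).  ``Protospacer.nick_pos`` stores the plus-strand coordinate of
that +1 base; PAM-strand offsets count 0, 1, 2, ... from it (offset k is
position +(k+1)), with negative offsets 5' of the nick (the PBS side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils import gc_fraction

from .parts import DEFAULT_PARTS, ECORI_SITE, ESP3I_SITE
from .variant_io import GeneModel, Variant, revcomp

RTT_GRID = (10, 15, 20, 25, 30)
PBS_GRID = (10, 13, 15)
MAX_PER_VARIANT = 30

#: Provisional composite-score weights.  Signs encode the documented
#: monotonicities (closer edits and longer post-edit homology score higher,
#: PAM/protospacer disruption and an in-range PBS GC are rewarded); the exact
#: magnitudes are tunable and not load-bearing.
DEFAULT_WEIGHTS = {
    "ontarget": 0.5,            # per unit of the 0-1 on-target score x100
    "dist_to_nick": -1.0,       # per nt
    "post_edit_homology": 0.5,  # per nt, capped
    "pam_disrupted": 5.0,
    "proto_disrupted": 2.0,
    "pbs_gc_in_range": 2.0,
    "extension_first_base_not_c": 2.0,
}
HOMOLOGY_CAP = 10
PBS_GC_RANGE = (0.30, 0.60)


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt NGG protospacer on either strand of the gene-model window."""

    seq20: str
    strand: int
    pam: str
    nick_pos: int
    specificity_score: Optional[float] = None
    ontarget_score: Optional[float] = None

    def __post_init__(self):
        if len(self.seq20) != 20 or self.pam[1:3] != "GG":
            raise ValueError("protospacer must be 20 nt with an NGG PAM")


def pam_window(sequence: str, proto: Protospacer, start: int, end: int) -> str:
    """PAM-strand sequence over nick offsets [start, end).

    Offset 0 is the first base 3' of the nick (+1); negative offsets are 5'
    of the nick.  Raises IndexError when the window leaves the reference.
    """
    if proto.strand == 1:
        lo, hi = proto.nick_pos + start, proto.nick_pos + end
        if lo < 0 or hi > len(sequence):
            raise IndexError("window outside reference")
        return sequence[lo:hi]
    lo, hi = proto.nick_pos - end + 1, proto.nick_pos - start + 1
    if lo < 0 or hi > len(sequence):
        raise IndexError("window outside reference")
    return revcomp(sequence[lo:hi])


def variant_on_pam_strand(variant: Variant, proto: Protospacer):
    """Express a variant in PAM-strand nick offsets.

    Returns ``(k0, ref_p, alt_p)`` where ``k0`` is the 0-based offset of the
    first altered (or first inserted) base from the nick, or ``None`` when
    the edit is not entirely 3' of the nick on this protospacer's strand.
    """
    if proto.strand == 1:
        k0 = variant.pos - proto.nick_pos
        ref_p, alt_p = variant.ref, variant.alt
    else:
        ref_p, alt_p = revcomp(variant.ref), revcomp(variant.alt)
        if variant.ref:
            k0 = proto.nick_pos - (variant.pos + len(variant.ref) - 1)
        else:  # insertion between plus positions pos-1 and pos
            k0 = proto.nick_pos - variant.pos + 1
    if k0 < 0:
        return None
    return k0, ref_p, alt_p


@dataclass
class PegFeatures:
    dist_to_nick: int
    post_edit_homology: int
    pbs_gc: float
    rtt_gc: float
    pam_disrupted: bool
    proto_disrupted: bool
    extension_first_base: str
    edit_len: int


@dataclass
class PegRNADesign:
    variant_id: str
    protospacer: Protospacer
    rtt_len: int
    pbs_len: int
    rtt: str
    pbs: str
    features: PegFeatures
    spacer_oligo: str
    sensor: object = None  # SensorConstruct, attached by the pipeline
    filter_flags: set = field(default_factory=set)
    composite_score: float = 0.0
    rank_within_variant: Optional[int] = None

    @property
    def extension(self) -> str:
        return self.rtt + self.pbs

    @property
    def design_id(self) -> str:
        if self.rank_within_variant is None:
            raise ValueError("design not ranked yet")
        return f"{self.variant_id}_pe{self.rank_within_variant:02d}"


class DesignRejection(Exception):
    """A candidate (protospacer, RTT, PBS) combination that cannot encode
    the edit; carries a human-readable reason."""


def enumerate_protospacers(
    gene_model: GeneModel, variant: Variant, max_rtt: int = max(RTT_GRID)
) -> list[Protospacer]:
    """All NGG protospacers (both strands) able to template the edit.

    A protospacer is eligible when the variant's first altered base sits at
    offset >= +1 from the nick on the PAM strand and an RTT of at most
    ``max_rtt`` nt can cover the whole edit plus >= 1 nt of post-edit
    homology inside the reference window.  Ordered by (strand, nick_pos).
    """
    seq = gene_model.sequence
    candidates = []
    for s in range(len(seq) - 22):
        if seq[s + 21 : s + 23] == "GG":
            candidates.append(
                Protospacer(
                    seq20=seq[s : s + 20], strand=1,
                    pam=seq[s + 20 : s + 23], nick_pos=s + 17,
                )
            )
    for j in range(len(seq) - 22):
        if seq[j : j + 2] == "CC":
            candidates.append(
                Protospacer(
                    seq20=revcomp(seq[j + 3 : j + 23]), strand=-1,
                    pam=revcomp(seq[j : j + 3]), nick_pos=j + 5,
                )
            )
    eligible = []
    for proto in candidates:
        placed = variant_on_pam_strand(variant, proto)
        if placed is None:
            continue
        k0, ref_p, alt_p = placed
        if k0 + len(alt_p) + 1 > max_rtt:
            continue
        try:  # >= 1 nt post-edit homology must exist inside the window
            pam_window(seq, proto, k0 + len(ref_p), k0 + len(ref_p) + 1)
        except IndexError:
            continue
        eligible.append(proto)
    eligible.sort(key=lambda p: (p.strand, p.nick_pos))
    return eligible


def build_pegrna(
    proto: Protospacer,
    variant: Variant,
    gene_model: GeneModel,
    rtt_len: int,
    pbs_len: int,
    prepend_g: bool = True,
) -> PegRNADesign:
    """Construct one pegRNA for a (protospacer, RTT length, PBS length) cell.

    The RTT is the reverse complement of the first ``rtt_len`` bases of the
    *edited* PAM strand read 3' from the nick; the PBS is the reverse
    complement of the ``pbs_len`` reference bases 5' of the nick.  Raises
    :class:`DesignRejection` when the RTT cannot cover the edit plus >= 1 nt
    of homology, or a window leaves the reference.
    """
    seq = gene_model.sequence
    placed = variant_on_pam_strand(variant, proto)
    if placed is None:
        raise DesignRejection("edit not 3' of the nick on this protospacer")
    k0, ref_p, alt_p = placed
    homology = rtt_len - k0 - len(alt_p)
    if homology < 1:
        raise DesignRejection(
            f"RTT {rtt_len} cannot cover edit end at +{k0 + len(alt_p)} "
            "with >=1 nt homology"
        )
    try:
        prefix = pam_window(seq, proto, 0, k0)
        ref_after = pam_window(seq, proto, k0 + len(ref_p), k0 + len(ref_p) + homology)
        pbs_target = pam_window(seq, proto, -pbs_len, 0)
    except IndexError as exc:
        raise DesignRejection(f"window outside reference ({exc})") from exc
    edited = prefix + alt_p + ref_after
    assert len(edited) == rtt_len
    rtt = revcomp(edited)
    pbs = revcomp(pbs_target)

    # PAM (+5/+6) and seed (+1..+3) disruption from the edited vs reference
    # first six post-nick bases; indels shift downstream bases and count.
    ref6 = pam_window(seq, proto, 0, 6)
    edited6 = (prefix + alt_p)[:6]
    if len(edited6) < 6:
        try:
            tail = pam_window(
                seq, proto, k0 + len(ref_p), k0 + len(ref_p) + 6 - len(edited6)
            )
        except IndexError:
            tail = ref_after[: 6 - len(edited6)]
        edited6 = (edited6 + tail)[:6].ljust(6, "N")
    features = PegFeatures(
        dist_to_nick=k0 + 1,
        post_edit_homology=homology,
        pbs_gc=gc_fraction(pbs),
        rtt_gc=gc_fraction(rtt),
        pam_disrupted=edited6[4:6] != ref6[4:6],
        proto_disrupted=edited6[0:3] != ref6[0:3],
        extension_first_base=rtt[0],
        edit_len=variant.edit_len,
    )
    spacer_oligo = ("G" + proto.seq20) if prepend_g else proto.seq20
    return PegRNADesign(
        variant_id=variant.id,
        protospacer=proto,
        rtt_len=rtt_len,
        pbs_len=pbs_len,
        rtt=rtt,
        pbs=pbs,
        features=features,
        spacer_oligo=spacer_oligo,
    )


@dataclass
class FilterConfig:
    polyt: bool = True
    ecori: bool = True
    esp3i: bool = True
    specificity: bool = False
    specificity_threshold: float = 50.0
    scaffold: str = DEFAULT_PARTS["scaffold"]
    motif3: str = DEFAULT_PARTS["motif3"]


def apply_filters(design: PegRNADesign, config: FilterConfig | None = None) -> set:
    """Exclusion flags for one design.

    POLYT scans the transcribed cassette (spacer oligo + scaffold +
    extension) for >= 4 consecutive Ts; the EcoRI/Esp3I scans cover the full
    variable region (spacer through sensor) and its reverse complement;
    SPECIFICITY fires when scoring is enabled and the protospacer's MIT
    specificity score is below the threshold.
    """
    config = config or FilterConfig()
    flags = set()
    transcribed = design.spacer_oligo + config.scaffold + design.extension
    if config.polyt and "TTTT" in transcribed:
        flags.add("POLYT")
    sensor_seq = design.sensor.wt_sensor if design.sensor is not None else ""
    variable = transcribed + config.motif3 + sensor_seq
    both = variable + "|" + revcomp(variable)
    if config.ecori and ECORI_SITE in both:
        flags.add("ECORI")
    if config.esp3i and ESP3I_SITE in both:
        flags.add("ESP3I")
    if config.specificity:
        score = design.protospacer.specificity_score
        if score is not None and score < config.specificity_threshold:
            flags.add("SPECIFICITY")
    design.filter_flags = flags
    return flags


def composite_score(design: PegRNADesign, weights: dict | None = None) -> float:
    """Linear composite score over the declared feature set.

    On-target scores are accepted on either a 0-1 or a 0-100 scale and
    contribute ``weight * score_0_1 * 100``; an absent score contributes 0.
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    unknown = set(weights) - set(DEFAULT_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown weight keys: {sorted(unknown)}")
    f = design.features
    ontarget = design.protospacer.ontarget_score or 0.0
    if ontarget > 1.0:
        ontarget /= 100.0
    phi = {
        "ontarget": ontarget * 100.0,
        "dist_to_nick": float(f.dist_to_nick),
        "post_edit_homology": float(min(f.post_edit_homology, HOMOLOGY_CAP)),
        "pam_disrupted": float(f.pam_disrupted),
        "proto_disrupted": float(f.proto_disrupted),
        "pbs_gc_in_range": float(PBS_GC_RANGE[0] <= f.pbs_gc <= PBS_GC_RANGE[1]),
        "extension_first_base_not_c": float(f.extension_first_base != "C"),
    }
    score = sum(weights.get(k, 0.0) * phi[k] for k in phi)
    design.composite_score = score
    return score


def rank_and_select(
    candidate_designs: list[PegRNADesign], max_per_variant: int = MAX_PER_VARIANT
) -> list[PegRNADesign]:
    """Rank passing candidates of one variant and truncate to the cap.

    Sorted by descending score; ties broken by smaller distance to nick,
    larger post-edit homology, then lexicographic spacer (stable and
    deterministic).  Ranks are assigned 1..n after truncation.
    """
    passing = [d for d in candidate_designs if not d.filter_flags]
    passing.sort(
        key=lambda d: (
            -d.composite_score,
            d.features.dist_to_nick,
            -d.features.post_edit_homology,
            d.protospacer.seq20,
            d.rtt_len,
            d.pbs_len,
        )
    )
    selected = passing[:max_per_variant]
    for i, d in enumerate(selected, start=1):
        d.rank_within_variant = i
    return selected
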