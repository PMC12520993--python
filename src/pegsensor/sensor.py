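"""Synthetic 60-nt sensors, oligo assembly and library export.

The sensor is a synthetic copy of the pegRNA's endogenous target window so
that each construct reports its own editing outcome.  The frame spans 24 nt
upstream to 36 nt downstream of the nick on the PAM strand — enough to cover
the full protospacer plus a 5-nt flank on one side and the longest RTT (30)
plus a 5-nt flank on the other — and is stored reverse-complemented
(reverse orientation relative to the cassette, which reduces lentiviral
template-switch recombination between spacer and sensor).  The first and
last five stored nucleotides double as recombination-detection barcodes and
are excluded from the editing quantification window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .design import PegRNADesign, Protospacer, pam_window, variant_on_pam_strand
from .parts import DEFAULT_PARTS, ECORI_SITE, ESP3I_SITE
from .variant_io import GeneModel, Variant, revcomp

SENSOR_UPSTREAM = 24   # nt of PAM-strand context 5' of the nick
SENSOR_DOWNSTREAM = 36  # nt 3' of the nick
SENSOR_LEN = SENSOR_UPSTREAM + SENSOR_DOWNSTREAM
BARCODE_LEN = 5


class SensorWindowError(ValueError):
    """Sensor frame leaves the gene-model window; the design is dropped."""


@dataclass
class SensorConstruct:
    wt_sensor: str
    edited_sensor: str
    barcode5: str
    barcode3: str
    window: tuple  # quantification window on the stored WT sensor
    nick_offset: int  # index of the first base 3' of the nick, stored frame
    barcode_collision: bool = False

    @property
    def wt_window(self) -> str:
        return self.wt_sensor[self.window[0] : self.window[1]]

    @property
    def edited_window(self) -> str:
        return self.edited_sensor[BARCODE_LEN : len(self.edited_sensor) - BARCODE_LEN]


def build_sensor(
    design: PegRNADesign,
    gene_model: GeneModel,
    variant: Variant,
    upstream: int = SENSOR_UPSTREAM,
    downstream: int = SENSOR_DOWNSTREAM,
) -> SensorConstruct:
    """Sensor for one design: endogenous PAM-strand window [nick-24, nick+36)
    reverse-complemented for storage, with the variant applied in-frame for
    the edited reference."""
    proto = design.protospacer
    try:
        window = pam_window(gene_model.sequence, proto, -upstream, downstream)
    except IndexError as exc:
        raise SensorWindowError(
            f"sensor frame exceeds gene model bounds for nick {proto.nick_pos}"
        ) from exc
    placed = variant_on_pam_strand(variant, proto)
    if placed is None:
        raise SensorWindowError("variant not placeable on this protospacer")
    k0, ref_p, alt_p = placed
    at = upstream + k0
    if window[at : at + len(ref_p)] != ref_p:
        raise AssertionError("sensor frame out of register with variant")
    edited_window = window[:at] + alt_p + window[at + len(ref_p) :]
    wt_sensor = revcomp(window)
    edited_sensor = revcomp(edited_window)
    return SensorConstruct(
        wt_sensor=wt_sensor,
        edited_sensor=edited_sensor,
        barcode5=wt_sensor[:BARCODE_LEN],
        barcode3=wt_sensor[-BARCODE_LEN:],
        window=(BARCODE_LEN, len(wt_sensor) - BARCODE_LEN),
        nick_offset=downstream,  # stored frame is reversed
    )


@dataclass
class OligoRecord:
    design_id: str
    full_sequence: str
    parts_map: dict  # part name -> (start, end) on full_sequence


def assemble_oligo(
    design: PegRNADesign, sensor: SensorConstruct, parts_config: dict | None = None
) -> OligoRecord:
    """Concatenate the full cloning oligo and return its part coordinate map.

    Fatal when the scaffold is missing or any part carries an EcoRI/Esp3I
    site other than the designated adapter sites.
    """
    parts_config = {**DEFAULT_PARTS, **(parts_config or {})}
    if not parts_config.get("scaffold"):
        raise ValueError("scaffold part is required")
    ordered = [
        ("adapter5", parts_config["adapter5"]),
        ("spacer", design.spacer_oligo),
        ("scaffold", parts_config["scaffold"]),
        ("extension", design.extension),
        ("motif3", parts_config["motif3"]),
        ("sensor", sensor.wt_sensor),
        ("adapter3", parts_config["adapter3"]),
    ]
    def physical_sites(seq: str, site: str) -> int:
        rc = revcomp(site)
        n = seq.count(site)
        if rc != site:  # palindromic sites exist once per duplex
            n += seq.count(rc)
        return n

    for name, seq in ordered:
        esp3i = physical_sites(seq, ESP3I_SITE)
        ecori = physical_sites(seq, ECORI_SITE)
        allowed_esp3i = 1 if name == "adapter5" else 0
        allowed_ecori = 1 if name == "adapter3" else 0
        if esp3i > allowed_esp3i or ecori > allowed_ecori:
            raise ValueError(f"part {name!r} contains an internal Esp3I/EcoRI site")
    full = ""
    parts_map = {}
    for name, seq in ordered:
        parts_map[name] = (len(full), len(full) + len(seq))
        full += seq
    return OligoRecord(
        design_id=design.design_id, full_sequence=full, parts_map=parts_map
    )


MANIFEST_COLUMNS = [
    "design_id", "variant_id", "rank", "vclass", "spacer", "spacer_oligo",
    "strand", "nick_pos", "pam", "rtt_len", "pbs_len", "rtt", "pbs",
    "extension", "dist_to_nick", "post_edit_homology", "pbs_gc", "rtt_gc",
    "pam_disrupted", "proto_disrupted", "extension_first_base", "edit_len",
    "composite_score", "specificity_score", "ontarget_score", "wt_sensor",
    "edited_sensor", "barcode5", "barcode3", "barcode_collision",
    "filter_flags",
]


def flag_barcode_collisions(designs: list[PegRNADesign]) -> int:
    """Mark designs whose (5', 3') sensor barcode pair is ambiguous.

    Designs of the same variant and protospacer legitimately share an
    identical sensor; that is not a collision.  A collision is the same
    barcode pair pointing at *different* sensor references (possible for
    nearby variants), which makes outcome attribution ambiguous.  Collisions
    are flagged (and those sensors excluded from editing accounting
    downstream), not fatal.  Returns the number of designs flagged.
    """
    groups: dict[tuple, list] = {}
    for d in designs:
        if d.sensor is None:
            continue
        groups.setdefault((d.sensor.barcode5, d.sensor.barcode3), []).append(d)
    n = 0
    for members in groups.values():
        references = {(d.sensor.wt_sensor, d.sensor.edited_sensor) for d in members}
        collide = len(references) > 1
        for d in members:
            d.sensor.barcode_collision = collide
        n += len(members) if collide else 0
    return n


def export_library(
    designs: list[PegRNADesign],
    manifest_path=None,
    fasta_path=None,
    variant_classes: dict | None = None,
    parts_config: dict | None = None,
) -> pd.DataFrame:
    """Write the library manifest CSV and full-oligo FASTA.

    One row / FASTA record per design, ordered by (variant_id, rank); the
    manifest is re-importable by the deconvolution stage.  Duplicate design
    ids are fatal.
    """
    flag_barcode_collisions(designs)
    ordered = sorted(designs, key=lambda d: (d.variant_id, d.rank_within_variant))
    rows = []
    seen = set()
    seen_cassettes = set()
    for d in ordered:
        if d.design_id in seen:
            raise ValueError(f"duplicate design_id {d.design_id}")
        seen.add(d.design_id)
        cassette = (d.spacer_oligo, d.extension)
        if cassette in seen_cassettes:
            raise ValueError(
                f"duplicate spacer+extension cassette at {d.design_id}; "
                "deduplicate the variant set (dedupe_variants)"
            )
        seen_cassettes.add(cassette)
        s = d.sensor
        rows.append(
            {
                "design_id": d.design_id,
                "variant_id": d.variant_id,
                "rank": d.rank_within_variant,
                "vclass": (variant_classes or {}).get(d.variant_id, ""),
                "spacer": d.protospacer.seq20,
                "spacer_oligo": d.spacer_oligo,
                "strand": d.protospacer.strand,
                "nick_pos": d.protospacer.nick_pos,
                "pam": d.protospacer.pam,
                "rtt_len": d.rtt_len,
                "pbs_len": d.pbs_len,
                "rtt": d.rtt,
                "pbs": d.pbs,
                "extension": d.extension,
                "dist_to_nick": d.features.dist_to_nick,
                "post_edit_homology": d.features.post_edit_homology,
                "pbs_gc": round(d.features.pbs_gc, 6),
                "rtt_gc": round(d.features.rtt_gc, 6),
                "pam_disrupted": d.features.pam_disrupted,
                "proto_disrupted": d.features.proto_disrupted,
                "extension_first_base": d.features.extension_first_base,
                "edit_len": d.features.edit_len,
                "composite_score": round(d.composite_score, 6),
                "specificity_score": d.protospacer.specificity_score,
                "ontarget_score": d.protospacer.ontarget_score,
                "wt_sensor": s.wt_sensor,
                "edited_sensor": s.edited_sensor,
                "barcode5": s.barcode5,
                "barcode3": s.barcode3,
                "barcode_collision": s.barcode_collision,
                "filter_flags": ";".join(sorted(d.filter_flags)),
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest_path is not None:
        manifest.to_csv(manifest_path, index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for d in ordered:
                record = assemble_oligo(d, d.sensor, parts_config)
                fh.write(f">{record.design_id}\n{record.full_sequence}\n")
    return manifest


def load_manifest(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    manifest = pd.read_csv(
        Path(path), sep=sep, dtype={"filter_flags": str}, keep_default_na=True
    )
    manifest["filter_flags"] = manifest["filter_flags"].fillna("")
    return manifest


def parse_design_id(design_id: str) -> tuple[str, int]:
    """Recover (variant_id, rank) from a design id."""
    variant_id, rank = design_id.rsplit("_pe", 1)
    return variant_id, int(rank)
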