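"""Gene models, variant tables and silent-control generation.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open, on the plus strand of the
supplied reference window.  Tables read and written by this module use the
1-based MAF-like dialect (columns ``gene, position, ref, alt, type`` plus any
numeric annotation columns).  For insertions the table ``position`` is the
1-based position of the base *before which* the insertion occurs; ``ref`` may
be ``-`` or empty.  Anchor-base rows (shared leading/trailing bases between
ref and alt) are left-aligned on parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

COMPLEMENT = str.maketrans("ACGT", "TGCA")
STOP_CODONS = {"TAA", "TAG", "TGA"}
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


class GeneModelError(ValueError):
    pass


@dataclass
class GeneModel:
    """Reference window with CDS annotation.

    Parameters
    ----------
    name : str
        Identifier of the locus.
    sequence : str
        Uppercase plus-strand DNA of the provided reference window.
    cds_intervals : list of (start, end)
        0-based half-open intervals on ``sequence``, in genomic order.
    strand_of_gene : int
        +1 if the coding strand is the stored plus strand, -1 otherwise.
    """

    name: str
    sequence: str
    cds_intervals: list[tuple[int, int]]
    strand_of_gene: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise GeneModelError(f"non-ACGT characters in sequence: {bad}")
        if self.strand_of_gene not in (1, -1):
            raise GeneModelError("strand_of_gene must be +1 or -1")
        ivals = [tuple(map(int, iv)) for iv in self.cds_intervals]
        ivals.sort()
        last = 0
        for s, e in ivals:
            if not (0 <= s < e <= len(self.sequence)):
                raise GeneModelError(f"CDS interval ({s}, {e}) out of bounds")
            if s < last:
                raise GeneModelError("CDS intervals overlap")
            last = e
        self.cds_intervals = ivals
        if self.cds_len % 3 != 0:
            raise GeneModelError(
                f"concatenated CDS length {self.cds_len} not divisible by 3"
            )
        # plus-strand positions of CDS bases, in translation order
        positions = [i for s, e in ivals for i in range(s, e)]
        if self.strand_of_gene == -1:
            positions = positions[::-1]
        self._cds_positions = positions
        self._pos_to_cds = {p: i for i, p in enumerate(positions)}

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_base(self, cds_index: int) -> str:
        base = self.sequence[self._cds_positions[cds_index]]
        return base if self.strand_of_gene == 1 else base.translate(COMPLEMENT)

    def cds_sequence(self) -> str:
        return "".join(self.cds_base(i) for i in range(self.cds_len))

    def protein(self) -> str:
        return translate(self.cds_sequence())

    def cds_index_of(self, pos: int) -> int | None:
        """CDS (translation-order) index of plus-strand position, or None."""
        return self._pos_to_cds.get(pos)

    def codon_at(self, codon_index: int) -> str:
        return "".join(self.cds_base(3 * codon_index + k) for k in range(3))


VALID_VTYPES = {"SNV", "INS", "DEL", "DELINS"}
VALID_VCLASSES = {"missense", "nonsense", "silent", "INS", "DEL", "noncoding"}


@dataclass
class Variant:
    """A single edit on a :class:`GeneModel`, left-aligned, anchor-free.

    ``pos`` is 0-based on the gene model sequence; for pure insertions the
    inserted bases go immediately before ``sequence[pos]``.
    """

    id: str
    pos: int
    ref: str
    alt: str
    vtype: str
    vclass: str = ""
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vtype not in VALID_VTYPES:
            raise ValueError(f"unknown vtype {self.vtype!r}")
        if self.vtype == "SNV" and not (
            len(self.ref) == len(self.alt) == 1 and self.ref != self.alt
        ):
            raise ValueError("SNV requires |ref|=|alt|=1 and ref != alt")

    @property
    def edit_len(self) -> int:
        return len(self.alt) - len(self.ref)

    def apply(self, sequence: str) -> str:
        """Return ``sequence`` with this variant installed."""
        if sequence[self.pos : self.pos + len(self.ref)] != self.ref:
            raise ValueError(f"ref allele mismatch at {self.pos}")
        return sequence[: self.pos] + self.alt + sequence[self.pos + len(self.ref) :]


def load_gene_model(fasta_path, cds_config) -> GeneModel:
    """Load a gene model from a FASTA file plus a CDS config.

    ``cds_config`` is a YAML path or a mapping with keys ``cds`` (list of
    1-based inclusive ``[start, end]`` pairs), optional ``record`` (FASTA
    record id when the file holds several), optional ``name`` and ``strand``.
    """
    if not isinstance(cds_config, dict):
        with open(cds_config) as fh:
            cds_config = yaml.safe_load(fh)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise GeneModelError(f"no FASTA records in {fasta_path}")
    wanted = cds_config.get("record")
    if wanted is None:
        if len(records) > 1:
            raise GeneModelError("multiple FASTA records; set 'record' in config")
        record = records[0]
    else:
        matches = [r for r in records if r.id == wanted]
        if not matches:
            raise GeneModelError(f"record {wanted!r} not found in {fasta_path}")
        record = matches[0]
    intervals = [(int(s) - 1, int(e)) for s, e in cds_config["cds"]]
    return GeneModel(
        name=cds_config.get("name", record.id),
        sequence=str(record.seq).upper(),
        cds_intervals=intervals,
        strand_of_gene=int(cds_config.get("strand", 1)),
    )


def _infer_vtype(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if not ref and alt:
        return "INS"
    if ref and not alt:
        return "DEL"
    return "DELINS"


def classify_variant(variant: Variant, gene_model: GeneModel) -> str:
    """Translated consequence class of a validated variant.

    Coding SNVs are translated in the CDS frame to
    missense/nonsense/silent; pure indels are classed INS/DEL; positions
    outside the CDS are noncoding.  Equal-length DELINS in the CDS is
    classed missense (protein-altering by construction).
    """
    if variant.vtype in ("INS", "DEL", "DELINS"):
        if variant.edit_len > 0:
            return "INS"
        if variant.edit_len < 0:
            return "DEL"
        in_cds = any(
            gene_model.cds_index_of(p) is not None
            for p in range(variant.pos, variant.pos + len(variant.ref))
        )
        return "missense" if in_cds else "noncoding"
    cds_idx = gene_model.cds_index_of(variant.pos)
    if cds_idx is None:
        return "noncoding"
    codon_index, offset = divmod(cds_idx, 3)
    ref_codon = gene_model.codon_at(codon_index)
    alt_base = variant.alt
    if gene_model.strand_of_gene == -1:
        alt_base = alt_base.translate(COMPLEMENT)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    if alt_aa == ref_aa:
        return "silent"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def _normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align: strip shared prefix (advancing pos), then shared suffix."""
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


def parse_variant_table(
    rows, gene_model: GeneModel
) -> tuple[list[Variant], pd.DataFrame]:
    """Parse a MAF-like table into validated :class:`Variant` objects.

    ``rows`` is a DataFrame (or path to TSV/CSV) with 1-based ``position``,
    ``ref``, ``alt`` and optional ``type``, ``id`` and numeric annotation
    columns.  Returns ``(variants, rejects)`` where ``rejects`` reports each
    dropped row with its reason.  Duplicate (pos, ref, alt) rows collapse to
    one Variant carrying an ``n_obs`` annotation.
    """
    if isinstance(rows, (str, Path)):
        sep = "," if str(rows).endswith(".csv") else "\t"
        rows = pd.read_csv(rows, sep=sep)
    rows = pd.DataFrame(rows)
    reserved = {"gene", "position", "ref", "alt", "type", "id"}
    annot_cols = [c for c in rows.columns if c not in reserved]

    variants: dict[tuple[int, str, str], Variant] = {}
    rejects = []

    def reject(i, row, reason):
        rejects.append(
            {
                "row_index": i,
                "position": row.get("position"),
                "ref": row.get("ref"),
                "alt": row.get("alt"),
                "reason": reason,
            }
        )

    for i, row in rows.iterrows():
        ref = "" if pd.isna(row.get("ref")) else str(row["ref"]).upper().strip()
        alt = "" if pd.isna(row.get("alt")) else str(row["alt"]).upper().strip()
        ref = "" if ref == "-" else ref
        alt = "" if alt == "-" else alt
        try:
            pos = int(row["position"]) - 1
        except (KeyError, TypeError, ValueError):
            reject(i, row, "bad position")
            continue
        pos, ref, alt = _normalize_alleles(pos, ref, alt)
        if not ref and not alt:
            reject(i, row, "empty edit")
            continue
        if (set(ref) | set(alt)) - set("ACGT"):
            reject(i, row, "non-ACGT allele")
            continue
        vtype = _infer_vtype(ref, alt)
        declared = row.get("type")
        if declared is not None and not pd.isna(declared):
            declared = str(declared).upper()
            if declared not in VALID_VTYPES:
                reject(i, row, f"unknown type {declared}")
                continue
            # declared type wins only if consistent with normalized alleles
            if declared != vtype and not (declared == "DELINS" and vtype == "SNV"):
                reject(i, row, f"type {declared} inconsistent with alleles")
                continue
        if not (0 <= pos <= len(gene_model.sequence)):
            reject(i, row, "position out of bounds")
            continue
        if gene_model.sequence[pos : pos + len(ref)] != ref:
            reject(i, row, "ref allele mismatch")
            continue
        key = (pos, ref, alt)
        if key in variants:
            variants[key].annotations["n_obs"] += 1
            continue
        vid = row.get("id")
        if vid is None or pd.isna(vid):
            vid = f"{gene_model.name}_{pos + 1}{ref or '-'}>{alt or '-'}"
        annotations = {"n_obs": 1}
        for c in annot_cols:
            val = row.get(c)
            if val is not None and not pd.isna(val):
                try:
                    annotations[c] = float(val)
                except (TypeError, ValueError):
                    pass
        variant = Variant(
            id=str(vid), pos=pos, ref=ref, alt=alt, vtype=vtype,
            annotations=annotations,
        )
        variant.vclass = classify_variant(variant, gene_model)
        variants[key] = variant

    rejects_df = pd.DataFrame(
        rejects, columns=["row_index", "position", "ref", "alt", "reason"]
    )
    return list(variants.values()), rejects_df


def write_variant_table(variants: list[Variant], gene_model: GeneModel) -> pd.DataFrame:
    """Render variants back to the 1-based table dialect (round-trippable)."""
    rows = []
    for v in variants:
        rows.append(
            {
                "gene": gene_model.name,
                "id": v.id,
                "position": v.pos + 1,
                "ref": v.ref or "-",
                "alt": v.alt or "-",
                "type": v.vtype,
                "vclass": v.vclass,
                **{k: val for k, val in v.annotations.items() if k != "n_obs"},
            }
        )
    return pd.DataFrame(rows)


def dedupe_variants(variants: list[Variant]) -> list[Variant]:
    """Drop later variants duplicating an earlier (pos, ref, alt) triple.

    Needed when combining sources — e.g. a generated silent control can
    coincide with an observed patient SNV, and duplicate edits would yield
    indistinguishable pegRNA cassettes downstream.
    """
    seen = set()
    unique = []
    for v in variants:
        key = (v.pos, v.ref, v.alt)
        if key not in seen:
            seen.add(key)
            unique.append(v)
    return unique


def _synonymous_options(gene_model: GeneModel, codon_index: int):
    """Single-nt synonymous substitutions of a codon, best first.

    Preference: third codon position, then transitions, then alphabetical alt.
    Returns (offset_in_codon, cds_ref_base, cds_alt_base) tuples.
    """
    codon = gene_model.codon_at(codon_index)
    if codon in STOP_CODONS:
        return []
    aa = translate(codon)
    options = []
    for offset in range(3):
        for alt in "ACGT":
            if alt == codon[offset]:
                continue
            mutated = codon[:offset] + alt + codon[offset + 1 :]
            if translate(mutated) == aa:
                is_transition = TRANSITIONS[codon[offset]] == alt
                options.append(
                    ((offset != 2, not is_transition, alt), offset, codon[offset], alt)
                )
    options.sort()
    return [(off, ref, alt) for _, off, ref, alt in options]


def generate_silent_controls(
    gene_model: GeneModel, n_controls: int, seed: int = 0
) -> list[Variant]:
    """Evenly tiled single-nucleotide synonymous controls across the CDS.

    Deterministic: eligible codons (those admitting a synonymous
    single-nucleotide substitution) are spread argmax-evenly over the CDS;
    within a codon, third-position transitions are preferred, ties broken
    alphabetically by alt allele.  ``seed`` is accepted for interface
    stability but the procedure has no random component.
    """
    del seed
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    n_codons = gene_model.cds_len // 3
    eligible = [
        ci for ci in range(n_codons) if _synonymous_options(gene_model, ci)
    ]
    if len(eligible) < n_controls:
        raise ValueError(
            f"only {len(eligible)} codons admit a synonymous substitution; "
            f"{n_controls} requested"
        )
    if n_controls == 1:
        chosen = [eligible[(len(eligible) - 1) // 2]]
    else:
        picks = sorted(
            {
                round(i * (len(eligible) - 1) / (n_controls - 1))
                for i in range(n_controls)
            }
        )
        # rounding can merge neighbours; pad with unused codons closest in order
        unused = [k for k in range(len(eligible)) if k not in set(picks)]
        while len(picks) < n_controls:
            picks.append(unused.pop(0))
        chosen = [eligible[k] for k in sorted(picks[:n_controls])]

    controls = []
    for ci in chosen:
        offset, cds_ref, cds_alt = _synonymous_options(gene_model, ci)[0]
        cds_index = 3 * ci + offset
        pos = gene_model._cds_positions[cds_index]
        ref, alt = cds_ref, cds_alt
        if gene_model.strand_of_gene == -1:
            ref = ref.translate(COMPLEMENT)
            alt = alt.translate(COMPLEMENT)
        controls.append(
            Variant(
                id=f"{gene_model.name}_silent_c{ci + 1}",
                pos=pos,
                ref=ref,
                alt=alt,
                vtype="SNV",
                vclass="silent",
            )
        )
    return controls
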