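"""Fully synthetic screens with known ground truth.

The simulator emulates the pooled sensor-screen protocol: a plasmid/early
control timepoint and later timepoints in untreated and drug-treated arms,
with replicates.  Each design carries a true sensor-editing rate (Beta-
distributed); editing accrues over passages toward that rate (saturating,
reflecting constitutive editor expression); and each variant carries a log2
per-passage fitness effect that acts only on the *edited* subpopulation of a
design's cell pool — the mechanism that makes sensor calibration
informative.  Silent controls always carry effect 0.  Reads are emitted as
three parallel FASTQ files per sample (spacer / extension / sensor), with
configurable pegRNA-sensor recombination, low-quality and unmatched-read
contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import GeneModel

STOPS = {"TAA", "TAG", "TGA"}


def simulate_gene(seed: int, length: int = 1200, gc: float = 0.5) -> GeneModel:
    """Random all-CDS toy gene: starts ATG, no internal in-frame stop,
    ends with a stop codon, GC content near ``gc``.  Deterministic by seed."""
    if length % 3 != 0 or length < 9:
        raise ValueError("length must be divisible by 3 and >= 9")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        codon = "".join(rng.choice(bases, size=3, p=probs))
        if codon not in STOPS:
            codons.append(codon)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    sequence = "".join(codons)
    return GeneModel(
        name=f"simgene{seed}",
        sequence=sequence,
        cds_intervals=[(0, length)],
        strand_of_gene=1,
    )


def simulate_variant_table(
    gene_model: GeneModel,
    n_snv: int = 40,
    n_ins: int = 5,
    n_del: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Random patient-style variant table (1-based dialect) on a toy gene."""
    rng = np.random.default_rng(seed)
    seq = gene_model.sequence
    rows = []
    margin = 40  # keep edits designable away from window edges
    positions = rng.choice(
        np.arange(margin, len(seq) - margin), size=n_snv + n_ins + n_del,
        replace=False,
    )
    for i, pos in enumerate(positions[:n_snv]):
        ref = seq[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        rows.append({"gene": gene_model.name, "position": pos + 1,
                     "ref": ref, "alt": alt, "type": "SNV"})
    for pos in positions[n_snv : n_snv + n_ins]:
        ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
        rows.append({"gene": gene_model.name, "position": pos + 1,
                     "ref": "-", "alt": ins, "type": "INS"})
    for pos in positions[n_snv + n_ins :]:
        size = int(rng.integers(1, 4))
        rows.append({"gene": gene_model.name, "position": pos + 1,
                     "ref": seq[pos : pos + size], "alt": "-", "type": "DEL"})
    return pd.DataFrame(rows)


@dataclass
class SimTruth:
    """Ground truth of one simulated screen."""

    editing_rate: dict        # design_id -> asymptotic correct-editing rate
    variant_effect: dict      # variant_id -> log2 growth advantage / passage
    recombination_rate: float = 0.0         # pegRNA-level (spacer/extension)
    sensor_recombination_rate: float = 0.0  # sensor-level (barcode swap)
    indel_rate: float = 0.01
    depth: int = 500          # expected reads per design per sample
    editing_rate_constant: float = 0.35  # saturation constant per passage
    low_quality_rate: float = 0.0
    unmatched_rate: float = 0.0
    seed: int = 0

    @classmethod
    def generate(
        cls,
        manifest: pd.DataFrame,
        seed: int = 0,
        beta_a: float = 0.35,
        beta_b: float = 1.3,
        effect_sd: float = 0.3,
        null_fraction: float = 0.5,
        **kwargs,
    ) -> "SimTruth":
        """Draw editing rates per design and fitness effects per variant.

        Rates are Beta(a, b); non-silent variants are null with probability
        ``null_fraction`` and otherwise Normal(0, effect_sd); silent
        variants always get effect 0.
        """
        rng = np.random.default_rng(seed)
        rates = {
            did: float(r)
            for did, r in zip(
                manifest["design_id"], rng.beta(beta_a, beta_b, len(manifest))
            )
        }
        effects = {}
        vclass = (
            manifest.drop_duplicates("variant_id")
            .set_index("variant_id")["vclass"]
            .to_dict()
        )
        for vid in manifest["variant_id"].unique():
            if vclass.get(vid) == "silent":
                effects[vid] = 0.0
            elif rng.random() < null_fraction:
                effects[vid] = 0.0
            else:
                effects[vid] = float(rng.normal(0.0, effect_sd))
        return cls(editing_rate=rates, variant_effect=effects, seed=seed, **kwargs)

    def edited_fraction(self, design_id: str, passages: float) -> float:
        rate = self.editing_rate[design_id]
        return rate * (1.0 - np.exp(-self.editing_rate_constant * passages))


@dataclass
class Sample:
    sample_id: str
    passages: float
    arm: str = "treated"  # "control" | "untreated" | "treated"


DEFAULT_SAMPLES = [
    Sample("ctrl_r1", 0.0, "control"),
    Sample("ctrl_r2", 0.0, "control"),
    Sample("ctrl_r3", 0.0, "control"),
    Sample("trt_r1", 10.0, "treated"),
    Sample("trt_r2", 10.0, "treated"),
    Sample("trt_r3", 10.0, "treated"),
]

ARM_SELECTION = {"control": 0.0, "untreated": 0.3, "treated": 1.0}


def simulate_counts(
    manifest: pd.DataFrame,
    truth: SimTruth,
    samples: list[Sample] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts-level simulation (no FASTQ round trip).

    Returns ``(counts, summaries, design_truth)``: the design x sample
    counts table, per-design/sample editing summaries in the deconvolution
    output schema, and a per-design truth table with realized edited
    fractions and the true treated-arm LFC.
    """
    samples = list(samples) if samples is not None else list(DEFAULT_SAMPLES)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    design_ids = list(manifest["design_id"])
    variant_of = dict(zip(manifest["design_id"], manifest["variant_id"]))
    n = len(design_ids)
    base_abundance = rng.lognormal(0.0, 0.3, n)

    counts = {}
    summary_rows = []
    truth_rows = {
        did: {
            "design_id": did,
            "variant_id": variant_of[did],
            "editing_rate": truth.editing_rate[did],
            "effect": truth.variant_effect[variant_of[did]],
        }
        for did in design_ids
    }
    for sample in samples:
        selection = ARM_SELECTION[sample.arm]
        e = np.array(
            [truth.edited_fraction(d, sample.passages) for d in design_ids]
        )
        effects = np.array(
            [truth.variant_effect[variant_of[d]] for d in design_ids]
        )
        growth = (1.0 - e) + e * np.exp2(
            effects * selection * sample.passages
        )
        weights = base_abundance * growth
        total_reads = truth.depth * n
        sample_counts = rng.multinomial(total_reads, weights / weights.sum())
        counts[sample.sample_id] = pd.Series(sample_counts, index=design_ids)
        # sensor outcome draws; sensor-recombined reads never reach outcomes
        kept = rng.binomial(sample_counts, 1.0 - truth.sensor_recombination_rate)
        p_correct = e * (1.0 - truth.indel_rate)
        p_indel = np.full(n, truth.indel_rate)
        for i, did in enumerate(design_ids):
            probs = [p_correct[i], p_indel[i], 1.0 - p_correct[i] - p_indel[i]]
            n_correct, n_indel, n_unedited = rng.multinomial(kept[i], probs)
            total = int(kept[i])
            summary_rows.append(
                {
                    "design_id": did,
                    "sample_id": sample.sample_id,
                    "n_assigned_reads": int(sample_counts[i]),
                    "n_sensor_reads": total,
                    "n_correct": int(n_correct),
                    "n_unedited": int(n_unedited),
                    "n_indel": int(n_indel),
                    "n_other": 0,
                    "frac_correct": n_correct / total if total else 0.0,
                    "frac_unedited": n_unedited / total if total else 0.0,
                    "frac_indel": n_indel / total if total else 0.0,
                    "frac_other": 0.0,
                    "below_efficiency_min": total < 100,
                    "below_calibration_min": total < 10,
                    "correct_pct": 100.0 * n_correct / total if total else 0.0,
                }
            )
            truth_rows[did][f"edited_frac_{sample.sample_id}"] = float(e[i])
        max_t = max((s.passages for s in samples), default=0.0)
        if sample.arm == "treated" and sample.passages == max_t:
            for i, did in enumerate(design_ids):
                truth_rows[did]["true_lfc"] = float(np.log2(growth[i]))
    counts_df = pd.DataFrame(counts)
    counts_df.index.name = "design_id"
    return (
        counts_df,
        pd.DataFrame(summary_rows),
        pd.DataFrame(truth_rows.values()),
    )


def _write_fastq(path: Path, reads: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "".join(f"@{name}\n{seq}\n+\n{qual}\n" for name, seq, qual in reads)
        )


GOOD_Q = "I"   # Phred 40
LOW_Q = ":"    # Phred 25, below the mean-30 filter


def simulate_screen(
    manifest: pd.DataFrame,
    truth: SimTruth,
    out_dir,
    samples: list[Sample] | None = None,
) -> dict:
    """Write per-sample FASTQ triplets plus truth tables.

    Returns a mapping ``sample_id -> {role: path}`` consumable by
    :func:`pegsensor.deconvolution.run_deconvolution`.  Contamination reads
    (pegRNA-recombined, low-quality, unmatched) are emitted on top of the
    assigned counts so that the deconvolution tallies can be checked
    against known injection rates.
    """
    samples = list(samples) if samples is not None else list(DEFAULT_SAMPLES)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed + 1)
    counts_df, summaries, design_truth = simulate_counts(manifest, truth, samples)

    rows = list(manifest.itertuples(index=False))
    by_id = {r.design_id: r for r in rows}
    design_ids = [r.design_id for r in rows]
    layout = {}
    summaries = summaries.set_index(["design_id", "sample_id"])
    for sample in samples:
        spacer_reads, ext_reads, sensor_reads = [], [], []
        serial = 0

        def emit(spacer, ext, sensor, qual):
            nonlocal serial
            name = f"{sample.sample_id}.{serial}"
            serial += 1
            spacer_reads.append((name, spacer, qual * len(spacer)))
            ext_reads.append((name, ext, qual * len(ext)))
            sensor_reads.append((name, sensor, qual * len(sensor)))

        for did in design_ids:
            row = by_id[did]
            s = summaries.loc[(did, sample.sample_id)]
            n_assigned = int(s["n_assigned_reads"])
            n_sensor = int(s["n_sensor_reads"])
            n_swapped = n_assigned - n_sensor
            outcome_reads = (
                [(row.edited_sensor, int(s["n_correct"]))]
                + [(row.wt_sensor, int(s["n_unedited"]))]
                + [(_indel_read(row.wt_sensor), int(s["n_indel"]))]
            )
            for sensor_seq, k in outcome_reads:
                for _ in range(k):
                    emit(row.spacer_oligo, row.extension, sensor_seq, GOOD_Q)
            for _ in range(n_swapped):  # sensor recombination: foreign sensor
                other = by_id[design_ids[rng.integers(len(design_ids))]]
                emit(row.spacer_oligo, row.extension, other.wt_sensor, GOOD_Q)
            # contamination on top of assigned counts
            for _ in range(rng.binomial(n_assigned, truth.recombination_rate)):
                other = by_id[design_ids[rng.integers(len(design_ids))]]
                if other.extension != row.extension:
                    emit(row.spacer_oligo, other.extension, other.wt_sensor, GOOD_Q)
            for _ in range(rng.binomial(n_assigned, truth.low_quality_rate)):
                emit(row.spacer_oligo, row.extension, row.wt_sensor, LOW_Q)
            for _ in range(rng.binomial(n_assigned, truth.unmatched_rate)):
                emit("N" * len(row.spacer_oligo), row.extension, row.wt_sensor,
                     GOOD_Q)
        paths = {
            role: out_dir / f"{sample.sample_id}_{role}.fastq"
            for role in ("spacer", "extension", "sensor")
        }
        _write_fastq(paths["spacer"], spacer_reads)
        _write_fastq(paths["extension"], ext_reads)
        _write_fastq(paths["sensor"], sensor_reads)
        layout[sample.sample_id] = {k: str(v) for k, v in paths.items()}

    design_truth.to_csv(out_dir / "truth_designs.tsv", sep="\t", index=False)
    counts_df.to_csv(out_dir / "truth_counts.tsv", sep="\t")
    return layout


def _indel_read(wt_sensor: str) -> str:
    """WT sensor with a 2-nt deletion at the window centre (barcodes kept)."""
    mid = len(wt_sensor) // 2
    return wt_sensor[:mid] + wt_sensor[mid + 2 :]
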